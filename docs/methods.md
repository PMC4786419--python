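# Methods

This note documents the models, the synthetic world the generator states,
the numerical choices, and what a green test does and does not establish.

## Coordinate and sign conventions

All positions are in nm, with the extracellular space at +x (the standard
orientation for these preparations); pixel `i` spans `[i·ps, (i+1)·ps)` with
center `(i+0.5)·ps`, and every fit reports continuous nm coordinates.
Vesicle positions are expressed relative to the ribbon center (the peak of
the ribbon's fitted Gaussian) to cancel slow drift of the cell or ribbon;
positive displacement components point toward the plasma membrane.

## The profile model

The intensity along a line crossing the membrane is modeled as
`f(x) = s(x) + g(x)` with

* `s(x) = b − c / (1 + exp((x½ − x)/d))` — a logistic transition from the
  intracellular background `b` to the extracellular level `b − c`, with
  slope factor `d`; `x½` is taken as the membrane position. (The logistic
  form is used throughout; a `1 − exp` denominator would have a pole at
  `x = x½` and cannot describe the smooth transition it is meant to
  represent, so it is treated as a sign typo in the source description.)
* `g(x) = a·exp(−(x − x₀)²/w²)` — the emitter (ribbon, vesicle label or
  fusion reporter), `x₀` its position, and `w = √2 · SD`.

Identifiability comes from constraints, not from the data alone:
`w` is bounded to the PSF-derived width `√2·σ_psf` ± 30 % when a PSF
calibration is supplied; `d ∈ [pixel/2, 10·pixel]`; `b` and `c` are seeded
from the inner/outer 10 % tails; positions are bounded to the fitted
window, so a fit can never report a position outside it. Weighting is
uniform (the source does not state a weighting scheme).

**Optimization.** Bounded trust-region least squares with analytic
Jacobians, tolerance 1e-8, ≤2000 evaluations. The composite fit is
multi-started over `x₀` (profile max after subtracting a sigmoid-only
pre-fit, optional hint, window midpoint, deduplicated within one pixel)
plus one "emitter-on-the-membrane" start in which the Gaussian claims the
whole peak and the sigmoid crosses steeply just extracellular of it; a
final alternation pass (subtract fitted Gaussian → refit sigmoid →
recompose) guards against overlap local minima. Best residual wins; ties
break toward the smallest `|x₀ − start|`. On noiseless profiles the fit
agrees with a 0.5-nm brute-force grid search to within one grid step.

A composite request falls back (flagged) to Gaussian-plus-offset when the
tail difference is below 8 % of the profile's dynamic range — no sigmoid
transition is detectable. Composite fits with `x₀ ≥ x½` are flagged, not
dropped. Emitter-channel blocks are fitted Gaussian-only and take the
membrane from the ribbon channel's composite fit of the same scan.

## 2-D localization and PSF calibration

Frame-averaged spots are fitted as elliptical 2-D Gaussians plus offset
(six parameters, same optimizer). The PSF sigma is calibrated by fitting a
rendered sub-resolution bead (uniform 27-nm disc convolved with the PSF;
the disc adds only `r²/4 ≈ 46 nm²` to the ~12 000 nm² PSF variance, hence
the sub-2 % agreement). Anisotropy `|sd_x − sd_y|/σ > 0.2` sets a warning
flag. Against Poisson noise the localization RMSE of the bounded fit
matches a plain unconstrained least-squares oracle within 25 %; it sits
~35 % above the position-only Cramér–Rao bound, the expected cost of
estimating offset and widths simultaneously with uniform weights.

## Event detection and decline classification

The per-block fitted amplitude is thresholded at `baseline + k·σ` with
`k = 4`, held for `m = 3` consecutive blocks (both tunable; the source
states no criterion, so this k·SD change-point rule is a declared
stand-in). The baseline matters: with a structured background the fitted
amplitude of an emitter-free block is small but not zero-mean, so baseline
and σ are estimated from emitter-free blocks — externally calibrated, or
taken from the low mode of the amplitude trace when it is clearly bimodal
(separation > 6σ); otherwise the baseline stays at zero. Appearance loci
are read from the first supra-threshold block, disappearance loci from the
last. Fusion-reporter channels are treated identically with appearances
labeled fusions.

Declines around a disappearance are fitted with three candidates —
constant-then-Gaussian (`A·exp(−(t−t₀)²/width²)`, the exact time course of
an emitter leaving the scanned line at constant speed), instantaneous step
(bleaching; changepoint by exhaustive scan), and first-order exponential —
and selected by small-sample-corrected AIC. Gaussian wins only on a
strictly lowest criterion (ties go to step), and a fitted decline faster
than one averaged block collapses to step: below the sampling resolution
the models are not distinguishable.

## Membrane curvature across the optical section

Sigmoid fits at multiple y-offsets of a ribbon-channel frame give
`x½(y)`; rows where the fitted emitter amplitude exceeds half the sigmoid
drop are excluded (the membrane is read from rows the ribbon does not
dominate). An algebraic (Kåsa) circle fit on ≥5 points gives radius `R`
(treated as flat above 1e5 nm or when `x½(y)` is structureless), and the
membrane at the top/bottom of an optical section of thickness `T` is
`x_extreme = x_mid − [R − √(R² − (T/2)²)]`, assuming the in-plane curvature
also applies along z.

## Statistics

Sign test: exact binomial at p = ½; two-sided p is twice the smaller tail,
capped at 1. (A reported p of 0.0008 for 45/64 positive corresponds to the
one-sided tail; the two-sided default gives 0.0016. Both sidedness options
are exposed.) Rank-sum: two-sample Wilcoxon/Mann–Whitney, exact
permutation distribution for tie-free samples with `min(n) ≤ 7` and
`n₁+n₂ ≤ 14`, otherwise the tie-corrected normal approximation; identical
samples return p = 1 with a degeneracy flag. "Wilcoxon rank test" is
interpreted as this two-sample test since the compared displacement sets
are independent; sidedness defaults to two-sided. Population means are
reported ± sem; the 50-nm amplitude threshold uses strict inequality.

## The synthetic world

The generator states one set of conditions and the tests live inside it:

* Imaging: pixel 40 nm, PSF σ 110 nm, line period 1.4 ms, frame period
  0.5 s, Poisson shot noise on `(signal + background)·photon_scale`
  (photon-limited confocal detection; optional Gaussian read noise, default
  0). Backgrounds: cytoplasmic fill 2.0 vs extracellular 0.2 intensity
  units in the ribbon channel (the ribbon label also fills the cell,
  rendered as the logistic transition), scaled by 0.25 in the sparse
  emitter channel; emitter amplitude 5, photon scale 3.
* Geometry: membrane at x = 800 nm (circular arc optional), ribbon center
  150 nm intracellular of it, ribbon label an anisotropic Gaussian
  (60, 120) nm SD.
* Tether wobble: AR(1) jitter with stationary SD (10, 7) nm and a 5-s
  correlation time. Independent per-frame jitter would be averaged away by
  4–10-frame epochs; a slow wobble survives epoch averaging (observed x/y
  position ranges ≈ 25/18 nm over ten repeats) yet decorrelates across
  18-s repeats. No quantitative SNR is stated by the source; these levels
  are calibrated only to reproduce the reported localization jitter
  qualitatively.
* Stimulus-evoked behavior: the stimulus is a timestamp; behavior is
  conditioned on it directly (no calcium model). Displaced survivors draw
  gamma(shape 3) shift magnitudes whose mixture mean equals the configured
  `mean_shift_x` (default 33 nm) given the configured positive fraction
  (default 0.70); the away/toward mean-magnitude ratio is fixed at 59/89.
  The toward/away **composition** is fixed at `round(f·n)` (shuffled), not
  an iid coin flip — the generator emulates a stated population
  composition, keeping the scene-level truth close to the configured
  effect. Disappearances start membrane-proximal (0.30–0.85 of the
  ribbon–membrane distance), appearances distal; in the x-y paradigm the
  loss is locked to the stimulus gap and the label disperses fast against
  the frame interval (departure speed floored at 50 nm/ms), while in line
  scans departures move along −y at 1.5 nm/ms, giving decline widths of
  ~70 ms. Fusion loci spread along the ribbon with SD `event_spread`
  (default 120 nm).

**What the generator does not emulate:** mechanistic ribbon diffusion or
calcium domains, 3-D volumetric rendering (the optical section enters only
through the curvature correction), detector artifacts beyond Poisson/read
noise, multi-emitter fields (the paradigm guarantees at most one labeled
vesicle per field), or focus drift. A green test therefore establishes
that the analysis recovers what it measures under photon-limited noise and
the stated wobble — not that real detectors or real vesicle biophysics are
reproduced.

## Known limitations

* The automatic amplitude-baseline estimator needs a clearly bimodal trace;
  an all-empty emitter channel without external calibration can flicker
  across the zero-baseline threshold. Supply `noise_sd` (and use
  emitter-free calibration scans) for such data.
* Ribbon-channel 2-D spot fits sit on the membrane-fill gradient, giving a
  small constant intracellular bias in the ribbon center; it cancels in
  ribbon-relative differences, which is what every reported quantity uses.
* Per-block composite fits at low SNR scatter in `x½`; membrane distances
  from single blocks are correspondingly noisy (ribbon-relative `dx` is
  not affected).
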