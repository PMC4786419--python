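# ribbontrack

Single-vesicle localization and dynamics at the ribbon-type active zone of
retinal bipolar-cell terminals, from two-channel confocal imaging.

At ribbon synapses, a presynaptic structure — the synaptic ribbon — tethers
synaptic vesicles and supplies them for continuous transmitter release.
Experiments that follow one fluorescently tagged vesicle at a time (a
photoactivatable label on the vesicle, a second label on the ribbon, and
optionally a pH-sensitive fusion reporter) produce two kinds of data:

* **x-y repeat trials** — short bursts of frames averaged before and after a
  brief depolarizing stimulus, repeated at ~18-s intervals, from which one
  asks whether the vesicle appeared, disappeared, or moved;
* **x-t line scans** — a line scanned across the plasma membrane every
  ~1.4 ms during sustained depolarization, from which one tracks the
  vesicle's approach to the membrane and the time course of its loss.

`ribbontrack` implements the full analysis for both paradigms, plus a
ground-truth synthetic-scene generator used to validate every stage.

## The models at the core

**1-D profile model** (line scans, `ProfileModel`). The intensity along a
scan line crossing the membrane is fitted with `f(x) = s(x) + g(x)`:

    s(x) = b − c / (1 + exp((x½ − x)/d))        (membrane transition)
    g(x) = a · exp(−(x − x₀)² / w²)             (emitter, w = √2·SD)

`b` is the intracellular background, `b − c` the extracellular level, `d`
the sigmoid slope factor, and `w` is tied to the measured PSF (±30 %).
**`x½` is taken as the plasma-membrane position and `x₀` as the emitter
(ribbon or vesicle) position**; with the other parameters tightly
constrained these are the effective free parameters. Fitting is bounded
nonlinear least squares with multi-start initialization and analytic
Jacobians; `fit()` returns a results object with estimates, standard
errors, residual, convergence flag and a `summary()` table.

**2-D spot model** (frame averages, `SpotModel2D`). Ribbon and vesicle are
localized as elliptical 2-D Gaussians plus offset; the PSF is calibrated by
the same fit on a sub-resolution (27-nm) bead image.

Downstream, vesicle positions are expressed **relative to the ribbon
center** (+x toward the membrane), trial-to-trial changes become
displacement vectors `(ΔΔx, ΔΔy)` with amplitude `√(ΔΔx² + ΔΔy²)`,
appearances/disappearances are detected by a k·SD amplitude threshold held
for m consecutive averaged blocks, intensity declines are classified
(Gaussian-in-time vs step vs exponential, by AICc), and membrane curvature
across the optical section is corrected by a circle fit to `x½(y)`:
`x_extreme = x_mid − [R − √(R² − (T/2)²)]`. Statistics are nonparametric
(exact sign test, Wilcoxon rank-sum).

## Worked example

```python
import ribbontrack as rt

cfg      = rt.RunConfig(paradigm="xy_repeat_trials", n_trials=64, seed=0)
behavior = rt.BehaviorConfig(mean_shift_x=33.0, frac_positive_ddx=0.70)
imaging  = rt.ImagingParams(channel_scheme="simultaneous")

report = rt.run_xy_repeat_trials(cfg, behavior, imaging,
                                 kinds=["displaced"] * 64)
print(report.stats.to_string(index=False))
```

prints (seed 0):

```
             name     value
        n_vectors 64.000000
      mean_ddx_nm 32.995288
       sem_ddx_nm  8.491431
      mean_ddy_nm -8.060106
  frac_below_50nm  0.375000
frac_positive_ddx  0.703125
      sign_test_p  0.001563
    n_appearances  0.000000
 n_disappearances  0.000000
```

Sixty-four vesicles that survive a brief stimulus were simulated with a
mean 33-nm shift toward the membrane and 70 % of shifts positive; the
pipeline (render → average → 2-D Gaussian fits → ribbon-relative vectors)
recovers a mean ΔΔx of ~33 nm, a positive fraction of 0.70, and a two-sided
sign test rejecting equal +/− at p ≈ 0.0016. A no-stimulation control
(`mean_shift_x=0`, `kinds=["stable"]*n`) yields vectors almost entirely
below 50 nm and no detected events.

There is also a CLI: `ribbontrack simulate|fit-linescan|run --help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main end-to-end analyses from scratch: a
194-trial brief-stimulus series (59 losses, 71 gains, 64 survivors) with
its displacement and locus statistics, and a sustained-depolarization line
scan with event detection and decline classification, writing the results
JSON to `--out`.
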