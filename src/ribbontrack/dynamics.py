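"""Ribbon-relative vesicle dynamics: positions, displacements, events.

All positions are expressed relative to the center of the ribbon (the peak
of its fitted Gaussian) to control for slow movements of the cell or ribbon
during an experiment.  The sign convention is fixed throughout: **+x points
toward the plasma membrane / extracellular side**, y runs along the
membrane.  A trial-to-trial change in relative position is the displacement
vector (ddx, ddy) with amplitude ``sqrt(ddx^2 + ddy^2)``.

Appearances and disappearances of the single labeled vesicle are detected
from the fitted-amplitude trace with a k·SD threshold held for a minimum
number of consecutive averaged blocks; the intensity decline around a
disappearance is classified as Gaussian-in-time (emitter diffusing out of
the scanned region), an abrupt step (bleaching), or an exponential, by
corrected small-sample AIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import NoEventError, PropagationError
from .profiles import ProfileFitResults, SpotFit2DResults, fit_profile
from .scene import ImagingParams

__all__ = [
    "RelativePosition",
    "DisplacementVector",
    "VesicleEvent",
    "DeclineFit",
    "MembraneBounds",
    "relative_position",
    "displacement",
    "track_line_positions",
    "detect_events",
    "classify_decline",
    "membrane_bounds",
    "event_position_histogram",
    "HistogramResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelativePosition:
    """Emitter position relative to the ribbon center (nm); +x extracellular."""

    dx: float
    dy: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx) and np.isfinite(self.dy)):
            raise ValueError("relative position must be finite")


@dataclass(frozen=True)
class DisplacementVector:
    """Change in ribbon-relative position across a trial (nm)."""

    ddx: float
    ddy: float

    @property
    def amplitude(self) -> float:
        return math.hypot(self.ddx, self.ddy)


@dataclass
class DeclineFit:
    """Best decline model around a disappearance.

    ``width`` is the Gaussian temporal width (sqrt(2) x SD, s); ``t_half``
    the time at which the fitted intensity reaches half its pre-decline
    level; ``scores`` maps each candidate model to its AICc.
    """

    model: str
    t_half: float
    width: float
    scores: dict


@dataclass
class VesicleEvent:
    """An appearance, disappearance or fusion with its ribbon-relative locus."""

    kind: str
    locus: RelativePosition
    membrane_distance: float
    t_event: float
    decline: DeclineFit | None = None
    block_index: int = -1


@dataclass
class MembraneBounds:
    """Membrane x at the focal plane and at the optical-section extremes (nm).

    Curvature moves the membrane intracellularly (toward smaller x) away
    from the focal plane, so ``x_extreme <= x_mid``.
    """

    x_mid: float
    x_extreme: float
    radius: float = math.inf

    def __post_init__(self) -> None:
        if self.x_extreme > self.x_mid + 1e-9:
            raise ValueError("x_extreme cannot exceed x_mid")


# ---------------------------------------------------------------------------
# positions and displacements
# ---------------------------------------------------------------------------

def _peak_of(fit) -> tuple[float, float]:
    if isinstance(fit, SpotFit2DResults):
        return fit.x_peak, fit.y_peak
    if isinstance(fit, ProfileFitResults):
        return fit.x_0, 0.0
    raise TypeError("fit must be a SpotFit2DResults or ProfileFitResults")


def relative_position(spot, ribbon, t: float = 0.0) -> RelativePosition:
    """Emitter peak minus ribbon peak, +x toward the extracellular side.

    Both fits must have converged and share a coordinate frame; profile fits
    contribute only their x coordinate (dy = 0).
    """
    for name, f in (("spot", spot), ("ribbon", ribbon)):
        if not f.converged:
            raise PropagationError(f"{name} fit did not converge")
    sx, sy = _peak_of(spot)
    rx, ry = _peak_of(ribbon)
    return RelativePosition(dx=sx - rx, dy=sy - ry, t=t)


def displacement(before: RelativePosition, after: RelativePosition) -> DisplacementVector:
    """Displacement vector across a trial; positive ddx = toward the membrane."""
    return DisplacementVector(ddx=after.dx - before.dx, ddy=after.dy - before.dy)


# ---------------------------------------------------------------------------
# line-scan tracking
# ---------------------------------------------------------------------------

def track_line_positions(emitter_fits: list, emitter_times: list,
                         ribbon_fits: list, ribbon_times: list) -> pd.DataFrame:
    """Express per-block emitter positions relative to ribbon and membrane.

    Both fit streams come from the same interleaved scan; each emitter block
    is paired with the nearest-in-time ribbon block, which supplies the
    ribbon center ``x_0`` and the membrane ``x_half``.  Blocks without a
    converged ribbon fit are skipped and logged.  Returns a DataFrame with
    columns ``t, dx, membrane_distance, amplitude, converged``.
    """
    rib_t, rib = [], []
    for t, f in zip(ribbon_times, ribbon_fits):
        if f is not None and f.converged:
            rib_t.append(t)
            rib.append(f)
    rows = []
    for t, f in zip(emitter_times, emitter_fits):
        if f is None:
            continue
        if not rib:
            logger.warning("no converged ribbon fit for block at t=%.4f; skipped", t)
            continue
        j = int(np.argmin(np.abs(np.asarray(rib_t) - t)))
        r = rib[j]
        x_half = r.x_half
        rows.append({
            "t": t,
            "dx": f.x_0 - r.x_0,
            "membrane_distance": (x_half - f.x_0) if np.isfinite(x_half) else np.nan,
            "amplitude": f.a,
            "converged": bool(f.converged),
        })
    return pd.DataFrame(rows, columns=["t", "dx", "membrane_distance",
                                       "amplitude", "converged"])


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_events(track: pd.DataFrame, noise_sd: float, k_on: float = 4.0,
                  m_consec: int = 3, channel: str = "emitter",
                  baseline: float = 0.0) -> list[VesicleEvent]:
    """Detect appearance/disappearance events on an amplitude trace.

    An appearance is scored when the fitted amplitude rises above
    ``baseline + k_on * noise_sd`` for at least ``m_consec`` consecutive
    averaged blocks from a below-threshold state (locus: the first
    qualifying block); a disappearance when it falls below for as long
    (locus: the last supra-threshold block).  ``baseline`` and ``noise_sd``
    are estimated from emitter-free blocks: with a structured background
    the fitted amplitude of an empty block is small but not zero-mean.
    ``channel="fusion"`` labels appearances as fusion events (a reporter
    with zero pre-stimulus baseline).
    """
    if k_on <= 0 or m_consec < 1:
        raise ValueError("k_on must be positive and m_consec >= 1")
    n = len(track)
    if n < m_consec:
        raise ValueError(f"track has {n} blocks, fewer than m_consec={m_consec}")
    amp = track["amplitude"].to_numpy(dtype=float)
    above = amp > baseline + k_on * noise_sd

    def _runs_ok(i: int, state: bool) -> bool:
        j = i
        while j < n and above[j] == state:
            j += 1
        return (j - i) >= m_consec

    events: list[VesicleEvent] = []
    appear_kind = "fusion" if channel == "fusion" else "appearance"

    def _event(kind: str, idx: int) -> VesicleEvent:
        row = track.iloc[idx]
        locus = RelativePosition(dx=float(row["dx"]),
                                 dy=float(row.get("dy", 0.0)),
                                 t=float(row["t"]))
        return VesicleEvent(kind=kind, locus=locus,
                            membrane_distance=float(row["membrane_distance"]),
                            t_event=float(row["t"]), block_index=idx)

    state = bool(above[0])
    i = 1
    while i < n:
        if above[i] != state and _runs_ok(i, not state):
            if not state:
                events.append(_event(appear_kind, i))
            else:
                events.append(_event("disappearance", i - 1))
            state = not state
        i += 1
    return events


# ---------------------------------------------------------------------------
# decline classification
# ---------------------------------------------------------------------------

def _aicc(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def classify_decline(times, amplitudes) -> DeclineFit:
    """Classify the intensity decline around a disappearance.

    Fits three candidates by least squares and selects by AICc:

    * ``gaussian`` — level A until t0, then ``A exp(-(t-t0)^2/width^2)``:
      the signature of an emitter moving away from the scanned line at
      roughly constant speed;
    * ``step`` — instantaneous drop to baseline at t0 (bleaching);
    * ``exponential`` — first-order decay from t0.

    A Gaussian verdict requires a strictly lowest criterion; criterion ties
    go to ``step`` (conservative against over-claiming diffusion).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 10:
        raise ValueError("need matched 1-D times/amplitudes with >= 10 blocks "
                         "(>= 5 before and after the candidate disappearance)")
    k5 = 5
    pre, post = float(np.mean(y[:k5])), float(np.mean(y[-k5:]))
    if not (pre > 0 and post < 0.5 * pre):
        raise NoEventError("trace shows no decline to classify")

    n = t.size
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    scores: dict[str, float] = {}
    fits: dict[str, tuple] = {}

    # gaussian: A before t0, Gaussian decline after
    def g_model(p):
        A, t0, w, b = p
        out = np.where(t <= t0, A, b + (A - b) * np.exp(-((t - t0) ** 2) / w**2))
        return out

    best = None
    for t0g in np.quantile(t, [0.2, 0.4, 0.6, 0.8]):
        p0 = np.array([pre, t0g, max(4 * dt, span / 8), max(post, 0.0)])
        lb = np.array([0.0, t[0], dt, 0.0])
        ub = np.array([2 * max(pre, y.max()), t[-1], 2 * span, pre])
        sol = least_squares(lambda p: g_model(p) - y, np.clip(p0, lb, ub),
                            bounds=(lb, ub), method="trf", max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    sse_g = 2.0 * best.cost
    scores["gaussian"] = _aicc(sse_g, n, 4)
    fits["gaussian"] = tuple(best.x)

    # step: optimal changepoint by exhaustive scan
    best_step = None
    for i in range(1, n):
        a, b = y[:i].mean(), y[i:].mean()
        sse = float(((y[:i] - a) ** 2).sum() + ((y[i:] - b) ** 2).sum())
        if best_step is None or sse < best_step[0]:
            best_step = (sse, i, a, b)
    sse_s, i_s, a_s, b_s = best_step
    scores["step"] = _aicc(sse_s, n, 3)
    t0_step = 0.5 * (t[i_s - 1] + t[i_s])
    fits["step"] = (a_s, t0_step, b_s)

    # exponential: A before t0, decay toward baseline after
    def e_model(p):
        A, t0, tau, b = p
        return np.where(t <= t0, A, b + (A - b) * np.exp(-(t - t0) / tau))

    p0 = np.array([pre, t0_step, max(4 * dt, span / 8), max(post, 0.0)])
    lb = np.array([0.0, t[0], dt / 4, 0.0])
    ub = np.array([2 * max(pre, y.max()), t[-1], 4 * span, pre])
    sol = least_squares(lambda p: e_model(p) - y, np.clip(p0, lb, ub),
                        bounds=(lb, ub), method="trf", max_nfev=400)
    scores["exponential"] = _aicc(2.0 * sol.cost, n, 4)
    fits["exponential"] = tuple(sol.x)

    order = min(scores, key=scores.get)
    if order == "gaussian" and not all(
            scores["gaussian"] < scores[m] - 1e-12 for m in ("step", "exponential")):
        order = "step"
    # identifiability at the sampling resolution: a decline faster than one
    # averaged block is indistinguishable from an instantaneous step
    if order == "exponential" and fits["exponential"][2] <= dt:
        order = "step"
    elif order == "gaussian" and fits["gaussian"][2] <= dt:
        order = "step"

    if order == "gaussian":
        A, t0, w, b = fits["gaussian"]
        t_half = t0 + w * math.sqrt(math.log(2.0))
        width = float(w)
    elif order == "step":
        A, t0, b = fits["step"]
        t_half, width = float(t0), float("nan")
    else:
        A, t0, tau, b = fits["exponential"]
        t_half, width = float(t0 + tau * math.log(2.0)), float("nan")
    return DeclineFit(model=order, t_half=t_half, width=width, scores=scores)


# ---------------------------------------------------------------------------
# membrane curvature / optical-section correction
# ---------------------------------------------------------------------------

def _fit_circle(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle through (y, x) points.

    Returns (y_center, x_center, radius).
    """
    A = np.column_stack([2 * y, 2 * x, np.ones_like(y)])
    b = y**2 + x**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    yc, xc = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + yc**2 + xc**2, 0.0))
    return float(yc), float(xc), float(r)


def membrane_bounds(xy_image: np.ndarray, params: ImagingParams,
                    y_rows: list[int] | None = None,
                    max_radius: float = 1e5) -> MembraneBounds:
    """Estimate the membrane position across the optical section.

    Fits sigmoid profiles at multiple y offsets of a ribbon-channel frame
    (composite where the ribbon bump overlaps the row), fits a circle to
    ``x_half(y)``, and applies the chord geometry
    ``x_extreme = x_mid - [R - sqrt(R^2 - (T/2)^2)]`` with ``T`` the optical
    section thickness, assuming the in-plane curvature also applies along z.
    Radii above ``max_radius`` are treated as flat.
    """
    img = np.asarray(xy_image, dtype=float)
    ny, nx = img.shape
    ps = params.pixel_size
    if y_rows is None:
        y_rows = list(range(2, ny - 2, max(1, ny // 24)))
    xs = (np.arange(nx) + 0.5) * ps
    pts_y, pts_x = [], []
    for r in y_rows:
        prof = img[r]
        try:
            fit = fit_profile(xs, prof, model="composite")
            if fit.model == "gaussian_only":      # no transition on this row
                continue
        except Exception:
            continue
        # membrane position is read from rows the ribbon does not dominate
        if np.isfinite(fit.a) and fit.c > 0 and fit.a > 0.5 * fit.c:
            continue
        if fit.converged and np.isfinite(fit.x_half):
            pts_y.append((r + 0.5) * ps)
            pts_x.append(fit.x_half)
    if len(pts_y) < 5:
        raise RuntimeError("fewer than 5 usable membrane rows for curvature fit")
    yv, xv = np.asarray(pts_y), np.asarray(pts_x)

    # flat-membrane shortcut: negligible structure in x_half(y)
    if np.ptp(xv) < 0.05 * ps:
        x_mid = float(np.mean(xv))
        return MembraneBounds(x_mid=x_mid, x_extreme=x_mid, radius=math.inf)

    yc, xc, radius = _fit_circle(yv, xv)
    if not np.isfinite(radius) or radius > max_radius:
        x_mid = float(np.mean(xv))
        return MembraneBounds(x_mid=x_mid, x_extreme=x_mid, radius=math.inf)
    x_mid = xc + radius            # apex of the arc (membrane bows outward)
    half_t = params.optical_section_thickness / 2.0
    if half_t >= radius:
        raise ValueError("membrane radius must exceed half the optical "
                         "section thickness")
    x_extreme = x_mid - (radius - math.sqrt(radius**2 - half_t**2))
    return MembraneBounds(x_mid=float(x_mid), x_extreme=float(x_extreme),
                          radius=radius)


# ---------------------------------------------------------------------------
# event histograms
# ---------------------------------------------------------------------------

@dataclass
class HistogramResult:
    """Histogram of event x-positions relative to the ribbon center."""

    counts: np.ndarray
    edges: np.ndarray
    n_beyond_mid: int = 0
    n_beyond_extreme: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def event_position_histogram(events: list[VesicleEvent], bin_width: float,
                             bounds: MembraneBounds | None = None,
                             ribbon_x: float = 0.0) -> HistogramResult:
    """Bin event loci (dx, nm) at ``bin_width``; total count is preserved.

    With membrane ``bounds`` given (same frame as ``ribbon_x``), also counts
    events beyond the focal-plane membrane and beyond the curvature-corrected
    extreme membrane position.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dx = np.asarray([e.locus.dx for e in events], dtype=float)
    if dx.size == 0:
        return HistogramResult(counts=np.zeros(0, dtype=int),
                               edges=np.zeros(1))
    lo = math.floor(dx.min() / bin_width) * bin_width
    hi = (math.floor(dx.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(dx, bins=edges)
    nb_mid = nb_ext = 0
    if bounds is not None:
        mid_rel = bounds.x_mid - ribbon_x
        ext_rel = bounds.x_extreme - ribbon_x
        nb_mid = int((dx > mid_rel).sum())
        nb_ext = int((dx > ext_rel).sum())
    return HistogramResult(counts=counts, edges=edges,
                           n_beyond_mid=nb_mid, n_beyond_extreme=nb_ext)
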