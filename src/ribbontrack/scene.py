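"""Synthetic ground-truth scenes and confocal renderers.

The generator emulates the two imaging paradigms used to follow single
synaptic vesicles at the ribbon-type active zone of retinal bipolar cells:

* **x-y repeat trials** — short bursts of two-channel frames (ribbon/landmark
  channel plus a sparse single-emitter channel) bracketing a brief
  depolarizing stimulus, repeated at long intervals;
* **x-t line scans** — a short line perpendicular to the plasma membrane,
  scanned every ~1.4 ms with channel alternation, during sustained
  depolarization.

Scenes are specified in physical units (nm, s) with the standard orientation
that the extracellular space is to the right (+x).  Each vesicle is a
:class:`Trajectory` whose base path is piecewise linear and exact in time,
with an AR(1) tether-wobble jitter superimposed; renderers sample emitters
through a Gaussian point-spread function and apply Poisson shot noise on
``(signal + background) * photon_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GeometryError

__all__ = [
    "ImagingParams",
    "Trajectory",
    "GroundTruthScene",
    "BehaviorConfig",
    "ScanLine",
    "LineScanImage",
    "make_trajectory",
    "make_scene",
    "render_xy_stack",
    "render_line_scan",
    "bead_image",
    "membrane_x_at",
]

#: correlation time (s) of the tether-wobble jitter; slow relative to the
#: frame period so the wobble survives 4-10-frame averaging, fast relative to
#: the 18-s repeat interval so repeats decorrelate.
JITTER_TAU_S = 5.0

#: ratio of mean away-from-membrane to toward-membrane displacement magnitude
#: used when drawing stimulus-evoked shifts (away moves are smaller).
AWAY_TOWARD_RATIO = 59.0 / 89.0

#: SD (nm) of the along-membrane (y) component of stimulus-evoked shifts.
SHIFT_DDY_SD = 40.0

#: logistic slope (nm) that approximates a PSF-blurred step of SD sigma.
_LOGISTIC_D = math.sqrt(3.0) / math.pi


def _logistic_d_for(psf_sigma: float) -> float:
    return _LOGISTIC_D * psf_sigma


@dataclass(frozen=True)
class ImagingParams:
    """Physical acquisition parameters shared by the renderers and fitters.

    Lengths are nm; ``line_period`` is in ms and ``frame_period`` in s,
    following the conventions of the respective paradigms.
    """

    pixel_size: float = 40.0
    psf_sigma: float = 110.0
    line_period: float = 1.4
    frame_period: float = 0.5
    channel_scheme: str = "alternate_lines"
    photon_scale: float = 3.0
    background_intra: float = 2.0
    background_extra: float = 0.2
    optical_section_thickness: float = 600.0
    read_noise_sd: float = 0.0
    #: cytoplasmic fill in the emitter channel, as a fraction of the
    #: ribbon-channel background levels (the vesicle label is sparse).
    emitter_background_scale: float = 0.25

    def __post_init__(self) -> None:
        for name in ("pixel_size", "psf_sigma", "line_period", "frame_period",
                     "photon_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("background_intra", "background_extra", "read_noise_sd",
                     "optical_section_thickness", "emitter_background_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.channel_scheme not in ("alternate_lines", "alternate_frames",
                                       "simultaneous"):
            raise ConfigurationError(
                f"channel_scheme={self.channel_scheme!r} is not recognised")

    @property
    def line_period_s(self) -> float:
        return self.line_period * 1e-3


TRAJECTORY_KINDS = (
    "stable",
    "displaced",
    "departing",
    "bleaching",
    "appearing_then_departing",
    "fusion_flash",
)


@dataclass
class Trajectory:
    """One emitter: a piecewise-linear base path plus AR(1) jitter.

    ``breakpoints_t``/``breakpoints_xy`` define the exact base path; the
    jitter realisation is stored on the scene time grid and interpolated.
    ``positions`` is the sampled ground-truth path on the grid.
    """

    kind: str
    amplitude: float
    t_on: float
    t_off: float
    breakpoints_t: np.ndarray
    breakpoints_xy: np.ndarray           # (k, 2) nm
    times: np.ndarray                    # scene time grid (s)
    jitter: np.ndarray                   # (n, 2) nm, AR(1) realisation
    departure_speed: float = 0.0         # nm/ms, |dy/dt| after t_off
    shift: tuple[float, float] = (0.0, 0.0)   # stimulus-evoked (ddx, ddy)
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TRAJECTORY_KINDS:
            raise ConfigurationError(f"kind={self.kind!r} is not a trajectory kind")
        if not self.t_on < self.t_off:
            raise ConfigurationError("t_on must precede t_off")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")

    # -- exact path -------------------------------------------------------
    def base_position_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = np.interp(t, self.breakpoints_t, self.breakpoints_xy[:, 0])
        y = np.interp(t, self.breakpoints_t, self.breakpoints_xy[:, 1])
        return np.column_stack([x, y])

    def position_at(self, t) -> np.ndarray:
        """Ground-truth position (nm) at time(s) ``t``: base path + jitter."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pos = self.base_position_at(t)
        if self.jitter.size:
            pos[:, 0] += np.interp(t, self.times, self.jitter[:, 0])
            pos[:, 1] += np.interp(t, self.times, self.jitter[:, 1])
        return pos

    def amplitude_at(self, t) -> np.ndarray:
        """Intrinsic emitter brightness at time(s) ``t``.

        Departing kinds keep their brightness after ``t_off`` — the rendered
        decline arises from the emitter physically leaving the sampled
        region — whereas ``bleaching`` switches off abruptly.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        on = t >= self.t_on
        if self.kind == "bleaching":
            on &= t <= self.t_off
        return np.where(on, self.amplitude, 0.0)

    @property
    def positions(self) -> np.ndarray:
        """Sampled ground-truth path (n, 2) on the scene time grid."""
        return self.position_at(self.times)


@dataclass
class GroundTruthScene:
    """Membrane geometry, ribbon locus and per-vesicle trajectories.

    Coordinates are absolute nm with the extracellular side at +x; the
    membrane is a circular arc of radius ``membrane_radius`` (``inf`` for
    flat) whose apex sits at ``(membrane_x0, membrane_apex_y)``.
    """

    membrane_x0: float = 800.0
    membrane_radius: float = math.inf
    ribbon_center: tuple[float, float] = (650.0, 1280.0)
    ribbon_extent: tuple[float, float] = (60.0, 120.0)
    ribbon_amplitude: float = 8.0
    membrane_apex_y: float | None = None
    stimulus_time: float = 4.0
    duration: float = 10.0
    dt: float = 0.01
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.membrane_apex_y is None:
            self.membrane_apex_y = self.ribbon_center[1]
        if not self.ribbon_center[0] < self.membrane_x0:
            raise ConfigurationError(
                "ribbon_center.x must be intracellular (less than membrane_x0)")
        if self.membrane_radius <= 0:
            raise ConfigurationError("membrane_radius must be positive")
        if self.ribbon_extent[0] <= 0 or self.ribbon_extent[1] <= 0:
            raise ConfigurationError("ribbon_extent components must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigurationError("duration and dt must be positive")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    def membrane_x_at(self, y) -> np.ndarray:
        return membrane_x_at(self.membrane_x0, self.membrane_radius,
                             self.membrane_apex_y, y)

    @property
    def events(self) -> list[dict]:
        """Ground-truth events of every trajectory, time-ordered."""
        ev = [e for tr in self.trajectories for e in tr.events]
        return sorted(ev, key=lambda e: e["t"])


def membrane_x_at(x0: float, radius: float, apex_y: float, y) -> np.ndarray:
    """Membrane x-position (nm) at height(s) ``y`` for a circular-arc membrane.

    The arc bows outward at the apex and retreats intracellularly (toward
    smaller x) away from it; a flat membrane (infinite radius) is constant.
    """
    y = np.asarray(y, dtype=float)
    if math.isinf(radius):
        return np.full_like(y, x0, dtype=float)
    dy = np.clip(np.abs(y - apex_y), 0.0, radius)
    return x0 - (radius - np.sqrt(radius**2 - dy**2))


@dataclass(frozen=True)
class BehaviorConfig:
    """Stimulus-conditioned vesicle behavior drawn by :func:`make_scene`.

    Effect sizes default to the reported phenomenology: a ~33-nm mean
    stimulus-evoked shift toward the membrane with ~70 % of shifts positive,
    disappearances membrane-proximal and appearances membrane-distal.
    """

    n_vesicles: int = 1
    p_disappear_proximal: float = 0.0
    p_appear_distal: float = 0.0
    p_fusion: float = 0.0
    mean_shift_x: float = 33.0
    frac_positive_ddx: float = 0.70
    jitter_sd: tuple[float, float] = (10.0, 7.0)
    event_spread: float = 120.0
    departure_speed: float = 1.5     # nm/ms
    amplitude: float = 5.0

    def __post_init__(self) -> None:
        if self.n_vesicles < 0:
            raise ConfigurationError("n_vesicles must be non-negative")
        for name in ("p_disappear_proximal", "p_appear_distal", "p_fusion",
                     "frac_positive_ddx"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.p_disappear_proximal + self.p_appear_distal + self.p_fusion > 1.0:
            raise ConfigurationError("kind probabilities sum to more than 1")
        if min(self.jitter_sd) < 0 or max(self.jitter_sd) > 15.0:
            raise ConfigurationError(
                "jitter_sd components must lie in [0, 15] nm (stable tethering)")
        if self.event_spread <= 0:
            raise ConfigurationError("event_spread must be positive")
        if self.departure_speed <= 0:
            raise ConfigurationError("departure_speed must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def _ar1_jitter(times: np.ndarray, sd: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) wobble with correlation time JITTER_TAU_S."""
    n = times.size
    out = np.zeros((n, 2))
    if max(sd) == 0 or n == 0:
        return out
    dt = np.diff(times, prepend=times[0] - (times[1] - times[0] if n > 1 else 1.0))
    rho = np.exp(-dt / JITTER_TAU_S)
    eps = rng.standard_normal((n, 2))
    for axis in range(2):
        s = sd[axis]
        x = eps[0, axis] * s
        out[0, axis] = x
        for i in range(1, n):
            x = rho[i] * x + math.sqrt(max(0.0, 1 - rho[i] ** 2)) * s * eps[i, axis]
            out[i, axis] = x
    return out


def make_trajectory(kind: str, base_xy: tuple[float, float], *, times: np.ndarray,
                    amplitude: float, t_on: float, t_off: float,
                    jitter_sd: tuple[float, float] = (0.0, 0.0),
                    departure_speed: float = 1.5,
                    shift: tuple[float, float] = (0.0, 0.0),
                    move_to_x: float | None = None,
                    stimulus_time: float = 0.0,
                    rng: np.random.Generator | None = None) -> Trajectory:
    """Construct a trajectory of the given kind with an exact base path.

    ``shift`` applies at ``stimulus_time`` (displaced kind); ``move_to_x``
    gives a pre-departure drift target in x (distal vesicles approaching the
    membrane before loss); departures move along -y at ``departure_speed``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    x0, y0 = float(base_xy[0]), float(base_xy[1])
    eps = 1e-9
    bp_t = [times[0] - 1.0]
    bp_xy = [(x0, y0)]

    def add(t, x, y):
        bp_t.append(t)
        bp_xy.append((x, y))

    if kind in ("stable", "bleaching", "fusion_flash"):
        add(t_off + 1e6, x0, y0)
    elif kind == "displaced":
        add(stimulus_time, x0, y0)
        add(stimulus_time + 0.05, x0 + shift[0], y0 + shift[1])
        add(t_off + 1e6, x0 + shift[0], y0 + shift[1])
    elif kind in ("departing", "appearing_then_departing"):
        x_pre = x0
        t_move0 = max(t_on, stimulus_time)
        if move_to_x is not None and t_off > t_move0 + eps:
            add(t_move0, x0, y0)
            add(t_off, move_to_x, y0)
            x_pre = move_to_x
        else:
            add(t_off, x0, y0)
        # constant-velocity departure perpendicular to the scan line (-y)
        v = departure_speed * 1e3   # nm/s
        t_far = t_off + 1e4
        add(t_far, x_pre, y0 - v * (t_far - t_off))
    else:
        raise ConfigurationError(f"kind={kind!r} is not a trajectory kind")

    traj = Trajectory(
        kind=kind, amplitude=amplitude, t_on=t_on, t_off=t_off,
        breakpoints_t=np.asarray(bp_t), breakpoints_xy=np.asarray(bp_xy),
        times=times, jitter=_ar1_jitter(times, jitter_sd, rng),
        departure_speed=departure_speed, shift=tuple(shift),
    )

    # ground-truth event bookkeeping
    def _locus(t):
        p = traj.base_position_at(t)[0]
        return {"x": float(p[0]), "y": float(p[1])}

    if kind == "fusion_flash":
        traj.events.append({"kind": "fusion", "t": t_on, **_locus(t_on)})
    elif kind == "appearing_then_departing" or (kind != "stable" and t_on > times[0]):
        traj.events.append({"kind": "appearance", "t": t_on, **_locus(t_on)})
    if kind in ("departing", "appearing_then_departing", "bleaching",
                "fusion_flash") and t_off <= times[-1]:
        traj.events.append({"kind": "disappearance", "t": t_off, **_locus(t_off)})
    return traj


def make_scene(template: GroundTruthScene, behavior: BehaviorConfig,
               seed: int, kinds: list[str] | None = None,
               paradigm: str = "line_scan") -> GroundTruthScene:
    """Draw a fully specified scene from the behavior distributions.

    ``kinds`` overrides the stochastic kind assignment (one entry per
    vesicle).  ``paradigm`` controls event-time conventions: ``"xy"`` locks
    appearances/disappearances to the stimulus so that pre/post averaged
    epochs see a clean gain or loss; ``"line_scan"`` spreads event times
    through the sustained-depolarization window.  Deterministic given seed.
    """
    if paradigm not in ("line_scan", "xy"):
        raise ConfigurationError(f"paradigm={paradigm!r} is not recognised")
    rng = np.random.default_rng(seed)
    scene = replace(template, trajectories=[])
    times = scene.times
    t_stim = scene.stimulus_time
    delta = scene.membrane_x0 - scene.ribbon_center[0]
    rx, ry = scene.ribbon_center
    ey = scene.ribbon_extent[1]

    if kinds is None:
        kinds = []
        for _ in range(behavior.n_vesicles):
            u = rng.random()
            if u < behavior.p_disappear_proximal:
                kinds.append("departing")
            elif u < behavior.p_disappear_proximal + behavior.p_appear_distal:
                kinds.append("appearing_then_departing")
            elif (u < behavior.p_disappear_proximal + behavior.p_appear_distal
                    + behavior.p_fusion):
                kinds.append("fusion_flash")
            elif behavior.mean_shift_x != 0 or behavior.frac_positive_ddx != 0.5:
                kinds.append("displaced")
            else:
                kinds.append("stable")
    elif len(kinds) != behavior.n_vesicles:
        raise ConfigurationError("kinds must have one entry per vesicle")

    # Stimulus-evoked shifts: gamma(shape 3) magnitudes whose mixture mean
    # matches mean_shift_x given the positive fraction.  The toward/away
    # composition is fixed (round(f * n) positive, shuffled), emulating a
    # stated composition of the vector population rather than an iid coin
    # flip per vesicle.
    f = behavior.frac_positive_ddx
    denom = f - (1.0 - f) * AWAY_TOWARD_RATIO
    mean_pos = behavior.mean_shift_x / denom if abs(denom) > 1e-9 else 0.0
    mean_neg = mean_pos * AWAY_TOWARD_RATIO
    n_displaced = sum(k == "displaced" for k in kinds)
    n_pos = int(round(f * n_displaced))
    signs = [True] * n_pos + [False] * (n_displaced - n_pos)
    rng.shuffle(signs)
    signs = iter(signs)

    for kind in kinds:
        y_base = ry + rng.normal(0.0, ey)
        t_on, t_off = times[0] - 1.0, times[-1] + 1e4
        shift, move_to = (0.0, 0.0), None

        speed = behavior.departure_speed
        if kind == "departing":
            x_base = rx + delta * rng.uniform(0.30, 0.85)   # proximal
            if paradigm == "xy":
                # loss occurs between the pre and post epochs; the label
                # disperses fast against the frame interval
                t_off = t_stim + 0.01
                speed = max(speed, 50.0)
            else:
                t_off = t_stim + rng.uniform(
                    0.3, max(0.4, scene.duration - t_stim - 1.5))
        elif kind == "appearing_then_departing":
            x_base = rx - delta * rng.uniform(0.40, 1.60)   # distal
            if paradigm == "xy":
                t_on, t_off = t_stim + 0.01, times[-1] + 1e4
            else:
                t_on = t_stim + rng.uniform(0.1, 0.6)
                t_off = t_on + rng.uniform(0.8, max(1.0, scene.duration - t_on - 1.2))
                move_to = rx + delta * rng.uniform(0.1, 0.5)
        elif kind == "bleaching":
            x_base = rx + rng.normal(0.0, 0.5 * delta)
            t_off = t_stim + rng.uniform(0.3, max(0.4, scene.duration - t_stim - 1.0))
        elif kind == "fusion_flash":
            x_base = float(np.clip(rx + rng.normal(0.0, behavior.event_spread),
                                   rx - 3.0 * behavior.event_spread,
                                   scene.membrane_x0 - 10.0))
            t_on = t_stim + rng.uniform(0.05, max(0.1, scene.duration - t_stim - 1.5))
            t_off = t_on + rng.uniform(0.4, 1.0)
        else:  # stable / displaced
            x_base = float(np.clip(rx + rng.normal(0.0, 0.45 * delta),
                                   rx - 1.6 * delta, rx + 0.85 * delta))
            if kind == "displaced":
                toward = next(signs)
                mag = rng.gamma(3.0, (mean_pos if toward else mean_neg) / 3.0)
                shift = ((mag if toward else -mag),
                         rng.normal(0.0, SHIFT_DDY_SD))

        scene.trajectories.append(make_trajectory(
            kind, (x_base, y_base), times=times, amplitude=behavior.amplitude,
            t_on=t_on, t_off=t_off, jitter_sd=behavior.jitter_sd,
            departure_speed=speed, shift=shift,
            move_to_x=move_to, stimulus_time=t_stim, rng=rng))
    return scene


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def _pixel_centers(n: int, pixel_size: float) -> np.ndarray:
    # pixel i spans [i*ps, (i+1)*ps) nm with center (i+0.5)*ps
    return (np.arange(n) + 0.5) * pixel_size


def _apply_noise(expected: np.ndarray, params: ImagingParams,
                 rng: np.random.Generator) -> np.ndarray:
    lam = expected * params.photon_scale
    out = rng.poisson(lam).astype(float)
    if params.read_noise_sd > 0:
        out += rng.normal(0.0, params.read_noise_sd, size=out.shape)
    return out


def _ribbon_channel_2d(scene: GroundTruthScene, params: ImagingParams,
                       xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    """Expected ribbon-channel image: cytoplasmic fill + ribbon blob."""
    xm = scene.membrane_x_at(yg)[:, None]
    d = _logistic_d_for(params.psf_sigma)
    occ = 1.0 / (1.0 + np.exp(np.clip((xg[None, :] - xm) / d, -500, 500)))
    img = params.background_extra + (params.background_intra
                                     - params.background_extra) * occ
    sx = math.hypot(params.psf_sigma, scene.ribbon_extent[0])
    sy = math.hypot(params.psf_sigma, scene.ribbon_extent[1])
    rx, ry = scene.ribbon_center
    img = img + scene.ribbon_amplitude * np.exp(
        -((xg[None, :] - rx) ** 2) / (2 * sx**2)
        - ((yg[:, None] - ry) ** 2) / (2 * sy**2))
    return img


def render_xy_stack(scene: GroundTruthScene, params: ImagingParams,
                    n_frames: int, seed: int, shape: tuple[int, int] = (64, 64),
                    t_start: float = 0.0, noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render a two-channel x-y time-lapse stack.

    Returns ``(stack, times)`` with ``stack`` of shape
    ``(n_frames, 2, ny, nx)`` — channel 0 the ribbon/landmark channel,
    channel 1 the emitter channel — in detected photons (floats).
    """
    ny, nx = shape
    xg = _pixel_centers(nx, params.pixel_size)
    yg = _pixel_centers(ny, params.pixel_size)
    rx, ry = scene.ribbon_center
    if not (xg[0] <= rx <= xg[-1] and yg[0] <= ry <= yg[-1]):
        raise GeometryError("ribbon center lies outside the field of view")
    if not xg[0] <= scene.membrane_x0 <= xg[-1]:
        raise GeometryError("membrane lies outside the field of view")
    for tr in scene.trajectories:
        bx, by = tr.base_position_at(max(tr.t_on, t_start))[0]
        if not (xg[0] - params.psf_sigma <= bx <= xg[-1] + params.psf_sigma
                and yg[0] - params.psf_sigma <= by <= yg[-1] + params.psf_sigma):
            raise GeometryError("a trajectory starts outside the field of view")

    rng = np.random.default_rng(seed)
    times = t_start + np.arange(n_frames) * params.frame_period
    ribbon = _ribbon_channel_2d(scene, params, xg, yg)
    bg_em = ( params.emitter_background_scale
              * (_ribbon_channel_2d(replace(scene, ribbon_amplitude=0.0),
                                    params, xg, yg)) )
    s2 = 2.0 * params.psf_sigma**2

    stack = np.empty((n_frames, 2, ny, nx))
    for k, t in enumerate(times):
        em = bg_em.copy()
        for tr in scene.trajectories:
            a = float(tr.amplitude_at(t)[0])
            if a <= 0:
                continue
            px, py = tr.position_at(t)[0]
            em += a * np.exp(-((xg[None, :] - px) ** 2
                               + (yg[:, None] - py) ** 2) / s2)
        if noise:
            stack[k, 0] = _apply_noise(ribbon, params, rng)
            stack[k, 1] = _apply_noise(em, params, rng)
        else:
            stack[k, 0] = ribbon * params.photon_scale
            stack[k, 1] = em * params.photon_scale
    return stack, times


@dataclass(frozen=True)
class ScanLine:
    """Geometry of an x-t scan line: fixed y, a 1-D pixel range in x (nm)."""

    y_offset: float
    x_min: float = 0.0
    n_pixels: int = 64


@dataclass
class LineScanImage:
    """An x-t image: ``data[(line), x]`` with per-line times and channels."""

    data: np.ndarray           # (n_lines, n_pixels) or (n_lines, 2, n_pixels)
    times: np.ndarray          # (n_lines,) s
    channels: np.ndarray | None   # (n_lines,) 0=ribbon, 1=emitter; None if simultaneous
    scan_line: ScanLine
    pixel_size: float


def render_line_scan(scene: GroundTruthScene, params: ImagingParams,
                     scan_line: ScanLine, n_lines: int, seed: int,
                     t_start: float = 0.0, noise: bool = True) -> LineScanImage:
    """Render an x-t line-scan image across the membrane.

    With ``channel_scheme="alternate_lines"`` successive lines alternate
    ribbon/emitter channels (data ``(n_lines, n_pixels)``); with
    ``"simultaneous"`` both channels are sampled every line
    (data ``(n_lines, 2, n_pixels)``).
    """
    if params.channel_scheme == "alternate_frames":
        raise ConfigurationError(
            "alternate_frames is a frame-paradigm scheme; line scans use "
            "alternate_lines or simultaneous")
    xg = scan_line.x_min + _pixel_centers(scan_line.n_pixels, params.pixel_size)
    y0 = scan_line.y_offset
    xm = float(scene.membrane_x_at(np.asarray([y0]))[0])
    if not (xg[0] < xm < xg[-1]):
        raise GeometryError(
            "scan line does not cross the membrane (must span intra- and "
            "extracellular space)")

    rng = np.random.default_rng(seed)
    lp = params.line_period_s
    times = t_start + np.arange(n_lines) * lp
    d = _logistic_d_for(params.psf_sigma)
    fill = (params.background_extra + (params.background_intra
            - params.background_extra) / (1.0 + np.exp((xg - xm) / d)))
    sx = math.hypot(params.psf_sigma, scene.ribbon_extent[0])
    sy = math.hypot(params.psf_sigma, scene.ribbon_extent[1])
    rx, ry = scene.ribbon_center
    ribbon_line = fill + (scene.ribbon_amplitude
                          * math.exp(-((y0 - ry) ** 2) / (2 * sy**2))
                          * np.exp(-((xg - rx) ** 2) / (2 * sx**2)))
    em_bg = params.emitter_background_scale * fill
    s2 = 2.0 * params.psf_sigma**2

    def emitter_line(t: float) -> np.ndarray:
        line = em_bg.copy()
        for tr in scene.trajectories:
            a = float(tr.amplitude_at(t)[0])
            if a <= 0:
                continue
            px, py = tr.position_at(t)[0]
            a_eff = a * math.exp(-((py - y0) ** 2) / s2)
            if a_eff < 1e-12:
                continue
            line += a_eff * np.exp(-((xg - px) ** 2) / s2)
        return line

    if params.channel_scheme == "simultaneous":
        data = np.empty((n_lines, 2, scan_line.n_pixels))
        for i, t in enumerate(times):
            exp_r, exp_e = ribbon_line, emitter_line(t)
            if noise:
                data[i, 0] = _apply_noise(exp_r, params, rng)
                data[i, 1] = _apply_noise(exp_e, params, rng)
            else:
                data[i, 0] = exp_r * params.photon_scale
                data[i, 1] = exp_e * params.photon_scale
        channels = None
    else:
        data = np.empty((n_lines, scan_line.n_pixels))
        channels = (np.arange(n_lines) % 2).astype(int)
        for i, t in enumerate(times):
            expected = ribbon_line if channels[i] == 0 else emitter_line(t)
            data[i] = (_apply_noise(expected, params, rng) if noise
                       else expected * params.photon_scale)
    return LineScanImage(data=data, times=times, channels=channels,
                         scan_line=scan_line, pixel_size=params.pixel_size)


def bead_image(params: ImagingParams, bead_diameter: float, seed: int,
               shape: tuple[int, int] = (32, 32), amplitude: float = 50.0,
               center: tuple[float, float] | None = None,
               noise: bool = True, oversample: int = 8) -> np.ndarray:
    """Render a sub-resolution fluorescent bead: uniform disc ⊗ Gaussian PSF.

    For diameters well below the PSF width the image is an effective sample
    of the point-spread function, suitable for PSF calibration.
    """
    if bead_diameter < 0:
        raise ConfigurationError("bead_diameter must be non-negative")
    ny, nx = shape
    if center is None:
        center = (nx * params.pixel_size / 2.0, ny * params.pixel_size / 2.0)
    cx, cy = center
    s2 = 2.0 * params.psf_sigma**2
    if bead_diameter == 0:
        xg = _pixel_centers(nx, params.pixel_size)
        yg = _pixel_centers(ny, params.pixel_size)
        img = amplitude * np.exp(-((xg[None, :] - cx) ** 2
                                   + (yg[:, None] - cy) ** 2) / s2)
    else:
        ps = params.pixel_size / oversample
        xf = (np.arange(nx * oversample) + 0.5) * ps
        yf = (np.arange(ny * oversample) + 0.5) * ps
        r = bead_diameter / 2.0
        disc = (((xf[None, :] - cx) ** 2 + (yf[:, None] - cy) ** 2)
                <= r**2).astype(float)
        blurred = ndimage.gaussian_filter(disc, sigma=params.psf_sigma / ps,
                                          mode="constant")
        img = blurred.reshape(ny, oversample, nx, oversample).mean(axis=(1, 3))
        peak = img.max()
        if peak > 0:
            img = img * (amplitude / peak)
    if noise:
        rng = np.random.default_rng(seed)
        return _apply_noise(img + params.background_extra, params, rng)
    return (img + params.background_extra) * params.photon_scale
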