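"""Sub-pixel localization models for membrane, ribbon and single emitters.

Two model families, presented in the Model -> ``fit()`` -> Results style:

* :class:`ProfileModel` — a 1-D intensity profile along x (nm) fitted with a
  composite model ``f(x) = s(x) + g(x)``, where

  .. math::

     s(x) = b - \\frac{c}{1 + e^{(x_{1/2} - x)/d}}, \\qquad
     g(x) = a\\, e^{-(x - x_0)^2 / w^2}

  The sigmoid describes the fall from intracellular background ``b`` to the
  extracellular level ``b - c`` across the plasma membrane at ``x_{1/2}``
  with slope factor ``d``; the Gaussian describes the emitter (ribbon,
  vesicle label, or fusion reporter) peaking at ``x_0`` with width
  ``w = sqrt(2) * SD``.  ``x_{1/2}`` is taken as the membrane position and
  ``x_0`` as the emitter position; the remaining parameters are tightly
  constrained by the data and the measured PSF, leaving ``x_{1/2}`` and
  ``x_0`` as the effective free parameters.

* :class:`SpotModel2D` — an elliptical 2-D Gaussian plus constant offset
  fitted to an x-y spot, used for ribbon and vesicle localization in frame
  averages and for PSF calibration against a sub-resolution bead.

Fits are bounded nonlinear least squares (uniform weighting) with
multi-start over the emitter-position initialization; fitted positions are
reported in nm and can never leave the fitted window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import CalibrationError, ConfigurationError, NoSpotError

__all__ = [
    "PsfCalibration",
    "ProfileModel",
    "ProfileFitResults",
    "SpotModel2D",
    "SpotFit2DResults",
    "average_frames",
    "average_lines",
    "calibrate_psf",
    "fit_profile",
    "fit_spot_2d",
    "sigmoid_component",
    "gaussian_component",
    "composite_profile",
]

PROFILE_MODELS = ("composite", "sigmoid_only", "gaussian_only")

#: fractional band around the PSF-derived Gaussian width w = sqrt(2)*sigma
W_BAND = 0.30
#: convergence tolerance on the relative residual change
FIT_TOL = 1e-8
MAX_NFEV = 2000


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------

def sigmoid_component(x, b, c, d, x_half):
    """Logistic intra->extracellular transition; ``b`` inside, ``b - c`` outside."""
    z = np.clip((np.asarray(x, dtype=float) - x_half) / d, -500.0, 500.0)
    return b - c / (1.0 + np.exp(-z))


def gaussian_component(x, a, w, x_0):
    """Emitter profile ``a * exp(-(x - x_0)^2 / w^2)`` with ``w = sqrt(2)*SD``."""
    x = np.asarray(x, dtype=float)
    return a * np.exp(-((x - x_0) ** 2) / (w**2))


def composite_profile(x, a, b, c, d, w, x_0, x_half):
    return sigmoid_component(x, b, c, d, x_half) + gaussian_component(x, a, w, x_0)


def _logistic(x, d, x_half):
    z = np.clip((np.asarray(x, dtype=float) - x_half) / d, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


def _sigmoid_jac_cols(x, c, d, x_half):
    """Partials of s(x) w.r.t. (b, c, d, x_half)."""
    L = _logistic(x, d, x_half)
    Lp = L * (1.0 - L)
    z = (np.asarray(x, dtype=float) - x_half) / d
    return np.ones_like(L), -L, c * Lp * z / d, c * Lp / d


def _gaussian_jac_cols(x, a, w, x_0):
    """Partials of g(x) w.r.t. (a, w, x_0)."""
    u = (np.asarray(x, dtype=float) - x_0) / w
    g = np.exp(-(u**2))
    return g, a * g * 2.0 * u**2 / w, a * g * 2.0 * u / w


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsfCalibration:
    """Point-spread-function width (Gaussian SD, nm) and its provenance."""

    sigma: float
    source: str = "configured"
    anisotropy_warning: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("psf sigma must be positive")

    @property
    def w(self) -> float:
        """Profile-model Gaussian width, ``w = sqrt(2) * sigma``."""
        return math.sqrt(2.0) * self.sigma


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def average_frames(stack: np.ndarray, window: int) -> np.ndarray:
    """Mean over non-overlapping blocks of ``window`` frames (leading axis).

    ``window=1`` is the identity; trailing frames that do not fill a block
    are dropped.  Image dimensions are unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if not 1 <= window <= n:
        raise ValueError(f"window={window} must lie in [1, {n}]")
    nb = n // window
    return stack[: nb * window].reshape((nb, window) + stack.shape[1:]).mean(axis=1)


def average_lines(xt: np.ndarray, n_lines: int, n_x_pixels: int = 1,
                  times: np.ndarray | None = None):
    """Block-average an x-t image over ``n_lines`` (time) and ``n_x_pixels`` (x).

    Returns ``(averaged, block_times)`` where each block time is the mean of
    its member line times (``None`` if ``times`` is not given).  Trailing
    partial blocks are dropped.
    """
    xt = np.asarray(xt, dtype=float)
    if xt.ndim != 2:
        raise ValueError("xt must be a 2-D (lines, x) image")
    nt, nx = xt.shape
    if not 1 <= n_lines <= nt:
        raise ValueError(f"n_lines={n_lines} must lie in [1, {nt}]")
    if not 1 <= n_x_pixels <= nx:
        raise ValueError(f"n_x_pixels={n_x_pixels} must lie in [1, {nx}]")
    bt, bx = nt // n_lines, nx // n_x_pixels
    out = (xt[: bt * n_lines, : bx * n_x_pixels]
           .reshape(bt, n_lines, bx, n_x_pixels).mean(axis=(1, 3)))
    block_times = None
    if times is not None:
        times = np.asarray(times, dtype=float)
        block_times = times[: bt * n_lines].reshape(bt, n_lines).mean(axis=1)
    return out, block_times


# ---------------------------------------------------------------------------
# 1-D profile model
# ---------------------------------------------------------------------------

@dataclass
class ProfileFitResults:
    """Estimates from a 1-D profile fit.

    ``x_0`` is the emitter/ribbon peak and ``x_half`` the membrane position
    (both nm); ``a`` the Gaussian amplitude, ``b`` the intracellular
    background, ``c`` the sigmoid drop to the extracellular level, ``d`` the
    sigmoid slope factor and ``w = sqrt(2)*SD`` the Gaussian width.
    Parameters absent from the fitted model are NaN.  ``orientation_flag``
    marks composite fits with the emitter on the extracellular side
    (``x_0 >= x_half``), which are reported but flagged rather than dropped.
    """

    model: str
    a: float
    b: float
    c: float
    d: float
    w: float
    x_0: float
    x_half: float
    rms_residual: float
    converged: bool
    nobs: int
    bse: dict
    fallback: bool = False
    orientation_flag: bool = False

    @property
    def params(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d,
                "w": self.w, "x_0": self.x_0, "x_half": self.x_half}

    def predict(self, x) -> np.ndarray:
        if self.model == "sigmoid_only":
            return sigmoid_component(x, self.b, self.c, self.d, self.x_half)
        if self.model == "gaussian_only":
            return self.b + gaussian_component(x, self.a, self.w, self.x_0)
        return composite_profile(x, self.a, self.b, self.c, self.d, self.w,
                                 self.x_0, self.x_half)

    def summary(self) -> str:
        lines = [
            "Profile fit results",
            "=" * 46,
            f"model:        {self.model}{' (fallback)' if self.fallback else ''}",
            f"observations: {self.nobs}",
            f"converged:    {self.converged}",
            f"rms residual: {self.rms_residual:.4g}",
            "-" * 46,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for k, v in self.params.items():
            if np.isnan(v):
                continue
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:>8} {v:12.4f} {se:12.4f}")
        if self.orientation_flag:
            lines.append("warning: emitter fitted extracellular of the membrane")
        return "\n".join(lines)


class ProfileModel:
    """1-D intensity profile model over x (nm).

    Parameters
    ----------
    x : array
        Sample positions in nm (pixel centers), strictly increasing.
    y : array
        Intensities at ``x``.
    kind : {"composite", "sigmoid_only", "gaussian_only"}
        Which components to fit.  A composite request falls back to
        ``gaussian_only`` (flagged) when no sigmoid transition is detectable.
    psf : PsfCalibration, optional
        Constrains the Gaussian width to ``sqrt(2)*sigma`` within ±30 %.
    hints : dict, optional
        Optional initial values, e.g. ``{"x_0": ..., "x_half": ...}`` (nm);
        the ``x_0`` hint joins the multi-start initializations.
    """

    def __init__(self, x, y, kind: str = "composite",
                 psf: PsfCalibration | None = None,
                 hints: dict | None = None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 16:
            raise ValueError("profile must have at least 16 samples")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if kind not in PROFILE_MODELS:
            raise ValueError(f"kind={kind!r} is not one of {PROFILE_MODELS}")
        self.kind = kind
        self.psf = psf
        self.hints = dict(hints or {})
        self.pixel_size = float(np.median(np.diff(self.x)))

    # -- initialization helpers ------------------------------------------
    def _tails(self) -> tuple[float, float]:
        k = max(2, self.x.size // 10)
        return float(self.y[:k].mean()), float(self.y[-k:].mean())

    def _w_bounds(self) -> tuple[float, float, float]:
        if self.psf is not None:
            w0 = self.psf.w
            return w0 * (1 - W_BAND), w0, w0 * (1 + W_BAND)
        span = self.x[-1] - self.x[0]
        w0 = max(2.0 * self.pixel_size, span / 8.0)
        return self.pixel_size, w0, span

    def _sigmoid_detectable(self) -> bool:
        tin, tout = self._tails()
        rng = float(self.y.max() - self.y.min())
        return (tin - tout) > 0.08 * rng and rng > 0

    # -- fitting ----------------------------------------------------------
    def fit(self) -> ProfileFitResults:
        y = self.y
        if not np.isfinite(y).all():
            raise ValueError("profile contains non-finite values")
        rng_y = float(y.max() - y.min())
        if rng_y <= 0 or (y.max() != 0 and rng_y < 1e-9 * abs(y.max())):
            raise NoSpotError("flat profile: no emitter or membrane signal")

        kind = self.kind
        fallback = False
        if kind == "composite" and not self._sigmoid_detectable():
            kind = "gaussian_only"
            fallback = True

        if kind == "sigmoid_only":
            res = self._fit_sigmoid_only()
        elif kind == "gaussian_only":
            res = self._fit_gaussian_only()
        else:
            res = self._fit_composite()
        res.fallback = fallback
        if res.model == "composite" and res.converged:
            res.orientation_flag = bool(res.x_0 >= res.x_half)
        return res

    def _run(self, resid, p0, lb, ub, names,
             jac=None) -> tuple[np.ndarray, float, bool, dict]:
        p0 = np.clip(p0, lb, ub)
        sol = least_squares(resid, p0, jac=jac or "2-point", bounds=(lb, ub),
                            method="trf", xtol=FIT_TOL, ftol=FIT_TOL,
                            gtol=FIT_TOL, max_nfev=MAX_NFEV)
        rms = math.sqrt(2.0 * sol.cost / self.x.size)
        bse = _bse_from_jac(sol.jac, 2.0 * sol.cost, self.x.size, names)
        return sol.x, rms, bool(sol.success), bse

    def _x0_starts(self, baseline: np.ndarray) -> list[float]:
        cands = [float(self.x[np.argmax(self.y - baseline)])]
        if "x_0" in self.hints:
            cands.append(float(self.hints["x_0"]))
        cands.append(float(0.5 * (self.x[0] + self.x[-1])))
        starts: list[float] = []
        for c in cands:   # dedupe within one pixel
            if all(abs(c - s) > self.pixel_size for s in starts):
                starts.append(c)
        return starts

    def _fit_composite(self) -> ProfileFitResults:
        x, y = self.x, self.y
        tin, tout = self._tails()
        wlo, w0, whi = self._w_bounds()
        dlo, dhi = self.pixel_size / 2.0, 10.0 * self.pixel_size
        d0 = min(max(0.55 * (self.psf.sigma if self.psf else 2 * self.pixel_size),
                     dlo), dhi)
        ymax, ymin = float(y.max()), float(y.min())
        xh0 = float(self.hints.get(
            "x_half", x[int(np.argmin(np.abs(y - 0.5 * (tin + tout))))]))
        names = ["a", "b", "c", "d", "w", "x_0", "x_half"]
        lb = np.array([0.0, 0.0, 0.0, dlo, wlo, x[0], x[0]])
        ub = np.array([2.0 * (ymax - ymin) + 1e-9, 2.0 * ymax + 1e-9,
                       2.0 * (ymax - ymin) + 1e-9, dhi, whi, x[-1], x[-1]])

        def resid(p):
            return composite_profile(x, *p) - y

        def jac(p):
            a, b, c, d, w, x0, xh = p
            jb, jc, jd, jxh = _sigmoid_jac_cols(x, c, d, xh)
            ja, jw, jx0 = _gaussian_jac_cols(x, a, w, x0)
            return np.column_stack([ja, jb, jc, jd, jw, jx0, jxh])

        # two-stage seeding: a sigmoid-only pre-fit locates the membrane
        # robustly; its residual peak seeds the Gaussian basin
        base = sigmoid_component(x, tin, tin - tout, d0, xh0)
        try:
            pre = self._fit_sigmoid_only()
            if pre.converged:
                xh0 = float(np.clip(pre.x_half, x[0], x[-1]))
                d0 = float(np.clip(pre.d, dlo, dhi))
                base = pre.predict(x)
        except Exception:
            pass
        best = None
        starts = []
        for x0_init in self._x0_starts(base):
            idx = int(np.argmin(np.abs(x - x0_init)))
            a0 = max(float(y[idx] - base[idx]), 0.1 * (ymax - ymin))
            starts.append(np.array([a0, tin, max(tin - tout, 1e-6), d0, w0,
                                    x0_init, xh0]))
        # emitter-on-the-membrane hypothesis: Gaussian claims the whole peak,
        # sigmoid crosses steeply just extracellular of it
        x0_peak = float(x[int(np.argmax(y))])
        starts.append(np.array([max(ymax - tin, 0.1 * (ymax - ymin)), tin,
                                max(tin - tout, 1e-6), dlo, w0, x0_peak,
                                float(np.clip(x0_peak + w0 / 3.0,
                                              x[0], x[-1]))]))
        for p0 in starts:
            fitted, rms, ok, bse = self._run(resid, p0, lb, ub, names, jac=jac)
            key = (rms, abs(fitted[5] - p0[5]))
            if best is None or key < best[0]:
                best = (key, fitted, rms, ok, bse)
        _, p, rms, ok, bse = best

        # one alternation pass guards against overlap local minima (emitter
        # sitting on the membrane transition): re-seed the sigmoid from the
        # Gaussian-subtracted profile and re-run once
        try:
            y_sig = y - gaussian_component(x, p[0], p[4], p[5])
            pre2 = ProfileModel(x, y_sig, kind="sigmoid_only", psf=self.psf,
                                hints={"x_half": p[6]}).fit()
            if pre2.converged:
                resid2 = y - pre2.predict(x)
                x0b = float(x[np.argmax(resid2)])
                p0 = np.array([max(float(resid2.max()), 1e-6), pre2.b,
                               max(pre2.c, 1e-6),
                               float(np.clip(pre2.d, dlo, dhi)), p[4], x0b,
                               float(np.clip(pre2.x_half, x[0], x[-1]))])
                fitted, rms2, ok2, bse2 = self._run(resid, p0, lb, ub, names,
                                                    jac=jac)
                if rms2 < rms:
                    p, rms, ok, bse = fitted, rms2, ok2, bse2
        except Exception:
            pass
        return ProfileFitResults("composite", p[0], p[1], p[2], p[3], p[4],
                                 p[5], p[6], rms, ok, x.size, bse)

    def _fit_sigmoid_only(self) -> ProfileFitResults:
        x, y = self.x, self.y
        tin, tout = self._tails()
        dlo, dhi = self.pixel_size / 2.0, 10.0 * self.pixel_size
        d0 = min(max(0.55 * (self.psf.sigma if self.psf else 2 * self.pixel_size),
                     dlo), dhi)
        xh0 = float(self.hints.get(
            "x_half", x[int(np.argmin(np.abs(y - 0.5 * (tin + tout))))]))
        ymax, ymin = float(y.max()), float(y.min())
        names = ["b", "c", "d", "x_half"]
        lb = np.array([0.0, 0.0, dlo, x[0]])
        ub = np.array([2.0 * ymax + 1e-9, 2.0 * (ymax - ymin) + 1e-9, dhi, x[-1]])

        def resid(p):
            return sigmoid_component(x, *p) - y

        def jac(p):
            b, c, d, xh = p
            return np.column_stack(_sigmoid_jac_cols(x, c, d, xh))

        p0 = np.array([tin, max(tin - tout, 1e-6), d0, xh0])
        p, rms, ok, bse = self._run(resid, p0, lb, ub, names, jac=jac)
        nan = float("nan")
        return ProfileFitResults("sigmoid_only", nan, p[0], p[1], p[2], nan,
                                 nan, p[3], rms, ok, x.size, bse)

    def _fit_gaussian_only(self) -> ProfileFitResults:
        x, y = self.x, self.y
        wlo, w0, whi = self._w_bounds()
        ymax, ymin = float(y.max()), float(y.min())
        names = ["a", "b", "w", "x_0"]
        lb = np.array([0.0, min(0.0, ymin), wlo, x[0]])
        ub = np.array([2.0 * (ymax - ymin) + 1e-9, ymax + 1e-9, whi, x[-1]])

        def resid(p):
            a, b, w, x0 = p
            return b + gaussian_component(x, a, w, x0) - y

        def jac(p):
            a, b, w, x0 = p
            ja, jw, jx0 = _gaussian_jac_cols(x, a, w, x0)
            return np.column_stack([ja, np.ones_like(ja), jw, jx0])

        best = None
        for x0_init in self._x0_starts(np.full_like(y, ymin)):
            p0 = np.array([ymax - ymin, ymin, w0, x0_init])
            p, rms, ok, bse = self._run(resid, p0, lb, ub, names, jac=jac)
            key = (rms, abs(p[3] - x0_init))
            if best is None or key < best[0]:
                best = (key, p, rms, ok, bse)
        _, p, rms, ok, bse = best
        nan = float("nan")
        return ProfileFitResults("gaussian_only", p[0], p[1], nan, nan, p[2],
                                 p[3], nan, rms, ok, x.size, bse)


def _bse_from_jac(jac: np.ndarray, sse: float, n: int, names: list[str]) -> dict:
    k = jac.shape[1]
    dof = max(n - k, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(names, se))


def fit_profile(x, y, model: str = "composite",
                psf: PsfCalibration | None = None,
                hints: dict | None = None) -> ProfileFitResults:
    """Fit a 1-D intensity profile; see :class:`ProfileModel`."""
    return ProfileModel(x, y, kind=model, psf=psf, hints=hints).fit()


# ---------------------------------------------------------------------------
# 2-D spot model
# ---------------------------------------------------------------------------

@dataclass
class SpotFit2DResults:
    """Elliptical 2-D Gaussian spot fit; peak coordinates in nm."""

    x_peak: float
    y_peak: float
    sd_x: float
    sd_y: float
    amplitude: float
    offset: float
    rms_residual: float
    converged: bool
    nobs: int
    bse: dict

    @property
    def params(self) -> dict:
        return {"x_peak": self.x_peak, "y_peak": self.y_peak,
                "sd_x": self.sd_x, "sd_y": self.sd_y,
                "amplitude": self.amplitude, "offset": self.offset}

    def summary(self) -> str:
        lines = ["2-D Gaussian spot fit", "=" * 46,
                 f"observations: {self.nobs}",
                 f"converged:    {self.converged}",
                 f"rms residual: {self.rms_residual:.4g}",
                 "-" * 46,
                 f"{'param':>10} {'estimate':>12} {'std err':>12}"]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:>10} {v:12.4f} {se:12.4f}")
        return "\n".join(lines)


class SpotModel2D:
    """Elliptical 2-D Gaussian plus constant offset on an image ROI.

    ``roi`` is ``(row0, col0, n_rows, n_cols)`` in pixels (at least 5x5);
    coordinates are reported in nm with pixel ``i`` centered at
    ``(i + 0.5) * pixel_size``.
    """

    def __init__(self, image: np.ndarray, pixel_size: float,
                 roi: tuple[int, int, int, int] | None = None,
                 init: dict | None = None):
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("image must be 2-D")
        ny, nx = image.shape
        if roi is None:
            roi = (0, 0, ny, nx)
        r0, c0, nr, nc = roi
        if r0 < 0 or c0 < 0 or r0 + nr > ny or c0 + nc > nx:
            raise ValueError("roi extends outside the image")
        if nr < 5 or nc < 5:
            raise ValueError("roi must span at least 5x5 pixels")
        self.image = image
        self.roi = roi
        self.pixel_size = float(pixel_size)
        self.init = dict(init or {})

    def fit(self) -> SpotFit2DResults:
        r0, c0, nr, nc = self.roi
        sub = self.image[r0:r0 + nr, c0:c0 + nc]
        ps = self.pixel_size
        xg = (c0 + np.arange(nc) + 0.5) * ps
        yg = (r0 + np.arange(nr) + 0.5) * ps
        zmax, zmin = float(sub.max()), float(sub.min())
        if zmax - zmin <= 0 or (zmax != 0 and (zmax - zmin) < 1e-9 * abs(zmax)):
            raise NoSpotError("flat ROI: no spot to fit")

        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        x0 = self.init.get("x_peak", xg[ix])
        y0 = self.init.get("y_peak", yg[iy])
        # moment-based width initialization on the background-subtracted ROI
        wgt = np.clip(sub - zmin, 0, None)
        tot = wgt.sum()
        sx0 = self.init.get("sd_x", math.sqrt(
            max(((wgt.sum(axis=0) * (xg - x0) ** 2).sum() / tot), ps**2)))
        sy0 = self.init.get("sd_y", math.sqrt(
            max(((wgt.sum(axis=1) * (yg - y0) ** 2).sum() / tot), ps**2)))

        X, Y = np.meshgrid(xg, yg)
        span = max(xg[-1] - xg[0], yg[-1] - yg[0])

        def resid(p):
            a, b, x, y, sx, sy = p
            return (b + a * np.exp(-((X - x) ** 2) / (2 * sx**2)
                                   - ((Y - y) ** 2) / (2 * sy**2)) - sub).ravel()

        def jac(p):
            a, b, x, y, sx, sy = p
            u, v = (X - x) / sx, (Y - y) / sy
            g = np.exp(-0.5 * (u**2 + v**2))
            cols = [g, np.ones_like(g), a * g * u / sx, a * g * v / sy,
                    a * g * u**2 / sx, a * g * v**2 / sy]
            return np.column_stack([c.ravel() for c in cols])

        p0 = np.array([zmax - zmin, zmin, x0, y0, sx0, sy0])
        lb = np.array([0.0, min(0.0, zmin), xg[0], yg[0], 0.3 * ps, 0.3 * ps])
        ub = np.array([2 * (zmax - zmin) + 1e-9, zmax + 1e-9, xg[-1], yg[-1],
                       span, span])
        sol = least_squares(resid, np.clip(p0, lb, ub), jac=jac,
                            bounds=(lb, ub), method="trf", xtol=FIT_TOL,
                            ftol=FIT_TOL, gtol=FIT_TOL, max_nfev=MAX_NFEV)
        rms = math.sqrt(2.0 * sol.cost / sub.size)
        names = ["amplitude", "offset", "x_peak", "y_peak", "sd_x", "sd_y"]
        bse = _bse_from_jac(sol.jac, 2.0 * sol.cost, sub.size, names)
        a, b, x, y, sx, sy = sol.x
        return SpotFit2DResults(x, y, sx, sy, a, b, rms, bool(sol.success),
                                sub.size, bse)


def fit_spot_2d(image: np.ndarray, pixel_size: float,
                roi: tuple[int, int, int, int] | None = None,
                init: dict | None = None) -> SpotFit2DResults:
    """Fit an elliptical 2-D Gaussian spot; see :class:`SpotModel2D`."""
    return SpotModel2D(image, pixel_size, roi=roi, init=init).fit()


def calibrate_psf(bead: np.ndarray, pixel_size: float) -> PsfCalibration:
    """Calibrate the PSF width from a sub-resolution bead image.

    The PSF sigma is the mean of the fitted x and y spot SDs; strong
    anisotropy (``|sd_x - sd_y| / sigma > 0.2``) sets a warning flag.
    """
    bead = np.asarray(bead, dtype=float)
    med = float(np.median(bead))
    mad = float(np.median(np.abs(bead - med)))
    if bead.max() - med <= max(5.0 * 1.4826 * mad, 1e-12):
        raise CalibrationError("no spot above background in bead image")
    try:
        fit = fit_spot_2d(bead, pixel_size)
    except NoSpotError as exc:
        raise CalibrationError(str(exc)) from exc
    if not fit.converged:
        raise CalibrationError("bead spot fit did not converge")
    sigma = 0.5 * (fit.sd_x + fit.sd_y)
    warn = abs(fit.sd_x - fit.sd_y) / sigma > 0.2
    return PsfCalibration(sigma=sigma, source="bead", anisotropy_warning=warn)
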