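"""Imaging data I/O: multi-page TIFF with metadata sidecars, deinterleaving.

A dataset on disk is ``<base>.tif`` plus a required ``<base>.meta.yaml``
sidecar carrying the physical calibration (pixel size, line/frame period,
channel scheme); synthetic datasets additionally get a ``<base>.truth.json``
ground-truth sidecar.  Loading refuses data without a pixel size — there
are no silent pixel-unit defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import LoadError
from .scene import GroundTruthScene, ImagingParams

__all__ = ["deinterleave", "interleave", "save_imaging_data",
           "load_imaging_data", "save_ground_truth"]


def deinterleave(raw: np.ndarray, scheme: str, times: np.ndarray | None = None):
    """Split an interleaved two-channel stream into per-channel data.

    ``alternate_lines``/``alternate_frames``: channel 0 occupies even
    records along the leading axis, channel 1 odd records (one period
    later); the record count must be even.  ``simultaneous``: axis 1 holds
    the channels.  Returns ``(ch0, ch1, times0, times1)``; re-interleaving
    with :func:`interleave` reproduces the input exactly.
    """
    raw = np.asarray(raw)
    if scheme in ("alternate_lines", "alternate_frames"):
        n = raw.shape[0]
        if n % 2:
            raise ValueError(
                f"{scheme}: interleaved stream has odd record count {n}")
        ch0, ch1 = raw[0::2], raw[1::2]
        t0 = t1 = None
        if times is not None:
            times = np.asarray(times)
            t0, t1 = times[0::2], times[1::2]
        return ch0, ch1, t0, t1
    if scheme == "simultaneous":
        if raw.ndim < 2 or raw.shape[1] != 2:
            raise ValueError("simultaneous data must have a channel axis of 2")
        t = None if times is None else np.asarray(times)
        return raw[:, 0], raw[:, 1], t, t
    raise ValueError(f"unknown channel scheme {scheme!r}")


def interleave(ch0: np.ndarray, ch1: np.ndarray, scheme: str) -> np.ndarray:
    """Inverse of :func:`deinterleave` for the data stream."""
    ch0, ch1 = np.asarray(ch0), np.asarray(ch1)
    if ch0.shape != ch1.shape:
        raise ValueError("channels must have identical shapes")
    if scheme in ("alternate_lines", "alternate_frames"):
        out = np.empty((2 * ch0.shape[0],) + ch0.shape[1:], dtype=ch0.dtype)
        out[0::2], out[1::2] = ch0, ch1
        return out
    if scheme == "simultaneous":
        return np.stack([ch0, ch1], axis=1)
    raise ValueError(f"unknown channel scheme {scheme!r}")


def _sidecar_paths(base: Path) -> tuple[Path, Path, Path]:
    base = Path(base)
    if base.suffix == ".tif":
        base = base.with_suffix("")
    return (base.with_suffix(".tif"), Path(str(base) + ".meta.yaml"),
            Path(str(base) + ".truth.json"))


def save_imaging_data(base, data: np.ndarray, params: ImagingParams,
                      kind: str, times: np.ndarray | None = None,
                      extra_meta: dict | None = None) -> Path:
    """Write ``<base>.tif`` and its ``<base>.meta.yaml`` sidecar.

    ``kind`` is ``"xy"`` (pages are frames; axes may include a channel
    dimension) or ``"xt"`` (a line-scan image, lines x pixels).
    """
    tif, meta_p, _ = _sidecar_paths(Path(base))
    data = np.asarray(data)
    tifffile.imwrite(tif, data.astype(np.float32))
    meta = {
        "kind": kind,
        "shape": list(data.shape),
        "pixel_size_nm": params.pixel_size,
        "psf_sigma_nm": params.psf_sigma,
        "line_period_ms": params.line_period,
        "frame_period_s": params.frame_period,
        "channel_scheme": params.channel_scheme,
        "photon_scale": params.photon_scale,
        "background_intra": params.background_intra,
        "background_extra": params.background_extra,
        "optical_section_thickness_nm": params.optical_section_thickness,
    }
    if times is not None:
        meta["t_start_s"] = float(np.asarray(times).ravel()[0])
    if extra_meta:
        meta.update(extra_meta)
    meta_p.write_text(yaml.safe_dump(meta, sort_keys=False))
    return tif


def save_ground_truth(base, scene: GroundTruthScene) -> Path:
    """Write the ground-truth sidecar: geometry, trajectory kinds, events."""
    _, _, truth_p = _sidecar_paths(Path(base))
    payload = {
        "membrane_x0": scene.membrane_x0,
        "membrane_radius": (None if np.isinf(scene.membrane_radius)
                            else scene.membrane_radius),
        "ribbon_center": list(scene.ribbon_center),
        "ribbon_extent": list(scene.ribbon_extent),
        "stimulus_time": scene.stimulus_time,
        "duration": scene.duration,
        "trajectories": [
            {
                "kind": tr.kind,
                "amplitude": tr.amplitude,
                "t_on": tr.t_on,
                "t_off": tr.t_off,
                "shift": list(tr.shift),
                "base_xy": [float(tr.breakpoints_xy[0, 0]),
                            float(tr.breakpoints_xy[0, 1])],
                "events": tr.events,
            }
            for tr in scene.trajectories
        ],
    }
    truth_p.write_text(json.dumps(payload, indent=1))
    return truth_p


def load_imaging_data(base):
    """Load ``<base>.tif`` with its metadata sidecar.

    Returns ``(data, params, meta)``.  A missing or pixel-size-free sidecar
    raises :class:`LoadError`.
    """
    tif, meta_p, _ = _sidecar_paths(Path(base))
    if not tif.exists():
        raise LoadError(f"missing image file {tif}")
    if not meta_p.exists():
        raise LoadError(f"missing metadata sidecar {meta_p}")
    try:
        meta = yaml.safe_load(meta_p.read_text())
    except yaml.YAMLError as exc:
        raise LoadError(f"unreadable metadata sidecar {meta_p}: {exc}") from exc
    if not isinstance(meta, dict) or "pixel_size_nm" not in meta:
        raise LoadError(f"sidecar {meta_p} lacks pixel_size_nm; refusing to "
                        "assume pixel units")
    data = tifffile.imread(tif)
    params = ImagingParams(
        pixel_size=float(meta["pixel_size_nm"]),
        psf_sigma=float(meta.get("psf_sigma_nm", 110.0)),
        line_period=float(meta.get("line_period_ms", 1.4)),
        frame_period=float(meta.get("frame_period_s", 0.5)),
        channel_scheme=meta.get("channel_scheme", "simultaneous"),
        photon_scale=float(meta.get("photon_scale", 1.0)),
        background_intra=float(meta.get("background_intra", 0.0)),
        background_extra=float(meta.get("background_extra", 0.0)),
        optical_section_thickness=float(
            meta.get("optical_section_thickness_nm", 600.0)),
    )
    return data, params, meta
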