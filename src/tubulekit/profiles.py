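"""Ciliary intensity-profile quantification.

Profiles run from the proximal end (arclength 0) to the distal tip.  The
standard normalisation maps the length to a 0-100 % scale and each channel
to percent of its own maximum; ensembles are summarised per bin as
mean +/- SEM.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .core import NormalizedProfile, RawProfile

__all__ = [
    "extract_profile",
    "normalize_profile",
    "average_profiles",
    "enrichment_index",
    "cilium_length",
    "group_length_stats",
]


def extract_profile(
    image: np.ndarray,
    polyline: np.ndarray,
    pixel_size: float,
    width: float = 0.17,
) -> RawProfile:
    """Mean-intensity profile along a traced polyline of fixed width.

    At each arclength sample (spacing = one pixel) the intensity is the
    mean over a perpendicular segment of the given physical width,
    bilinearly interpolated.  The polyline is given in pixel coordinates
    (x, y); positions are returned in um from the first (proximal) point.
    """
    img = np.asarray(image, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
        raise ValueError("polyline must be an (n >= 2, 2) array of (x, y)")
    if width <= 0 or pixel_size <= 0:
        raise ValueError("width and pixel_size must be > 0")
    h, w_img = img.shape
    if (poly[:, 0].min() < 0 or poly[:, 0].max() > w_img - 1
            or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1):
        raise ValueError("polyline exits image bounds")

    # resample the polyline at 1-px arclength spacing
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    s = np.arange(0.0, total + 1e-9, 1.0)
    xs = np.interp(s, arclen, poly[:, 0])
    ys = np.interp(s, arclen, poly[:, 1])
    # unit tangents / normals at each sample
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm
    nx, ny = -ty, tx
    half_w_px = width / pixel_size / 2.0
    n_off = max(1, int(np.ceil(width / pixel_size)))
    offsets = np.linspace(-half_w_px, half_w_px, 2 * n_off + 1)
    sample_x = xs[:, None] + offsets[None, :] * nx[:, None]
    sample_y = ys[:, None] + offsets[None, :] * ny[:, None]
    vals = map_coordinates(img, [sample_y.ravel(), sample_x.ravel()], order=1, mode="nearest")
    prof = vals.reshape(sample_x.shape).mean(axis=1)
    return RawProfile(
        positions=s * pixel_size,
        intensities=np.clip(prof, 0.0, None)[:, None],
        channel_names=("A",),
        width=width,
    )


def normalize_profile(raw: RawProfile, n_bins: int = 101) -> NormalizedProfile:
    """Resample to ``n_bins`` positions on 0-100 % length and scale each
    channel to percent of its own maximum (no minimum subtraction; any
    background is assumed pre-subtracted).  All-zero channels are flagged
    and left unscaled."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    length = raw.positions[-1] - raw.positions[0]
    pct = np.linspace(0.0, 100.0, n_bins)
    s_target = raw.positions[0] + pct / 100.0 * length
    out = np.empty((n_bins, raw.intensities.shape[1]))
    flags = {}
    for c in range(raw.intensities.shape[1]):
        y = np.interp(s_target, raw.positions, raw.intensities[:, c])
        m = y.max()
        if m <= 0:
            flags[f"channel_{raw.channel_names[c]}_all_zero"] = True
            out[:, c] = y
        else:
            out[:, c] = y / m * 100.0
    return NormalizedProfile(positions=pct, intensities=out,
                             channel_names=tuple(raw.channel_names), flags=flags)


def average_profiles(profiles: Sequence[NormalizedProfile]) -> dict:
    """Per-bin mean and SEM per channel across an ensemble of profiles.

    SEM uses the sample SD (n-1 denominator).  All profiles must share the
    same bin count.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    n_bins = profiles[0].positions.size
    if any(p.positions.size != n_bins for p in profiles):
        raise ValueError("mixed bin counts")
    stack = np.stack([p.intensities for p in profiles])  # (n, bins, channels)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return {
        "positions": profiles[0].positions,
        "mean": mean,
        "sem": sem,
        "n": n,
        "channel_names": tuple(profiles[0].channel_names),
    }


def enrichment_index(
    profile: NormalizedProfile,
    boundary_pct: float = 50.0,
    channel: int = 0,
) -> float:
    """Proximal / distal mean intensity ratio of one channel, split at
    ``boundary_pct`` of the length.  A zero distal mean yields ``inf``."""
    if not (0.0 < boundary_pct < 100.0):
        raise ValueError("boundary_pct must lie in (0, 100)")
    y = profile.intensities[:, channel]
    prox = y[profile.positions < boundary_pct]
    dist = y[profile.positions >= boundary_pct]
    pm, dm = prox.mean(), dist.mean()
    if dm <= 0:
        return np.inf
    return float(pm / dm)


def cilium_length(polyline: np.ndarray, pixel_size: float) -> float:
    """Arclength of a traced cilium in um (sum of consecutive Euclidean
    distances scaled by the pixel size)."""
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) * pixel_size)


def group_length_stats(
    lengths_by_group: dict,
    experiment_ids: Optional[dict] = None,
) -> dict:
    """Mean +/- SD of cilium lengths per group, plus per-experiment means
    when experiment labels are supplied."""
    out = {}
    for group, lengths in lengths_by_group.items():
        v = np.asarray(lengths, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        entry = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }
        if experiment_ids and group in experiment_ids:
            ids = np.asarray(experiment_ids[group])
            entry["per_experiment_mean"] = {
                str(e): float(v[ids == e].mean()) for e in np.unique(ids)
            }
        out[group] = entry
    return out
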