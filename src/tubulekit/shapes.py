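"""Synthetic geometry and profile generators with recorded ground truth:
circular-arc B-tubule traces, annular density slices, and two-channel
ciliary intensity profiles."""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ArcSpec, ProfileSpec, RawProfile, TubuleTrace

__all__ = ["make_arc", "make_profiles", "make_annulus_slice", "render_profile_image"]

#: A-tubule radius (nm) used to place the O landmark relative to X
A_TUBULE_RADIUS_NM = 13.5


def make_arc(spec: ArcSpec, rng: Optional[np.random.Generator] = None) -> TubuleTrace:
    """Points on a circular arc of known radius, jittered and rigidly posed.

    ``n_points`` points are spread uniformly over ``arc_span`` degrees of a
    circle of radius ``radius_true``; isotropic Gaussian jitter of
    ``jitter_sigma`` nm is added, then the whole trace (with its O and X
    landmarks) is rotated by ``pose_angle`` and shifted by ``pose_shift``.
    X is the first arc point; O sits on the concave side of the arc at the
    distance implied by an A-tubule radius of 13.5 nm, giving every trace
    a reproducible O-X direction.  The generating radius is stored as
    ``radius_true``.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    theta = np.deg2rad(np.linspace(0.0, spec.arc_span, spec.n_points))
    centre = np.array([0.0, 0.0])
    pts = centre + spec.radius_true * np.column_stack([np.cos(theta), np.sin(theta)])
    if spec.jitter_sigma > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sigma, size=pts.shape)
    X = pts[0].copy()
    # O on the concave side: from X toward the arc centre, at the A-tubule radius
    to_centre = centre - np.array([spec.radius_true, 0.0])
    to_centre = to_centre / max(np.linalg.norm(to_centre), 1e-12) if np.linalg.norm(to_centre) > 0 else np.array([-1.0, 0.0])
    O = np.array([spec.radius_true, 0.0]) + A_TUBULE_RADIUS_NM * to_centre
    ang = np.deg2rad(spec.pose_angle)
    c, s = np.cos(ang), np.sin(ang)
    R = np.array([[c, -s], [s, c]])
    shift = np.asarray(spec.pose_shift, dtype=float)
    return TubuleTrace(
        points=pts @ R.T + shift,
        O=R @ O + shift,
        X=R @ X + shift,
        label=f"arc-{spec.rng_seed}",
        radius_true=spec.radius_true,
    )


def make_annulus_slice(
    mid_radius_nm: float = 13.5,
    wall_thickness_nm: float = 3.0,
    nm_per_px: float = 0.25,
    image_half_width_nm: float = 22.0,
    blur_sigma_px: float = 1.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Synthetic transverse density slice of a tubule wall: a bright
    annulus of mid radius ``mid_radius_nm`` and the given wall thickness,
    optionally blurred and corrupted with Gaussian noise.  Serves as a
    stand-in for a transverse slice of an experimental density map."""
    n = int(round(2 * image_half_width_nm / nm_per_px))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c) * nm_per_px
    img = np.where(np.abs(r - mid_radius_nm) <= wall_thickness_nm / 2.0, 1.0, 0.0)
    if blur_sigma_px > 0:
        img = gaussian_filter(img, blur_sigma_px)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, None)


def make_profiles(spec: ProfileSpec, rng: Optional[np.random.Generator] = None) -> RawProfile:
    """Two-channel ciliary intensity profile with proximal enrichment.

    Channel A steps down at ``proximal_fraction * length``: the proximal
    plateau is ``enrichment_ratio`` times the distal one (a logistic ramp
    of width ``step_softness * length`` replaces the hard step when
    requested).  Channel B is uniform along the length.  Both channels
    receive per-sample multiplicative Gaussian noise of relative sigma
    ``noise_sigma``.  The noise-free curves and generating parameters are
    stored in ``truth``.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    s = np.linspace(0.0, spec.length, spec.n_samples)
    x_step = spec.proximal_fraction * spec.length
    if spec.step_softness > 0:
        softness = spec.step_softness * spec.length
        step = 1.0 / (1.0 + np.exp((s - x_step) / softness))  # ~1 proximal, ~0 distal
    else:
        step = (s < x_step).astype(float)
    base = 100.0
    chan_a = base * (1.0 + (spec.enrichment_ratio - 1.0) * step)
    chan_b = np.full_like(s, base)
    clean = np.column_stack([chan_a, chan_b])
    noisy = clean.copy()
    if spec.noise_sigma > 0:
        noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sigma, clean.shape))
    return RawProfile(
        positions=s,
        intensities=np.clip(noisy, 0.0, None),
        channel_names=("A", "B"),
        truth={
            "clean": clean,
            "enrichment_ratio": spec.enrichment_ratio,
            "proximal_fraction": spec.proximal_fraction,
            "rng_seed": spec.rng_seed,
        },
    )


def render_profile_image(
    profile: RawProfile,
    pixel_size: float = 0.1,
    width_px: int = 5,
    pad_px: int = 6,
    channel: int = 0,
) -> np.ndarray:
    """Rasterise one profile channel as a straight horizontal cilium.

    The cilium runs left to right at a fixed row band of ``width_px``
    pixels; column intensity follows the profile resampled at
    ``pixel_size`` um/px.  Used for round-trip testing of image-based
    profile extraction.
    """
    length = profile.positions[-1]
    n_cols = int(np.ceil(length / pixel_size)) + 1
    cols = np.arange(n_cols) * pixel_size
    vals = np.interp(cols, profile.positions, profile.intensities[:, channel])
    img = np.zeros((width_px + 2 * pad_px, n_cols + 2 * pad_px))
    img[pad_px : pad_px + width_px, pad_px : pad_px + n_cols] = vals[None, :]
    return img
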