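"""Rasterisation of end traces into TIRF-like kymographs, and the inverse
operation: sub-pixel end-position extraction from kymograph images.

Geometry convention: rows are frames (time downward), columns are space.
The stable seed sits at a fixed column interval; the minus end extends to
the left and the plus end to the right.  Column coordinates are "edge"
coordinates: pixel ``j`` spans ``[j, j+1)`` and its centre is ``j + 0.5``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import EndTrace, Kymograph, KymoSpec

__all__ = ["render_kymograph", "extract_end_position", "expected_image"]


def _frame_positions(trace: EndTrace, frame_times: np.ndarray) -> np.ndarray:
    if trace.times[0] > frame_times[0] + 1e-9 or trace.times[-1] < frame_times[-1] - 1e-9:
        raise ValueError("trace does not cover the kymograph duration")
    return np.interp(frame_times, trace.times, trace.positions)


def expected_image(trace_plus: EndTrace, trace_minus: EndTrace, spec: KymoSpec):
    """Noise-free expected photon counts per pixel, plus the seed span.

    Partial pixels at the microtubule ends receive coverage-weighted
    intensity, so the above-background mass per row equals the lattice
    extent in pixels exactly.
    """
    px = spec.pixel_size
    frame_times = np.arange(spec.n_frames) * spec.frame_interval
    xp = _frame_positions(trace_plus, frame_times)
    xm = _frame_positions(trace_minus, frame_times)
    seed_px = max(1, int(round(spec.seed_length / px)))
    margin = 4
    seed_left = margin + int(np.ceil(xm.max() / px))
    seed_right = seed_left + seed_px
    n_cols = seed_right + int(np.ceil(xp.max() / px)) + margin
    u_left = seed_left - xm / px
    u_right = seed_right + xp / px
    j = np.arange(n_cols)
    cov = np.clip(
        np.minimum(j + 1.0, u_right[:, None]) - np.maximum(j * 1.0, u_left[:, None]),
        0.0, 1.0,
    )
    expect = spec.background + (spec.signal - spec.background) * cov
    if spec.psf_sigma > 0:
        expect = gaussian_filter1d(expect, spec.psf_sigma, axis=1, mode="nearest")
    return expect, (seed_left, seed_right)


def render_kymograph(
    trace_plus: EndTrace,
    trace_minus: EndTrace,
    spec: KymoSpec,
    noise: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> Kymograph:
    """Render a two-ended trace pair into a kymograph raster.

    Pixels covered by the lattice (between the minus and plus end, plus the
    seed span) get expected value ``signal``, others ``background``; rows are
    convolved with a Gaussian PSF and each pixel receives an independent
    Poisson draw (unless ``noise=False``, which returns the expectation).
    """
    expect, seed_span = expected_image(trace_plus, trace_minus, spec)
    if noise:
        rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
        image = rng.poisson(expect).astype(float)
    else:
        image = expect
    return Kymograph(image=image, spec=spec, seed_span=seed_span)


def extract_end_position(
    kymo: Kymograph,
    side: str = "right",
    threshold_frac: float = 0.5,
) -> EndTrace:
    """Trace one microtubule end through a kymograph, frame by frame.

    Per frame the end is the outermost crossing of
    ``background + threshold_frac * (plateau - background)`` on the chosen
    side, localised to sub-pixel precision by linear interpolation between
    pixel centres.  The plateau is the mean over the (always lit) seed
    columns and the background a low per-frame quantile.  Frames with no
    crossing yield NaN.  Positions are returned in um relative to the seed
    edge on that side, plus end on the right and minus end on the left.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    img = kymo.image
    n_frames, n_cols = img.shape
    s0, s1 = kymo.seed_span
    # plateau from the central seed columns (always lit, away from the
    # blurred seed edges); background from a global low quantile, which is
    # robust to frames where the lattice fills most of the row
    trim = max((s1 - s0) // 4, 0)
    plateau = img[:, s0 + trim : max(s1 - trim, s0 + trim + 1)].mean(axis=1)
    background = np.full(n_frames, np.quantile(img, 0.05))
    contrast = plateau - background
    if np.median(contrast) < 4.0 * np.sqrt(max(np.median(plateau), 1.0)):
        raise ValueError("blank kymograph: no significant plateau above background")
    level = background + threshold_frac * contrast

    if side == "right":
        sub = img[:, s1 - 1:]          # from last seed column outwards
        offset = s1 - 1
        sub = sub
    else:
        sub = img[:, s0::-1]           # from first seed column outwards (mirrored)
        offset = s0

    above = sub >= level[:, None]
    # outermost column still above threshold
    rev = above[:, ::-1]
    idx_rev = np.argmax(rev, axis=1)
    any_above = above.any(axis=1)
    idx = sub.shape[1] - 1 - idx_rev   # index within sub
    rows = np.arange(n_frames)
    v0 = sub[rows, idx]
    nxt = np.minimum(idx + 1, sub.shape[1] - 1)
    v1 = sub[rows, nxt]
    denom = v0 - v1
    frac = np.where(denom > 0, (v0 - level) / np.where(denom > 0, denom, 1.0), 0.5)
    frac = np.clip(frac, 0.0, 1.0)
    cross = idx + 0.5 + frac           # sub-image centre coordinate of the crossing

    px = kymo.spec.pixel_size
    if side == "right":
        u = offset + cross             # edge coordinate in full image
        pos = (u - s1) * px
    else:
        u = offset + 1 - cross
        pos = (s0 - u) * px
    pos = np.where(any_above, np.maximum(pos, 0.0), np.nan)
    times = np.arange(n_frames) * kymo.spec.frame_interval
    return EndTrace(
        times=times,
        positions=pos,
        end="plus" if side == "right" else "minus",
        meta={"side": side, "threshold_frac": threshold_frac},
    )
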