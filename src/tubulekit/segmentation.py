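"""Piecewise-linear segmentation of end traces into growth / shrink / pause.

Two segmenters share the same classification and merging rules:

- ``"penalized"`` (default): exact minimisation of
  ``sum(segment RSS) + beta * (#segments)`` by dynamic programming over
  candidate breakpoints.  Exact for piecewise-linear signals and sensitive
  to short events (single-interval shrink excursions, brief pauses).
- ``"recursive"``: top-down splitting at the point of maximum deviation
  until the per-segment residual drops below ``residual_tol``.

Classification uses the end-specific pause criterion: a segment is a pause
when the magnitude of its velocity is strictly below the threshold
(0.24 um/min at the plus end, 0.12 um/min at the minus end); otherwise the
sign of the velocity decides growth versus shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GROWTH, PAUSE, SHRINK, S_PER_MIN, EndTrace, PhaseSegment

__all__ = ["SegmentationParams", "segment_trace", "classify_slope"]


@dataclass
class SegmentationParams:
    """Tunable knobs of the trace segmenter.

    ``pause_threshold_plus`` / ``pause_threshold_minus`` are the strict
    velocity criteria (um/min) below which a segment counts as a pause.
    ``min_segment_frames`` suppresses short spurious segments unless a
    growth/shrink excursion justifies itself by amplitude
    (``min_event_length``, um).  ``residual_tol`` (um) is the stopping
    tolerance of the recursive splitter; ``penalty`` overrides the
    automatic breakpoint penalty of the dynamic program (um^2).
    """

    pause_threshold_plus: float = 0.24
    pause_threshold_minus: float = 0.12
    min_segment_frames: int = 3
    residual_tol: float = 0.214  # 2 x default pixel size
    min_event_length: float = 0.2
    penalty: float | None = None
    penalty_factor: float = 2.0
    max_gap_frames: int = 3

    def __post_init__(self) -> None:
        if self.pause_threshold_plus <= 0 or self.pause_threshold_minus <= 0:
            raise ValueError("pause thresholds must be > 0")
        if self.min_segment_frames < 2:
            raise ValueError("min_segment_frames must be >= 2")

    def threshold(self, end: str) -> float:
        return self.pause_threshold_plus if end == "plus" else self.pause_threshold_minus


def classify_slope(slope_um_per_min: float, threshold: float) -> str:
    """Apply the strict pause criterion to a velocity in um/min."""
    if abs(slope_um_per_min) < threshold:
        return PAUSE
    return GROWTH if slope_um_per_min > 0 else SHRINK


# ---------------------------------------------------------------------------
# least-squares line machinery over index windows (shared-endpoint segments)

class _Windows:
    """O(1) line-fit statistics over inclusive sample windows [i..j]."""

    def __init__(self, t: np.ndarray, x: np.ndarray):
        self.t = t - t.mean()
        self.x0 = x - x.mean()
        self.traw = t
        self.xraw = x

        def cum(a):
            c = np.zeros(len(a) + 1)
            np.cumsum(a, out=c[1:])
            return c

        tt, xx = self.t, self.x0
        self.C1 = cum(np.ones_like(tt))
        self.Ct = cum(tt)
        self.Ctt = cum(tt * tt)
        self.Cx = cum(xx)
        self.Ctx = cum(tt * xx)
        self.Cxx = cum(xx * xx)

    def _sums(self, i, j):
        sl = lambda C: C[j + 1] - C[i]
        return sl(self.C1), sl(self.Ct), sl(self.Ctt), sl(self.Cx), sl(self.Ctx), sl(self.Cxx)

    def rss(self, i, j):
        """Residual sum of squares of the LSQ line over [i..j]; vectorised in i."""
        n, st, stt, sx, stx, sxx = self._sums(i, j)
        stt_c = stt - st * st / n
        stx_c = stx - st * sx / n
        sxx_c = sxx - sx * sx / n
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sxx_c - np.where(stt_c > 0, stx_c**2 / np.where(stt_c > 0, stt_c, 1.0), 0.0)
        return np.maximum(out, 0.0)

    def fit(self, i, j, trim=True):
        """(slope um/s, x_at_t[i], x_at_t[j]) of the LSQ line over [i..j].

        With ``trim``, windows of >= 4 samples drop their two boundary
        samples before fitting: boundary samples straddle phase changes
        and bias speeds toward zero.
        """
        a, b = (i + 1, j - 1) if (trim and j - i + 1 >= 4) else (i, j)
        n, st, stt, sx, stx, _ = self._sums(a, b)
        stt_c = stt - st * st / n
        if stt_c <= 0:
            slope = 0.0
        else:
            slope = (stx - st * sx / n) / stt_c
        tm, xm = st / n, sx / n
        x_i = xm + slope * (self.t[i] - tm)
        x_j = xm + slope * (self.t[j] - tm)
        off = self.xraw.mean()
        return slope, x_i + off, x_j + off


def _estimate_noise(x: np.ndarray) -> float:
    d2 = np.diff(x, 2)
    if d2.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)


def _dp_breakpoints(w: _Windows, beta: float, min_size: int = 1) -> list[int]:
    """Optimal shared-endpoint breakpoints minimising sum(RSS) + beta * k."""
    n = len(w.traw)
    best = np.full(n, np.inf)
    prev = np.zeros(n, dtype=int)
    best[0] = 0.0
    for j in range(min_size, n):
        i_hi = j - min_size
        i_arr = np.arange(0, i_hi + 1)
        tot = best[: i_hi + 1] + w.rss(i_arr, j) + beta
        k = int(np.argmin(tot))
        best[j] = tot[k]
        prev[j] = k
    bps = [n - 1]
    while bps[-1] > 0:
        bps.append(int(prev[bps[-1]]))
    return bps[::-1]


def _recursive_breakpoints(w: _Windows, tol: float) -> list[int]:
    """Top-down max-deviation splitting until per-segment residual <= tol."""
    n = len(w.traw)
    bps = {0, n - 1}

    def split(i, j):
        if j - i < 2:
            return
        slope, x_i, _ = w.fit(i, j, trim=False)
        tt = w.t[i : j + 1]
        line = x_i + slope * (tt - w.t[i])
        resid = np.abs(w.xraw[i : j + 1] - line)
        k = 1 + int(np.argmax(resid[1:-1]))  # interior max only
        if resid[k] <= tol:
            return
        bps.add(i + k)
        split(i, i + k)
        split(i + k, j)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        split(0, n - 1)
    finally:
        sys.setrecursionlimit(old)
    return sorted(bps)


# ---------------------------------------------------------------------------
# segment assembly, classification, merging

def _build(w: _Windows, bps: list[int], threshold: float):
    segs = []
    for a, b in zip(bps[:-1], bps[1:]):
        slope, x_a, x_b = w.fit(a, b)
        segs.append([a, b, slope, x_a, x_b, classify_slope(slope * S_PER_MIN, threshold)])
    return segs


def _refit(w: _Windows, seg, threshold):
    a, b = seg[0], seg[1]
    slope, x_a, x_b = w.fit(a, b)
    return [a, b, slope, x_a, x_b, classify_slope(slope * S_PER_MIN, threshold)]


def _merge_same_class(w, segs, threshold):
    out = []
    for seg in segs:
        if out and out[-1][5] == seg[5]:
            out[-1] = _refit(w, [out[-1][0], seg[1]], threshold)
        else:
            out.append(seg)
    return out


def _violates(seg, params: SegmentationParams) -> bool:
    n = seg[1] - seg[0] + 1
    amp = abs(seg[4] - seg[3])
    phase = seg[5]
    if phase == PAUSE:
        return n < params.min_segment_frames
    if phase == SHRINK:
        return amp < params.min_event_length
    return n < params.min_segment_frames and amp < params.min_event_length


def _absorb(w, segs, params, threshold):
    """Iteratively merge spurious short/small segments into the neighbour
    whose velocity is most similar, reclassifying as we go."""
    for _ in range(10 * len(segs) + 10):
        segs = _merge_same_class(w, segs, threshold)
        if len(segs) <= 1:
            break
        bad = [k for k, s in enumerate(segs) if _violates(s, params)]
        if not bad:
            break
        # absorb the smallest-amplitude offender first
        k = min(bad, key=lambda k: abs(segs[k][4] - segs[k][3]))
        if k == 0:
            nb = 1
        elif k == len(segs) - 1:
            nb = k - 1
        else:
            nb = k - 1 if abs(segs[k - 1][2] - segs[k][2]) <= abs(segs[k + 1][2] - segs[k][2]) else k + 1
        lo, hi = min(k, nb), max(k, nb)
        merged = _refit(w, [segs[lo][0], segs[hi][1]], threshold)
        segs = segs[:lo] + [merged] + segs[hi + 1 :]
    return _merge_same_class(w, segs, threshold)


def _fill_gaps(times, positions, max_gap):
    """Linear interpolation across NaN runs of <= max_gap frames; longer
    runs split the trace into independently segmented chunks."""
    pos = positions.copy()
    isnan = ~np.isfinite(pos)
    if not isnan.any():
        return [(times, pos)]
    chunks = []
    idx = np.flatnonzero(~isnan)
    if idx.size == 0:
        raise ValueError("trace has no finite samples")
    # identify NaN runs
    runs = []
    k = 0
    n = len(pos)
    while k < n:
        if isnan[k]:
            j = k
            while j < n and isnan[j]:
                j += 1
            runs.append((k, j))
            k = j
        else:
            k += 1
    cut_points = [0]
    for a, b in runs:
        if b - a <= max_gap and a > 0 and b < n:
            pos[a:b] = np.interp(times[a:b], [times[a - 1], times[b]], [pos[a - 1], pos[b]])
        else:
            cut_points.extend([a, b])
    cut_points.append(n)
    for a, b in zip(cut_points[::2], cut_points[1::2]):
        seg_ok = np.isfinite(pos[a:b])
        if seg_ok.sum() >= 4:
            sel = slice(a, b)
            keep = np.isfinite(pos[sel])
            chunks.append((times[sel][keep], pos[sel][keep]))
    if not chunks:
        raise ValueError("no usable stretch of finite samples")
    return chunks


def segment_trace(
    trace: EndTrace,
    params: SegmentationParams | None = None,
    method: str = "penalized",
) -> list[PhaseSegment]:
    """Partition an end trace into classified growth/shrink/pause segments.

    Adjacent segments share their boundary sample, so the returned
    segments are contiguous in time.  Segment endpoints are taken from the
    per-segment least-squares line (interior-trimmed for long segments),
    so ``PhaseSegment.slope`` is the fitted velocity.
    """
    params = params or SegmentationParams()
    if trace.times.size < 2 * params.min_segment_frames:
        raise ValueError("trace too short to segment")
    threshold = params.threshold(trace.end)
    out: list[PhaseSegment] = []
    for t, x in _fill_gaps(trace.times, trace.positions, params.max_gap_frames):
        w = _Windows(t, x)
        if method == "penalized":
            beta = params.penalty
            if beta is None:
                sigma = _estimate_noise(x)
                beta = max(
                    params.penalty_factor * sigma**2 * np.log(len(x)),
                    1e-9 * max(float(np.var(x)), 1.0),
                )
            bps = _dp_breakpoints(w, beta)
        elif method == "recursive":
            bps = _recursive_breakpoints(w, params.residual_tol)
        else:
            raise ValueError(f"unknown method {method!r}")
        segs = _build(w, bps, threshold)
        segs = _absorb(w, segs, params, threshold)
        # refine boundaries, reclassify on pure interior samples, repeat:
        # the shared boundary samples straddle transitions and would
        # otherwise bias (or, if trimmed, noise up) short-segment slopes
        for _ in range(3):
            bounds_t, _ = _refined_bounds(t, segs)
            changed = False
            for k, seg in enumerate(segs):
                cls = _interior_class(w, t, seg, bounds_t[k], bounds_t[k + 1], threshold)
                if cls != seg[5]:
                    segs[k][5] = cls
                    changed = True
            if not changed:
                break
            segs = _absorb(w, segs, params, threshold)
        out.extend(_to_phase_segments(t, segs))
    return out


def _interior_class(w, t, seg, t_lo, t_hi, threshold):
    """Classify a segment by the LSQ slope of the samples strictly inside
    its refined boundaries (those samples are free of phase mixing)."""
    a, b = seg[0], seg[1]
    idx = np.arange(a, b + 1)
    inside = idx[(t[idx] > t_lo - 1e-9) & (t[idx] < t_hi + 1e-9)]
    if inside.size >= 3:
        tt = t[inside]
        xx = w.xraw[inside]
        tc = tt - tt.mean()
        denom = float(tc @ tc)
        slope = float(tc @ (xx - xx.mean())) / denom if denom > 0 else 0.0
    elif t_hi > t_lo:
        slope = seg[2]
    else:
        slope = seg[2]
    return classify_slope(slope * S_PER_MIN, threshold)


def _refined_bounds(t, segs):
    """Boundary times/positions from intersections of adjacent fitted lines."""
    n = len(segs)
    bounds_t = [t[segs[0][0]]]
    bounds_x = [segs[0][3]]
    for k in range(n - 1):
        a1, b1, m1, xa1, xb1, _ = segs[k]
        a2, b2, m2, xa2, xb2, _ = segs[k + 1]
        tb = t[b1]
        t_lo = max(t[max(b1 - 1, a1)], bounds_t[-1] + 1e-6)
        t_hi = t[min(b1 + 1, b2)] - 1e-6
        if abs(m1 - m2) > 1e-12:
            # line k: x = xb1 + m1 (t - tb); line k+1: x = xa2 + m2 (t - tb)
            t_star = tb + (xa2 - xb1) / (m1 - m2)
            t_star = float(np.clip(t_star, t_lo, t_hi))
        else:
            t_star = tb
        bounds_t.append(t_star)
        bounds_x.append(xb1 + m1 * (t_star - tb))
    bounds_t.append(t[segs[-1][1]])
    bounds_x.append(segs[-1][4])
    return bounds_t, bounds_x


def _to_phase_segments(t, segs) -> list[PhaseSegment]:
    """Convert fitted index-range segments to PhaseSegments with
    intersection-refined boundaries (accurate event durations/amplitudes)."""
    bounds_t, bounds_x = _refined_bounds(t, segs)
    out = []
    for k, (a, b, m, xa, xb, phase) in enumerate(segs):
        t0, t1 = bounds_t[k], bounds_t[k + 1]
        if t1 <= t0:  # degenerate after clamping; keep the sample grid
            t0, t1 = t[a], t[b]
        out.append(PhaseSegment(t0, t1, max(bounds_x[k], 0.0), max(bounds_x[k + 1], 0.0), phase))
    return out
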