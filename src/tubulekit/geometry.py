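"""B-tubule curvature analysis: O-X rigid registration, per-triplet
circumradii, algebraic circle fitting, the two-circle radius of annular
density slices, and group comparison.

All coordinates are in nanometres.  The canonical registration frame puts
the outer junction X at the origin and the A-tubule centre O on the
negative x-axis, so the B-tubule extends into x > 0.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AlignedTrace, CurvatureResult, TubuleTrace

__all__ = [
    "register_trace",
    "local_radii",
    "mean_radius",
    "fit_circle",
    "two_circle_radius",
    "curvature_result",
    "compare_curvature_groups",
    "overlay_traces",
    "ring_edge_points",
    "measure_ring_radius",
]


def register_trace(trace: TubuleTrace, tol: float = 1e-9) -> AlignedTrace:
    """Rigid transform (rotation + translation, no reflection or scaling)
    mapping X to the origin and O onto the negative x-axis."""
    d = trace.O - trace.X
    norm = np.hypot(*d)
    if norm < tol:
        raise ValueError("|O - X| below numeric tolerance")
    # rotate the O-X direction onto the negative x-axis
    angle = np.pi - np.arctan2(d[1], d[0])
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    shift = -R @ trace.X
    pts = trace.points @ R.T + shift
    return AlignedTrace(points=pts, angle=angle, shift=shift, source=trace)


def local_radii(points: np.ndarray) -> np.ndarray:
    """Circumradius of each consecutive point triplet (nm).

    Collinear triplets yield ``inf``.  Duplicate consecutive points are
    rejected.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) coordinate array")
    if np.any(np.all(np.isclose(np.diff(p, axis=0), 0), axis=1)):
        raise ValueError("duplicate consecutive points")
    a = np.linalg.norm(p[1:-1] - p[:-2], axis=1)
    b = np.linalg.norm(p[2:] - p[1:-1], axis=1)
    c = np.linalg.norm(p[2:] - p[:-2], axis=1)
    cross = (p[1:-1, 0] - p[:-2, 0]) * (p[2:, 1] - p[:-2, 1]) - (
        p[1:-1, 1] - p[:-2, 1]
    ) * (p[2:, 0] - p[:-2, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore"):
        return np.where(area2 > 0, a * b * c / (2.0 * area2), np.inf)


def mean_radius(points: np.ndarray) -> float:
    """Mean curvature radius along a trace: the inverse of the mean
    per-triplet curvature (harmonic mean of the finite circumradii).

    Equal to the circumradius exactly when the points lie on a circle.
    Averaging in the curvature domain keeps the estimator consistent under
    coordinate jitter, where near-collinear triplets make the raw
    circumradii heavy-tailed and their arithmetic mean diverge.
    """
    r = local_radii(points)
    finite = r[np.isfinite(r)]
    if finite.size == 0:
        return np.nan
    return float(1.0 / np.mean(1.0 / finite))


def fit_circle(points: np.ndarray):
    """Algebraic (Kasa) least-squares circle: direct, non-iterative,
    exact when the points lie on a circle.  Returns (centre, radius)."""
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) coordinate array")
    x, y = p[:, 0], p[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points: circle is undefined")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    return np.array([cx, cy]), float(np.sqrt(r2))


def two_circle_radius(r_outer: float, r_inner: float) -> float:
    """Mid-wall radius from the external- and internal-surface circles."""
    if not (r_outer > r_inner > 0):
        raise ValueError("need r_outer > r_inner > 0")
    return 0.5 * (r_outer + r_inner)


def curvature_result(
    trace: TubuleTrace,
    method: str = "triplet_mean",
) -> CurvatureResult:
    """Curvature radii of a B-tubule trace.

    ``triplet_mean`` (default) reports the inverse mean curvature over
    consecutive point triplets; ``circle_fit`` the radius of a single
    algebraic circle fit.  Both are invariant to rigid motions of the
    input and exact on perfect circles.
    """
    r = local_radii(trace.points)
    if method == "triplet_mean":
        mean = mean_radius(trace.points)
    elif method == "circle_fit":
        _, mean = fit_circle(trace.points)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CurvatureResult(local_radii=r, mean_radius=mean, method=method,
                           label=trace.label, group=trace.group)


def compare_curvature_groups(
    group_a: Sequence[CurvatureResult],
    group_b: Sequence[CurvatureResult],
    names: tuple = ("A", "B"),
) -> dict:
    """Per-group mean +/- SD of the mean radii and the percent change
    of group B relative to group A; raw values are included so that
    significance testing can be done with standard statistics tooling."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    va = np.array([g.mean_radius for g in group_a], dtype=float)
    vb = np.array([g.mean_radius for g in group_b], dtype=float)
    out = {}
    for name, v in zip(names, (va, vb)):
        out[name] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
            "values": v.tolist(),
        }
    out["percent_change"] = float((vb.mean() - va.mean()) / va.mean() * 100.0)
    return out


def overlay_traces(aligned: Sequence[AlignedTrace], plot_path: Optional[str] = None) -> pd.DataFrame:
    """Common-frame coordinate table of registered traces (one row per
    point); optionally renders the overlay to ``plot_path``."""
    if not aligned:
        raise ValueError("need at least one aligned trace")
    rows = []
    for k, tr in enumerate(aligned):
        label = tr.source.label if tr.source is not None else str(k)
        for i, (x, y) in enumerate(tr.points):
            rows.append({"trace": label or str(k), "point_index": i, "x_nm": x, "y_nm": y})
    df = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        for _, sub in df.groupby("trace"):
            ax.plot(sub["x_nm"], sub["y_nm"], "-o", ms=2, lw=0.8, alpha=0.7)
        ax.plot(0, 0, "bs", ms=6, label="outer junction (X)")
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("y (nm)")
        ax.set_aspect("equal")
        ax.legend(frameon=False, fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


# ---------------------------------------------------------------------------
# two-circle measurement on annular density slices

def ring_edge_points(
    image: np.ndarray,
    nm_per_px: float,
    n_rays: int = 72,
    level_frac: float = 0.5,
):
    """Outer- and inner-surface points of a bright ring in a 2-D slice.

    Radial intensity profiles are cast from the intensity centroid; on each
    ray the outer (resp. inner) surface is the outermost (innermost)
    crossing of ``level_frac`` of the ring's peak-to-background range,
    localised by linear interpolation.  Returns (outer_points, inner_points)
    in nm, suitable for :func:`fit_circle`.
    """
    from scipy.ndimage import map_coordinates

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("need a 2-D slice")
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    w = img - img.min()
    cy = (yy * w).sum() / w.sum()
    cx = (xx * w).sum() / w.sum()
    r_max = min(img.shape) / 2.0 - 1
    radii = np.arange(0.0, r_max, 0.25)
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    outer, inner = [], []
    lo = np.quantile(img, 0.05)
    hi = np.quantile(img, 0.99)
    level = lo + level_frac * (hi - lo)
    for th in angles:
        ys = cy + radii * np.sin(th)
        xs = cx + radii * np.cos(th)
        prof = map_coordinates(img, [ys, xs], order=1, mode="nearest")
        above = prof >= level
        if not above.any():
            continue
        k_out = np.flatnonzero(above)[-1]
        k_in = np.flatnonzero(above)[0]
        for k, bucket, direction in ((k_out, outer, 1), (k_in, inner, -1)):
            k2 = k + direction
            if 0 <= k2 < len(prof) and prof[k] != prof[k2]:
                frac = (prof[k] - level) / (prof[k] - prof[k2])
                r = radii[k] + frac * (radii[k2] - radii[k])
            else:
                r = radii[k]
            bucket.append((cx + r * np.cos(th), cy + r * np.sin(th)))
    if len(outer) < 3 or len(inner) < 3:
        raise ValueError("could not trace ring surfaces")
    return np.asarray(outer) * nm_per_px, np.asarray(inner) * nm_per_px


def measure_ring_radius(image: np.ndarray, nm_per_px: float, **kwargs) -> dict:
    """Two-circle mid-wall radius of an annular slice (nm): circles are
    fitted to the external and internal surface points and averaged."""
    outer, inner = ring_edge_points(image, nm_per_px, **kwargs)
    _, r_out = fit_circle(outer)
    _, r_in = fit_circle(inner)
    return {
        "r_outer": r_out,
        "r_inner": r_in,
        "radius": two_circle_radius(r_out, r_in),
    }
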