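"""Dynamic-instability parameter estimation and event classification.

Definitions follow standard TIRF kymograph practice:

- growth / shrinkage speed: unweighted mean of per-event fitted slopes;
- catastrophe frequency ``f_cat``: transitions into shrinkage divided by
  total growth time;
- rescue frequency ``f_res``: transitions out of shrinkage (into growth
  or pause) divided by total shrinkage time;
- pause frequency ``f_pause``: pause count divided by total non-shrink
  (growth + pause) time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GROWTH, PAUSE, SHRINK, S_PER_MIN, PhaseSegment

__all__ = [
    "DynamicsSummary",
    "DilutionCriteria",
    "JunctionTolerance",
    "estimate_dynamics",
    "classify_dilution",
    "classify_rescues",
    "summarize_architecture",
    "pool_summaries",
    "truncation_corrected_count",
]


@dataclass
class DynamicsSummary:
    """Per-microtubule dynamics parameters plus the raw event lists."""

    v_g: float
    v_s: float
    f_cat: float
    f_res: float
    f_pause: float
    pause_durations: list = field(default_factory=list)
    n_catastrophes: int = 0
    n_rescues: int = 0
    n_pauses: int = 0
    t_growth: float = 0.0   # s
    t_shrink: float = 0.0   # s
    t_pause: float = 0.0    # s
    t_shrink_exposed: float = 0.0  # s, shrink time counted toward f_res
    shrink_amplitudes: list = field(default_factory=list)
    growth_durations: list = field(default_factory=list)
    n_sgs_triples: int = 0
    rescue_positions: list = field(default_factory=list)
    trace_id: Optional[str] = None
    end: str = "plus"
    flags: dict = field(default_factory=dict)


@dataclass
class DilutionCriteria:
    """Numeric criteria for the three post-dilution behaviours."""

    epsilon_loss: float = 0.5        # um
    shrink_time_fraction: float = 0.9
    window: float = 1800.0           # s after dilution

    def __post_init__(self) -> None:
        if self.epsilon_loss <= 0:
            raise ValueError("epsilon_loss must be > 0")
        if not (0 < self.shrink_time_fraction <= 1):
            raise ValueError("shrink_time_fraction must lie in (0, 1]")


@dataclass
class JunctionTolerance:
    delta: float = 0.2  # um

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def _check_contiguous(segments: Sequence[PhaseSegment]) -> None:
    for a, b in zip(segments[:-1], segments[1:]):
        if abs(a.t_end - b.t_start) > 1e-6:
            raise ValueError("segments must be contiguous")


def estimate_dynamics(
    segments: Sequence[PhaseSegment],
    observation_time: Optional[float] = None,
    *,
    trace_id: Optional[str] = None,
    end: str = "plus",
    min_speed_event_duration: float = 0.0,
    seed_exclusion_um: Optional[float] = None,
) -> DynamicsSummary:
    """Estimate dynamic-instability parameters from classified segments.

    ``min_speed_event_duration`` (s) excludes very short events from the
    *speed* means (their fitted slopes mix adjacent phases) without
    touching the event counts.  ``seed_exclusion_um``, when set, applies
    the seeded-assay convention that regrowth at the seed is not a lattice
    rescue: rescues at positions below the cutoff are discarded *and* the
    matching shrink exposure time below the cutoff is removed from the
    rescue-frequency denominator, which keeps the estimator unbiased.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments")
    _check_contiguous(segments)

    t_phase = {GROWTH: 0.0, SHRINK: 0.0, PAUSE: 0.0}
    g_slopes, s_slopes = [], []
    pauses, shrink_amps, rescue_pos, growth_durs = [], [], [], []
    n_cat = n_res = n_pause = n_sgs = 0
    t_shrink_exposed = 0.0
    flags: dict = {}

    for k, seg in enumerate(segments):
        t_phase[seg.phase] += seg.duration
        if seg.phase == GROWTH:
            growth_durs.append(seg.duration)
            if seg.duration >= min_speed_event_duration:
                g_slopes.append(seg.slope)
        if seg.phase == SHRINK:
            shrink_amps.append(abs(seg.dx))
            if seg.duration >= min_speed_event_duration:
                s_slopes.append(abs(seg.slope))
            if seed_exclusion_um is not None:
                hi, lo = max(seg.x_start, seg.x_end), min(seg.x_start, seg.x_end)
                if hi > seed_exclusion_um:
                    frac = (hi - max(lo, seed_exclusion_um)) / max(hi - lo, 1e-12)
                    t_shrink_exposed += seg.duration * frac
            else:
                t_shrink_exposed += seg.duration
        if seg.phase == PAUSE:
            pauses.append(seg.duration)
            n_pause += 1
        if k > 0:
            prev = segments[k - 1]
            if seg.phase == SHRINK and prev.phase != SHRINK:
                n_cat += 1
            if k >= 2 and seg.phase == SHRINK and prev.phase == GROWTH \
                    and segments[k - 2].phase == SHRINK:
                n_sgs += 1
            if prev.phase == SHRINK and seg.phase != SHRINK:
                x_res = seg.x_start
                if seed_exclusion_um is None or x_res > seed_exclusion_um:
                    n_res += 1
                    rescue_pos.append(x_res)

    v_g = float(np.mean(g_slopes)) if g_slopes else 0.0
    v_s = float(np.mean(s_slopes)) if s_slopes else 0.0
    if t_phase[GROWTH] > 0:
        f_cat = n_cat / (t_phase[GROWTH] / S_PER_MIN)
    else:
        f_cat = 0.0
        if n_cat:
            flags["f_cat_undefined"] = True
    if t_shrink_exposed > 0:
        f_res = n_res / (t_shrink_exposed / S_PER_MIN)
    else:
        f_res = 0.0
        if n_res:
            flags["f_res_undefined"] = True
    t_np = t_phase[GROWTH] + t_phase[PAUSE]
    f_pause = n_pause / (t_np / S_PER_MIN) if t_np > 0 else 0.0

    return DynamicsSummary(
        v_g=v_g, v_s=v_s, f_cat=f_cat, f_res=f_res, f_pause=f_pause,
        pause_durations=pauses, n_catastrophes=n_cat, n_rescues=n_res,
        n_pauses=n_pause, t_growth=t_phase[GROWTH], t_shrink=t_phase[SHRINK],
        t_pause=t_phase[PAUSE], t_shrink_exposed=t_shrink_exposed,
        shrink_amplitudes=shrink_amps, growth_durations=growth_durs,
        n_sgs_triples=n_sgs,
        rescue_positions=rescue_pos, trace_id=trace_id, end=end, flags=flags,
    )


def truncation_corrected_count(values, v_min: float):
    """Detection-limit correction for exponentially distributed event sizes.

    Events below ``v_min`` (duration or amplitude) escape detection.  With
    exponential sizes, the observed values above the limit estimate the
    scale (``tau = mean(v - v_min)``, the left-truncation MLE) and the
    undetected fraction is ``1 - exp(-v_min / tau)``.  Returns
    ``(corrected_count, n_observed, tau, mean_below)`` where ``mean_below``
    is the expected size of an undetected event.
    """
    v = np.asarray([x for x in values if x >= v_min], dtype=float)
    n0 = v.size
    if n0 == 0:
        return 0.0, 0, np.nan, np.nan
    tau = float(np.mean(v - v_min))
    if tau <= 0:
        return float(n0), n0, 0.0, 0.0
    p_detect = np.exp(-v_min / tau)
    r = v_min / tau
    # E[v | v < v_min] for an exponential truncated above at v_min
    mean_below = tau - v_min * np.exp(-r) / max(1.0 - np.exp(-r), 1e-300)
    return n0 / p_detect, n0, tau, mean_below


def classify_dilution(
    segments: Sequence[PhaseSegment],
    t_switch: float,
    criteria: DilutionCriteria | None = None,
) -> str:
    """Assign a post-dilution trace to one of the three stability classes.

    Precedence: ``persistent_pause`` (no shrinkage and negligible length
    loss) > ``slow_depolymerisation`` (shrinkage occupies most of the
    window) > ``pause_with_catastrophes``.
    """
    criteria = criteria or DilutionCriteria()
    t_hi = t_switch + criteria.window
    t_end = max(s.t_end for s in segments)
    if t_end < t_hi - 1e-9:
        import warnings

        warnings.warn("analysis window extends past trace end; truncated", stacklevel=2)
        t_hi = t_end
    window = t_hi - t_switch
    loss = 0.0
    t_by_phase = {GROWTH: 0.0, SHRINK: 0.0, PAUSE: 0.0}
    n_shrink = n_pause = 0
    for seg in segments:
        a, b = max(seg.t_start, t_switch), min(seg.t_end, t_hi)
        if b <= a:
            continue
        frac = (b - a) / seg.duration
        t_by_phase[seg.phase] += b - a
        loss -= seg.dx * frac
        if seg.phase == SHRINK:
            n_shrink += 1
        elif seg.phase == PAUSE:
            n_pause += 1
    if n_shrink == 0 and loss < criteria.epsilon_loss:
        return "persistent_pause"
    if t_by_phase[SHRINK] >= criteria.shrink_time_fraction * window:
        return "slow_depolymerisation"
    return "pause_with_catastrophes"


def classify_rescues(
    segments: Sequence[PhaseSegment],
    junction_x: float,
    tol: JunctionTolerance | None = None,
) -> dict:
    """Count rescues at versus beyond a stable/dynamic lattice junction.

    A rescue is any transition out of shrinkage; its position is compared
    with ``junction_x`` at tolerance ``tol.delta``.
    """
    if junction_x < 0:
        raise ValueError("junction_x must be >= 0")
    tol = tol or JunctionTolerance()
    records = []
    for prev, seg in zip(segments[:-1], segments[1:]):
        if prev.phase == SHRINK and seg.phase != SHRINK:
            x = seg.x_start
            where = "at_junction" if abs(x - junction_x) <= tol.delta else "beyond"
            records.append({"t": seg.t_start, "x": x, "class": where})
    return {
        "at_junction": sum(r["class"] == "at_junction" for r in records),
        "beyond": sum(r["class"] == "beyond" for r in records),
        "records": records,
    }


def summarize_architecture(lengths: dict) -> dict:
    """Percentage of total measured length per architecture class."""
    totals = {k: float(np.sum(v)) for k, v in lengths.items()}
    if any(t < 0 for t in totals.values()):
        raise ValueError("lengths must be >= 0")
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("need at least one positive length")
    return {k: 100.0 * t / grand for k, t in totals.items()}


_PARAMS = ("v_g", "v_s", "f_cat", "f_res", "f_pause")


def pool_summaries(
    summaries: Sequence[DynamicsSummary],
    experiment_ids: Optional[Sequence] = None,
) -> dict:
    """Group report: event-level mean +/- SD per parameter and
    per-experiment means, as in standard TIRF dynamics figures."""
    if not summaries:
        raise ValueError("need at least one summary")
    if experiment_ids is None:
        experiment_ids = [0] * len(summaries)
    df = pd.DataFrame(
        {
            "experiment": list(experiment_ids),
            **{p: [getattr(s, p) for s in summaries] for p in _PARAMS},
        }
    )
    report = {"n_microtubules": len(summaries), "n_experiments": df["experiment"].nunique()}
    for p in _PARAMS:
        vals = df[p].to_numpy(dtype=float)
        report[p] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
            "per_experiment_mean": df.groupby("experiment")[p].mean().to_dict(),
        }
    all_pauses = [d for s in summaries for d in s.pause_durations]
    report["pause_durations_s"] = {
        "mean": float(np.mean(all_pauses)) if all_pauses else np.nan,
        "sd": float(np.std(all_pauses, ddof=1)) if len(all_pauses) > 1 else 0.0,
        "n": len(all_pauses),
    }
    return report
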