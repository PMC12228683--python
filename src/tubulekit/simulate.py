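"""Event-driven simulation of microtubule dynamic instability.

The end is a three-state continuous-time Markov chain
(growth / shrink / pause) with exponential phase durations and
piecewise-linear motion at +v_g, -v_s or 0.  The seed acts as an
absorbing floor: a shrinking end reaching x = 0 instantly resumes
growth, mimicking regrowth from a stable GMPCPP seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import GROWTH, PAUSE, PHASES, SHRINK, S_PER_MIN, DynParams, EndTrace, PhaseSegment

__all__ = ["simulate_end", "simulate_dilution", "simulate_junction"]


def _as_rng(rng_seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(rng_seed)


def _velocity(params: DynParams, phase: str) -> float:
    """Velocity in um/s for a phase."""
    if phase == GROWTH:
        return params.v_g / S_PER_MIN
    if phase == SHRINK:
        return -params.v_s / S_PER_MIN
    return 0.0


def _exit_rates(params: DynParams, phase: str):
    """(total exit rate in 1/s, destinations, branch rates)."""
    if phase == GROWTH:
        dests, rates = (SHRINK, PAUSE), (params.f_cat, params.f_gp)
    elif phase == SHRINK:
        dests, rates = (GROWTH,), (params.f_res,)
    else:
        dests, rates = (GROWTH, SHRINK), (params.f_pg, params.f_ps)
    total = sum(rates) / S_PER_MIN
    return total, dests, np.asarray(rates, dtype=float)


def _truth_label(params: DynParams, phase: str) -> str:
    """Label a phase by its actual slope sign (a v=0 phase is a pause)."""
    v = _velocity(params, phase)
    if v > 0:
        return GROWTH
    if v < 0:
        return SHRINK
    return PAUSE


def _run_ctmc(params, t0, t_end, x0, phase, rng, floor_x=0.0, floor_rescue_p=1.0):
    """Advance the chain from (t0, x0, phase) to t_end.

    Returns (segments, knot_t, knot_x, terminated_at).  ``floor_rescue_p``
    is the probability that a shrink phase reaching ``floor_x`` converts
    to growth; otherwise the trajectory terminates there.
    """
    segments: list[PhaseSegment] = []
    knot_t, knot_x = [t0], [x0]
    t, x = t0, x0
    terminated_at = None
    while t < t_end:
        v = _velocity(params, phase)
        total, dests, rates = _exit_rates(params, phase)
        dwell = rng.exponential(1.0 / total) if total > 0 else np.inf
        # time to reach the floor during shrinkage
        t_floor = (x - floor_x) / (-v) if v < 0 else np.inf
        t_next = min(t + dwell, t + t_floor, t_end)
        x_next = x + v * (t_next - t)
        if t_next > t:
            label = _truth_label(params, phase)
            if segments and segments[-1].phase == label:
                prev = segments[-1]
                segments[-1] = PhaseSegment(prev.t_start, t_next, prev.x_start, x_next, label)
            else:
                segments.append(PhaseSegment(t, t_next, x, x_next, label))
            knot_t.append(t_next)
            knot_x.append(x_next)
        if t_next >= t_end:
            t, x = t_next, x_next
            break
        if t_floor < dwell:  # hit the floor mid-shrink
            x_next = floor_x
            if floor_rescue_p >= 1.0 or rng.random() < floor_rescue_p:
                phase = GROWTH
            else:
                terminated_at = t_next
                t, x = t_next, x_next
                break
        else:
            phase = dests[rng.choice(len(rates), p=rates / rates.sum())] if len(rates) > 1 else dests[0]
        t, x = t_next, x_next
    return segments, knot_t, knot_x, terminated_at


def _sample(knot_t, knot_x, times):
    return np.interp(times, np.asarray(knot_t), np.asarray(knot_x))


def simulate_end(
    params: DynParams,
    duration: float,
    x0: float = 0.0,
    rng_seed: int = 0,
    sample_dt: float = 2.0,
    initial_phase: str = GROWTH,
    rng: Optional[np.random.Generator] = None,
) -> EndTrace:
    """Simulate one end for ``duration`` seconds, sampled every ``sample_dt`` s.

    Identical ``rng_seed`` yields an identical trace.  The exact generating
    phase segments are stored in ``trace.truth``.
    """
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("duration must be finite and > 0")
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if initial_phase not in PHASES:
        raise ValueError(f"unknown initial phase {initial_phase!r}")
    rng = _as_rng(rng_seed, rng)
    segments, kt, kx, _ = _run_ctmc(params, 0.0, duration, x0, initial_phase, rng)
    times = np.arange(0.0, duration + sample_dt / 2, sample_dt)
    if not segments:  # fully static trace
        segments = [PhaseSegment(0.0, duration, x0, x0, PAUSE)]
    return EndTrace(
        times=times,
        positions=_sample(kt, kx, times),
        end=params.end,
        truth=segments,
        meta={"rng_seed": rng_seed, "x0": x0, "sample_dt": sample_dt},
    )


def simulate_dilution(
    params_pre: DynParams,
    params_post: DynParams,
    t_switch: float,
    duration: float,
    rng_seed: int = 0,
    x0: float = 0.0,
    sample_dt: float = 2.0,
    post_initial_phase: str = PAUSE,
    rng: Optional[np.random.Generator] = None,
) -> EndTrace:
    """Simulate a tubulin-dilution experiment.

    The trace evolves under ``params_pre`` until ``t_switch`` (dilution),
    then under ``params_post`` starting in ``post_initial_phase``.
    """
    if not (0 < t_switch < duration):
        raise ValueError("need 0 < t_switch < duration")
    rng = _as_rng(rng_seed, rng)
    seg1, kt1, kx1, _ = _run_ctmc(params_pre, 0.0, t_switch, x0, GROWTH, rng)
    x_sw = kx1[-1]
    seg2, kt2, kx2, _ = _run_ctmc(params_post, t_switch, duration, x_sw, post_initial_phase, rng)
    times = np.arange(0.0, duration + sample_dt / 2, sample_dt)
    segments = seg1 + seg2
    if not segments:
        segments = [PhaseSegment(0.0, duration, x0, x0, PAUSE)]
    return EndTrace(
        times=times,
        positions=_sample(kt1 + kt2[1:], kx1 + kx2[1:], times),
        end=params_pre.end,
        truth=segments,
        t_switch=t_switch,
        meta={"rng_seed": rng_seed, "x_switch": x_sw},
    )


def simulate_junction(
    params_dyn: DynParams,
    junction_x: float,
    p_rescue_at_junction: float,
    duration: float,
    rng_seed: int = 0,
    sample_dt: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> EndTrace:
    """Simulate a dynamic extension grown from a stable lattice junction.

    The extension grows and shrinks distal to ``junction_x``.  A shrink
    phase reaching the junction converts to growth with probability
    ``p_rescue_at_junction`` (a rescue *at* the junction); otherwise the
    trajectory terminates there.  Lattice rescues away from the junction
    arise from ``params_dyn.f_res`` as usual.
    """
    if junction_x < 0:
        raise ValueError("junction_x must be >= 0")
    if not (0.0 <= p_rescue_at_junction <= 1.0):
        raise ValueError("p_rescue_at_junction must lie in [0, 1]")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = _as_rng(rng_seed, rng)
    segments, kt, kx, terminated_at = _run_ctmc(
        params_dyn, 0.0, duration, junction_x, GROWTH, rng,
        floor_x=junction_x, floor_rescue_p=p_rescue_at_junction,
    )
    t_last = terminated_at if terminated_at is not None else duration
    times = np.arange(0.0, t_last + sample_dt / 2, sample_dt)
    if not segments:
        segments = [PhaseSegment(0.0, duration, junction_x, junction_x, PAUSE)]
    return EndTrace(
        times=times,
        positions=_sample(kt, kx, times),
        end=params_dyn.end,
        truth=segments,
        junction_x=junction_x,
        meta={"rng_seed": rng_seed, "terminated_at": terminated_at},
    )


def stationary_distribution(params: DynParams) -> dict:
    """Stationary phase occupancy of the three-state chain (growth/shrink/pause).

    Solved from the generator matrix; requires the chain to be irreducible
    (each phase reachable and leavable).
    """
    Q = np.array(
        [
            [-(params.f_cat + params.f_gp), params.f_cat, params.f_gp],
            [params.f_res, -params.f_res, 0.0],
            [params.f_pg, params.f_ps, -(params.f_pg + params.f_ps)],
        ]
    )
    A = np.vstack([Q.T, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return {GROWTH: pi[0], SHRINK: pi[1], PAUSE: pi[2]}
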