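"""Dynamics estimation, dilution/junction classification, architecture
summaries and pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tubulekit import (
    DilutionCriteria,
    DynParams,
    JunctionTolerance,
    SegmentationParams,
    classify_dilution,
    classify_rescues,
    estimate_dynamics,
    pool_summaries,
    segment_trace,
    simulate_junction,
    summarize_architecture,
)
from tubulekit.core import GROWTH, PAUSE, SHRINK, PhaseSegment
from tubulekit.dynamics import truncation_corrected_count
from tubulekit.pipeline import (
    pooled_dynamics,
    simulate_dilution_regime,
    simulate_render_analyze,
)


def seg(t0, t1, x0, x1, ph):
    return PhaseSegment(t0, t1, x0, x1, ph)


class TestEstimate:
    def test_catastrophe_frequency_arithmetic(self):
        # 3 transitions into shrink over 10 min of growth -> 0.3 / min
        segs = [
            seg(0, 200, 0, 4, GROWTH), seg(200, 210, 4, 1, SHRINK),
            seg(210, 410, 1, 5, GROWTH), seg(410, 420, 5, 2, SHRINK),
            seg(420, 620, 2, 6, GROWTH), seg(620, 630, 6, 3, SHRINK),
        ]
        s = estimate_dynamics(segs)
        assert s.n_catastrophes == 3
        assert s.f_cat == pytest.approx(3 / (600 / 60))
        assert s.n_rescues == 2  # last shrink is censored by the movie end
        assert s.f_res == pytest.approx(2 / (30 / 60))

    def test_single_growth_segment_flags_undefined_rescue(self):
        s = estimate_dynamics([seg(0, 600, 0, 12, GROWTH)])
        assert s.f_cat == 0.0
        assert s.n_rescues == 0 and s.f_res == 0.0
        assert not s.flags  # nothing undefined: zero events over zero time

    def test_pause_frequency_uses_nonshrink_time(self):
        segs = [
            seg(0, 300, 0, 6, GROWTH), seg(300, 360, 6, 6, PAUSE),
            seg(360, 660, 6, 12, GROWTH),
        ]
        s = estimate_dynamics(segs)
        assert s.n_pauses == 1
        assert s.f_pause == pytest.approx(1 / (660 / 60))
        assert s.pause_durations == [60.0]

    def test_rescue_into_pause_counts_as_rescue(self):
        segs = [
            seg(0, 300, 0, 6, GROWTH), seg(300, 310, 6, 3, SHRINK),
            seg(310, 370, 3, 3, PAUSE),
        ]
        s = estimate_dynamics(segs)
        assert s.n_rescues == 1

    def test_seed_exclusion_censors_rescues_and_exposure(self):
        segs = [
            seg(0, 300, 0, 6, GROWTH), seg(300, 320, 6, 0.0, SHRINK),
            seg(320, 620, 0.0, 6, GROWTH),
        ]
        plain = estimate_dynamics(segs)
        excl = estimate_dynamics(segs, seed_exclusion_um=0.25)
        assert plain.n_rescues == 1 and excl.n_rescues == 0
        # exposure shortened by exactly the time spent below the cutoff
        assert excl.t_shrink_exposed == pytest.approx(20 * (6 - 0.25) / 6)

    def test_noncontiguous_segments_rejected(self):
        with pytest.raises(ValueError):
            estimate_dynamics([seg(0, 10, 0, 1, GROWTH), seg(20, 30, 1, 2, GROWTH)])

    def test_parameter_recovery_trace_only(self):
        """Pooled estimates from segmentation of exact sampled traces fall
        within 3 SE of the generating rates."""
        p = DynParams(v_g=1.2, v_s=18, f_cat=0.4, f_res=6, f_gp=0.3, f_pg=2)
        sums = simulate_render_analyze(p, 120, seed=11, render=False, x0=15.0)
        est = pooled_dynamics(sums, pause_min_s=15.0, shrink_min_amp_um=0.4, n_boot=80)
        for key, true in (("f_cat", 0.4), ("f_res", 6.0), ("f_gp", 0.3)):
            z = (est[key]["value"] - true) / est[key]["se"]
            assert abs(z) < 3, (key, est[key])
        assert est["v_g"]["value"] == pytest.approx(1.2, rel=0.05)
        assert est["v_s"]["value"] == pytest.approx(18.0, rel=0.05)


class TestTruncationCorrection:
    def test_recovers_total_count_from_truncated_exponential(self):
        rng = np.random.default_rng(0)
        tau, n, lim = 30.0, 4000, 15.0
        d = rng.exponential(tau, n)
        corr, n0, tau_hat, _ = truncation_corrected_count(d, lim)
        assert tau_hat == pytest.approx(tau, rel=0.1)
        assert corr == pytest.approx(n, rel=0.05)


class TestDilution:
    def test_constant_position_is_persistent_pause(self):
        segs = [seg(600, 2400, 10, 10, PAUSE)]
        assert classify_dilution(segs, 600.0) == "persistent_pause"

    def test_single_shrink_spanning_window(self):
        segs = [seg(600, 2400, 12, 0.5, SHRINK)]
        assert classify_dilution(segs, 600.0) == "slow_depolymerisation"

    def test_mixed_pause_and_shrink(self):
        segs = [
            seg(600, 1200, 12, 12, PAUSE), seg(1200, 1260, 12, 11, SHRINK),
            seg(1260, 2400, 11, 11, PAUSE),
        ]
        assert classify_dilution(segs, 600.0) == "pause_with_catastrophes"

    def test_window_truncation_warns(self):
        segs = [seg(600, 1200, 10, 10, PAUSE)]
        with pytest.warns(UserWarning):
            assert classify_dilution(segs, 600.0, DilutionCriteria(window=1800)) \
                == "persistent_pause"

    @pytest.mark.parametrize("regime", [
        "persistent_pause", "pause_with_catastrophes", "slow_depolymerisation",
    ])
    def test_simulated_regimes_classified(self, regime):
        sp = SegmentationParams(min_segment_frames=2)
        ok = 0
        for s in range(40):
            tr = simulate_dilution_regime(regime, rng_seed=s)
            lab = classify_dilution(segment_trace(tr, sp), tr.t_switch)
            ok += lab == regime
        assert ok >= 38


class TestJunction:
    def test_rescue_at_and_beyond(self):
        segs = [
            seg(0, 100, 2, 4, GROWTH), seg(100, 110, 4, 2.0, SHRINK),
            seg(110, 300, 2.0, 6, GROWTH), seg(300, 310, 6, 4.05, SHRINK),
            seg(310, 400, 4.05, 5, GROWTH),
        ]
        res = classify_rescues(segs, junction_x=2.0, tol=JunctionTolerance(0.2))
        assert res["at_junction"] == 1 and res["beyond"] == 1

    def test_far_rescue_is_beyond(self):
        segs = [seg(0, 10, 4, 2, SHRINK), seg(10, 100, 4.0 + 2.0, 6, GROWTH)]
        segs = [seg(0, 10, 6, 4.0, SHRINK), seg(10, 100, 4.0, 6, GROWTH)]
        res = classify_rescues(segs, junction_x=2.0)
        assert res["beyond"] == 1 and res["at_junction"] == 0

    def test_simulated_fraction_matches_truth_replay(self):
        p = DynParams(v_g=1.2, v_s=18, f_cat=0.4, f_res=0.2)
        at_t = b_t = at_a = b_a = 0
        sp = SegmentationParams(min_segment_frames=2)
        for s in range(150):
            tr = simulate_junction(p, 2.0, 0.7, 1800.0, rng_seed=s)
            rt = classify_rescues(tr.truth, 2.0)
            at_t += rt["at_junction"]; b_t += rt["beyond"]
            if len(tr.times) >= 8:
                ra = classify_rescues(segment_trace(tr, sp), 2.0)
                at_a += ra["at_junction"]; b_a += ra["beyond"]
        frac_truth = at_t / (at_t + b_t)
        frac_analysed = at_a / (at_a + b_a)
        se = np.sqrt(frac_truth * (1 - frac_truth) / (at_a + b_a))
        assert abs(frac_analysed - frac_truth) < 3 * se + 0.02


class TestArchitecture:
    def test_percentages_by_total_length(self):
        out = summarize_architecture({"singlet": [60.0], "doublet": [40.0]})
        assert out == {"singlet": 60.0, "doublet": 40.0}
        out = summarize_architecture({"singlet": [10.0, 10.0], "doublet": []})
        assert out == {"singlet": 100.0, "doublet": 0.0}

    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=8),
           st.lists(st.floats(0.1, 50), min_size=1, max_size=8),
           st.data())
    @settings(derandomize=True, max_examples=40)
    def test_invariant_to_splitting_a_length(self, a, b, data):
        base = summarize_architecture({"s": a, "d": b})
        k = data.draw(st.integers(0, len(a) - 1))
        frac = data.draw(st.floats(0.1, 0.9))
        split = a[:k] + [a[k] * frac, a[k] * (1 - frac)] + a[k + 1:]
        out = summarize_architecture({"s": split, "d": b})
        assert out["s"] == pytest.approx(base["s"])
        assert sum(out.values()) == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            summarize_architecture({"s": [0.0], "d": []})


class TestPooling:
    def test_single_summary_mean_sd(self):
        s = estimate_dynamics([seg(0, 600, 0, 12, GROWTH)])
        rep = pool_summaries([s])
        assert rep["v_g"]["mean"] == pytest.approx(1.2)
        assert rep["v_g"]["sd"] == 0.0

    def test_per_experiment_means(self):
        a = estimate_dynamics([seg(0, 600, 0, 12, GROWTH)])   # v_g 1.2
        b = estimate_dynamics([seg(0, 600, 0, 6, GROWTH)])    # v_g 0.6
        rep = pool_summaries([a, b], experiment_ids=["e1", "e2"])
        assert rep["v_g"]["per_experiment_mean"] == {"e1": 1.2, "e2": 0.6}
        assert rep["v_g"]["mean"] == pytest.approx(0.9)
        assert rep["n_experiments"] == 2
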