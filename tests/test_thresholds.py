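"""Feature values, baseline selection and the four calling thresholds."""

import math

import pytest

from labelseg import (
    ThresholdParams,
    TargetSelection,
    estimate_baseline,
    feature_value,
    high_thresholds,
    low_thresholds,
    select_high_targets,
    select_low_targets,
)
from labelseg.thresholds import NoBaselineError, rank_by_length

from conftest import make_cluster, make_segment


class TestFeatureValue:
    def test_long_is_length_weighted_mean(self):
        members = [
            make_segment("1", 0.3, 0.50),
            make_segment("2", 0.5, 0.25),
        ]
        assert feature_value("long", members) == pytest.approx(0.3667, abs=1e-4)

    def test_short_positive_cluster_takes_minimum(self):
        members = [make_segment("1", 0.9, 0.05), make_segment("2", 1.2, 0.05)]
        assert feature_value("short", members) == 0.9

    def test_short_negative_cluster_takes_maximum(self):
        members = [make_segment("1", -1.4, 0.05), make_segment("2", -0.8, 0.05)]
        assert feature_value("short", members) == -0.8

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            feature_value("long", [])


class TestBaseline:
    def test_picks_near_zero_high_coverage_cluster(self):
        c1 = make_cluster("long", [-0.02], coverage=0.55)
        c2 = make_cluster("long", [0.30], coverage=0.30)
        baseline, flags = estimate_baseline([c1, c2])
        assert baseline is c1 and not flags

    def test_coverage_relaxes_stepwise(self):
        clusters = [
            make_cluster("long", [0.05], coverage=0.35),
            make_cluster("long", [0.5], coverage=0.30),
            make_cluster("long", [-0.6], coverage=0.25),
        ]
        baseline, flags = estimate_baseline(clusters)
        assert baseline.V == 0.05
        assert "baseline_coverage_relaxed" in flags

    def test_shift_moves_to_next_larger_v(self):
        clusters = [
            make_cluster("long", [0.05], coverage=0.35),
            make_cluster("long", [0.5], coverage=0.30),
            make_cluster("long", [-0.6], coverage=0.25),
        ]
        baseline, flags = estimate_baseline(
            clusters, ThresholdParams(baseline_shift=1)
        )
        assert baseline.V == 0.5
        assert "baseline_shifted" in flags

    def test_shift_with_no_candidate_keeps_baseline(self):
        clusters = [make_cluster("long", [0.0], coverage=0.9)]
        baseline, flags = estimate_baseline(
            clusters, ThresholdParams(baseline_shift=-1)
        )
        assert baseline.V == 0.0
        assert "baseline_shifted" not in flags

    def test_shift_zero_reproduces_unshifted(self):
        clusters = [
            make_cluster("long", [0.02], coverage=0.5),
            make_cluster("long", [-0.3], coverage=0.45),
        ]
        a, _ = estimate_baseline(clusters, ThresholdParams(baseline_shift=0))
        b, _ = estimate_baseline(clusters)
        assert a is b

    def test_nothing_qualifies_at_floor(self):
        with pytest.raises(NoBaselineError):
            estimate_baseline([make_cluster("long", [0.0], coverage=0.1)])


class TestLowTargets:
    def test_dup_window_upper_bound_excludes(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        c1 = make_cluster("long", [0.8], norm_lengths=[0.5])
        c2 = make_cluster("long", [0.4], norm_lengths=[0.3])
        low_dup, low_del = select_low_targets([c1, c2], baseline)
        assert low_dup is c2 and low_del is None

    def test_del_window(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        c1 = make_cluster("long", [-0.35], norm_lengths=[0.5])
        c2 = make_cluster("long", [-1.8], norm_lengths=[0.3])
        low_dup, low_del = select_low_targets([c1, c2], baseline)
        assert low_del is c1 and low_dup is None

    def test_rank_order_wins_within_window(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        big = make_cluster("long", [0.5], norm_lengths=[0.6])
        small = make_cluster("long", [0.2], norm_lengths=[0.25])
        ranked = rank_by_length([small, big])
        assert ranked[0] is big
        low_dup, _ = select_low_targets(ranked, baseline)
        assert low_dup is big

    def test_both_absent(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        c = make_cluster("long", [0.05], norm_lengths=[0.3])
        assert select_low_targets([c], baseline) == (None, None)

    def test_windows_follow_baseline_v(self):
        baseline = make_cluster("long", [0.2], coverage=0.6)
        c = make_cluster("long", [0.3], norm_lengths=[0.3])  # only 0.1 above
        low_dup, _ = select_low_targets([c], baseline)
        assert low_dup is None


class TestLowThresholds:
    def test_two_sigma_margin(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        target = make_cluster("long", [0.35, 0.45], norm_lengths=[0.3, 0.3])
        assert target.sigma == pytest.approx(0.05)
        sel = TargetSelection(baseline=baseline, low_dup=target)
        t_dup, t_del = low_thresholds(sel)
        assert t_dup == pytest.approx(0.40 - 2 * 0.05)
        assert t_del == -math.inf

    def test_singleton_sigma_zero(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        target = make_cluster("long", [-0.35], norm_lengths=[0.3])
        sel = TargetSelection(baseline=baseline, low_del=target)
        _, t_del = low_thresholds(sel)
        assert t_del == -0.35

    def test_absent_targets_disable_sides(self):
        sel = TargetSelection(baseline=make_cluster("long", [0.0], coverage=0.6))
        t_dup, t_del = low_thresholds(sel)
        assert t_dup == math.inf and t_del == -math.inf

    def test_crossing_threshold_clamped_above_baseline(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        # sd 0.2 > (V - baseline)/2: raw threshold 0.25 - 0.4 < baseline
        target = make_cluster("long", [0.05, 0.45], norm_lengths=[0.3, 0.3])
        sel = TargetSelection(baseline=baseline, low_dup=target)
        t_dup, _ = low_thresholds(sel)
        assert 0.0 < t_dup <= 0.25
        assert "low_dup_threshold_clamped" in sel.fallback_flags


class TestHighTargets:
    def test_dup_ratio_rule(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        low_dup = make_cluster("long", [0.3], norm_lengths=[0.3])
        sel = TargetSelection(baseline=baseline, low_dup=low_dup)
        shorts = [make_cluster("short", [v], cid=i) for i, v in enumerate([0.45, 0.65, 1.3])]
        high_dup, high_del = select_high_targets(shorts, sel)
        # cut = 2.2 - 0.6*0.3 = 2.02; 0.45/0.3=1.5 fails, 0.65/0.3~2.17 passes
        assert high_dup.V == 0.65 and high_del is None
        assert sel.s1 == pytest.approx(0.3)

    def test_del_ratio_rule_picks_largest_qualifying_v(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        low_del = make_cluster("long", [-0.4], norm_lengths=[0.3])
        sel = TargetSelection(baseline=baseline, low_del=low_del)
        shorts = [make_cluster("short", [v], cid=i) for i, v in enumerate([-0.5, -0.9, -2.0])]
        _, high_del = select_high_targets(shorts, sel)
        # ratios 1.25, 2.25, 5.0; qualifying V < -0.4 with ratio >= 2: pick -0.9
        assert high_del.V == -0.9

    def test_no_cluster_beyond_low_target(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        low_dup = make_cluster("long", [0.3], norm_lengths=[0.3])
        sel = TargetSelection(baseline=baseline, low_dup=low_dup)
        shorts = [make_cluster("short", [0.2])]
        assert select_high_targets(shorts, sel) == (None, None)

    def test_default_s_fallbacks_flagged(self):
        baseline = make_cluster("long", [0.0], coverage=0.6)
        sel = TargetSelection(baseline=baseline)
        shorts = [make_cluster("short", [2.5])]
        high_dup, _ = select_high_targets(shorts, sel)
        assert high_dup.V == 2.5
        assert {"default_s1", "default_s2"} <= sel.fallback_flags
        assert sel.s1 == 0.30 and sel.s2 == 0.35


class TestHighThresholds:
    def test_guard_raises_dup_threshold_above_long_segments(self):
        sel = TargetSelection(
            baseline=make_cluster("long", [0.0], coverage=0.6),
            high_dup=make_cluster("short", [0.65]),
        )
        t_dup, _ = high_thresholds(sel, [0.0, 0.80])
        assert t_dup == pytest.approx(0.81)

    def test_del_takes_more_extreme_of_target_and_guard(self):
        sel = TargetSelection(
            baseline=make_cluster("long", [0.0], coverage=0.6),
            high_del=make_cluster("short", [-0.9]),
        )
        _, t_del = high_thresholds(sel, [-0.5, 0.0])
        assert t_del == -0.9

    def test_absent_target_disables_side(self):
        sel = TargetSelection(baseline=make_cluster("long", [0.0], coverage=0.6))
        t_dup, t_del = high_thresholds(sel, [0.0])
        assert t_dup == math.inf and t_del == -math.inf

    def test_empty_long_set_omits_guard(self):
        sel = TargetSelection(
            baseline=make_cluster("short", [0.0], coverage=0.6),
            high_dup=make_cluster("short", [1.5]),
        )
        t_dup, _ = high_thresholds(sel, [])
        assert t_dup == 1.5


def test_params_validate_bounds():
    with pytest.raises(ValueError):
        ThresholdParams(low_bound=0.8, dup_upper=0.7)
    with pytest.raises(ValueError):
        ThresholdParams(del_lower=-0.1)
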