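"""End-to-end per-sample calling: partition, labeling rules, fallbacks."""

import math

import pytest

from labelseg import (
    ClusterParams,
    ThresholdParams,
    ThresholdSet,
    assign_labels,
    call_sample,
    fixed_threshold_labels,
    partition_by_length,
)

from conftest import make_profile, make_segment


class TestPartition:
    @pytest.mark.parametrize(
        "frac,expect_long",
        [(0.25, True), (0.199, False), (0.20, True)],  # boundary inclusive
    )
    def test_cutoff(self, frac, expect_long):
        seg = make_segment("1", 0.0, frac)
        long_segs, short_segs = partition_by_length([seg])
        assert (seg in long_segs) is expect_long
        assert (seg in short_segs) is not expect_long


class TestAssignLabels:
    THRESHOLDS = ThresholdSet(
        T_low_dup=0.2, T_low_del=-0.2, T_high_dup=1.0, T_high_del=-1.0,
        baseline_V=0.0,
    )

    @pytest.mark.parametrize(
        "logr,expected",
        [
            (0.5, "+1"),
            (1.0, "+2"),   # >= T_high_dup
            (-0.2, "-1"),  # <= T_low_del
            (-1.0, "-2"),  # <= T_high_del
            (0.19, "0"),
            (0.2, "+1"),   # >= T_low_dup
            (-0.19, "0"),
        ],
    )
    def test_boundary_conventions(self, logr, expected):
        seg = make_segment("1", logr, 0.1)
        assert assign_labels([seg], self.THRESHOLDS) == [expected]

    def test_disabled_dup_side_never_fires(self):
        ts = ThresholdSet(
            T_low_dup=math.inf, T_low_del=-0.2, T_high_dup=math.inf,
            T_high_del=-1.0, baseline_V=0.0,
        )
        segs = [make_segment("1", v, 0.1) for v in (5.0, 0.1, -0.5)]
        assert assign_labels(segs, ts) == ["0", "0", "-1"]

    def test_empty_list(self):
        assert assign_labels([], self.THRESHOLDS) == []


class TestCallSample:
    def two_cluster_toy(self):
        # 10 long near-neutral (80% coverage), 3 long gains, 2 short amps
        spec = [(str(i + 1), 0.001 * (i % 3) - 0.001, 0.40) for i in range(10)]
        spec += [(str(i + 11), 0.35, 0.30) for i in range(3)]
        spec += [("14", 1.20, 0.05), ("15", 1.21, 0.05)]
        return make_profile(spec)

    def test_two_cluster_toy_labels(self):
        res = call_sample(self.two_cluster_toy())
        assert res.labels == ["0"] * 10 + ["+1"] * 3 + ["+2"] * 2
        assert res.thresholds.baseline_V == pytest.approx(0.0, abs=0.01)
        # no deletion side exists, so only the default-s2 bookkeeping flag
        assert set(res.diagnostics["fallback_flags"]) <= {"default_s2"}
        # s1 ~ 0.35 so the ratio cut is ~1.99 and 1.2/0.35 ~ 3.4 passes
        assert res.selection.s1 == pytest.approx(0.35, abs=0.01)

    def test_pure_diploid_all_neutral(self):
        spec = [(str(i + 1), 0.01 * ((i % 5) - 2), 1.0) for i in range(10)]
        res = call_sample(make_profile(spec))
        assert res.labels == ["0"] * 10
        t = res.thresholds
        assert t.T_low_dup == math.inf and t.T_low_del == -math.inf
        assert t.T_high_dup == math.inf and t.T_high_del == -math.inf

    def test_focal_only_default_s1_fallback(self):
        spec = [(str(i + 1), 0.0, 0.9) for i in range(8)]
        spec += [("9", 2.5, 0.02)]
        res = call_sample(make_profile(spec))
        assert res.labels == ["0"] * 8 + ["+2"]
        assert "default_s1" in res.diagnostics["fallback_flags"]

    def test_no_long_segments_pseudo_baseline(self):
        spec = [(str(i % 5 + 1), 0.0, 0.10) for i in range(12)]
        spec += [("6", 2.0, 0.02)]
        res = call_sample(make_profile(spec))
        assert "no_long_segments" in res.diagnostics["fallback_flags"]
        assert res.labels == ["0"] * 12 + ["+2"]

    def test_label_monotone_in_logr(self):
        res = call_sample(self.two_cluster_toy())
        order = {"-2": 0, "-1": 1, "0": 2, "+1": 3, "+2": 4}
        pairs = sorted(zip(
            (s.logR for s in res.profile.segments), res.labels))
        ranks = [order[l] for _, l in pairs]
        assert ranks == sorted(ranks)

    def test_idempotent_on_labeled_profile(self):
        prof = self.two_cluster_toy()
        first = call_sample(prof).labels
        second = call_sample(prof).labels  # segments now carry labels
        assert first == second

    def test_sex_chromosomes_labeled_but_excluded_from_estimation(self):
        # hemizygous X at -1 would enter the low-del window if included
        spec = [(str(i + 1), 0.0, 0.5) for i in range(8)]
        prof = make_profile(spec + [("X", -1.0, 0.9)])
        res = call_sample(prof)
        assert len(res.labels) == 9
        x_label = res.labels[-1]  # X sorts after autosomes
        assert res.profile.segments[-1].chrom == "X"
        assert x_label == "0"  # no autosomal deletion cluster -> side disabled
        res_inc = call_sample(make_profile(spec + [("X", -1.0, 0.9)]),
                              include_sex=True)
        assert res_inc.labels[-1] == "-1"

    def test_long_segments_never_high_level(self):
        # a strong long gain plus an even stronger short amp
        spec = [(str(i + 1), 0.0, 0.6) for i in range(8)]
        spec += [("9", 0.65, 0.5), ("10", 0.9, 0.05)]
        res = call_sample(make_profile(spec))
        long_labels = [
            lab for seg, lab in zip(res.profile.segments, res.labels)
            if seg.norm_length >= 0.2
        ]
        assert "+2" not in long_labels and "-2" not in long_labels

    def test_empty_profile_errors(self):
        from labelseg import SegmentProfile

        with pytest.raises(ValueError):
            call_sample(SegmentProfile("S", []))

    def test_backend_hdbscan_uniform_runs(self):
        res = call_sample(
            self.two_cluster_toy(),
            ClusterParams(backend="hdbscan", uniform=True, minPts=2),
        )
        assert len(res.labels) == 15

    def test_baseline_shift_changes_neutral_state(self):
        # near-triploid-like profile: large cluster at 0.3, smaller at 0
        spec = [(str(i + 1), 0.30, 0.45) for i in range(8)]
        spec += [(str(i + 9), 0.0, 0.45) for i in range(6)]
        unshifted = call_sample(make_profile(spec))
        assert unshifted.thresholds.baseline_V == pytest.approx(0.0)
        shifted = call_sample(
            make_profile(spec), tparams=ThresholdParams(baseline_shift=1)
        )
        assert shifted.thresholds.baseline_V == pytest.approx(0.30)


def test_fixed_threshold_caller():
    segs = [make_segment("1", v, 0.1) for v in (-1.2, -0.5, 0.0, 0.4, 0.9)]
    assert fixed_threshold_labels(segs, 0.3, 1.0) == ["-2", "-1", "0", "+1", "+1"]
    assert fixed_threshold_labels(segs, 0.15, 0.7) == ["-2", "-1", "0", "+1", "+2"]
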