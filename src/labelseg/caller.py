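"""Per-sample SCNA calling: partition, cluster, estimate thresholds, label.

Each sample is processed independently. Segments covering at least 20% of
their chromosome are *long* (broad events, low amplitude); the rest are
*short* (focal events, potentially high amplitude). Thresholds estimated
from the clustered logR distribution are then applied as pure cutoffs,
assigning each segment one of five relative copy-number states:
"-2" high-level deletion, "-1" low-level deletion, "0" neutral,
"+1" low-level duplication, "+2" high-level duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cluster import ClusterAssignment, ClusterParams, cluster_profile
from .seg_io import Segment, SegmentProfile
from .thresholds import (
    INF,
    Cluster,
    NoBaselineError,
    TargetSelection,
    ThresholdParams,
    ThresholdSet,
    build_clusters,
    estimate_baseline,
    high_thresholds,
    low_thresholds,
    rank_by_length,
    select_high_targets,
    select_low_targets,
)

logger = logging.getLogger(__name__)

#: fraction of a chromosome at or above which a segment counts as long
LONG_FRACTION = 0.20


@dataclass
class CallResult:
    """Labels, thresholds and diagnostics for one sample."""

    profile: SegmentProfile
    labels: list[str]
    thresholds: ThresholdSet
    selection: TargetSelection
    diagnostics: dict = field(default_factory=dict)


def partition_by_length(
    segments: list[Segment], long_fraction: float = LONG_FRACTION
) -> tuple[list[Segment], list[Segment]]:
    """Split segments into (long, short) at the normalised-length cutoff.

    The boundary is inclusive: a segment covering exactly the cutoff
    fraction of its chromosome is long.
    """
    long_segs = [s for s in segments if s.norm_length >= long_fraction]
    short_segs = [s for s in segments if s.norm_length < long_fraction]
    return long_segs, short_segs


def assign_labels(segments: list[Segment], thresholds: ThresholdSet) -> list[str]:
    """Label each segment by pure threshold comparison on its logR.

    ``logR >= T_high_dup`` -> "+2"; ``T_low_dup <= logR < T_high_dup`` ->
    "+1"; ``logR <= T_high_del`` -> "-2"; ``T_high_del < logR <=
    T_low_del`` -> "-1"; otherwise "0". Disabled sides (±∞) never match.
    """
    labels = []
    for seg in segments:
        r = seg.logR
        if r >= thresholds.T_high_dup:
            labels.append("+2")
        elif r >= thresholds.T_low_dup:
            labels.append("+1")
        elif r <= thresholds.T_high_del:
            labels.append("-2")
        elif r <= thresholds.T_low_del:
            labels.append("-1")
        else:
            labels.append("0")
    return labels


def _pseudo_baseline(clusters: list[Cluster]) -> Cluster:
    """Fallback baseline: minimal |V|, ties broken by larger cum_length."""
    return min(clusters, key=lambda c: (abs(c.V), -c.cum_length, c.V))


def call_sample(
    profile: SegmentProfile,
    cparams: ClusterParams | None = None,
    tparams: ThresholdParams | None = None,
    include_sex: bool = False,
    long_fraction: float = LONG_FRACTION,
) -> CallResult:
    """Run the full calling pipeline on one sample.

    Sex chromosomes are excluded from baseline/target estimation by default
    (a hemizygous X would drag the baseline in male samples) but are still
    labeled. Exception paths: with no long segments a pseudo-baseline is
    taken from the short clusters and the long-segment guard is omitted;
    with no baseline at the coverage floor the pseudo-baseline rule is
    applied to the long clusters; a missing low-level target triggers the
    default-s1/s2 fallback for the corresponding high-level side.
    """
    cparams = cparams or ClusterParams()
    tparams = tparams or ThresholdParams()
    if not profile.segments:
        raise ValueError(f"sample {profile.sample_id!r} has no segments")

    est_segments = (
        profile.segments if include_sex
        else [s for s in profile.segments if not s.is_sex]
    )
    if not est_segments:
        logger.warning(
            "sample %s has only sex-chromosome segments; using them for "
            "estimation", profile.sample_id,
        )
        est_segments = profile.segments

    total_len = sum(s.length for s in est_segments)
    long_segs, short_segs = partition_by_length(est_segments, long_fraction)
    long_a, short_a = cluster_profile(
        [s.logR for s in long_segs], [s.logR for s in short_segs], cparams
    )
    long_clusters = build_clusters(long_segs, long_a.labels, "long", total_len)
    short_clusters = build_clusters(short_segs, short_a.labels, "short", total_len)

    flags: set[str] = set()
    baseline: Cluster
    if not long_clusters and not short_clusters:
        # every point was noise (possible with minPts > 1); use one
        # catch-all cluster over whichever partition has segments
        if long_segs:
            long_clusters = build_clusters(
                long_segs, [0] * len(long_segs), "long", total_len
            )
        else:
            short_clusters = build_clusters(
                short_segs, [0] * len(short_segs), "short", total_len
            )
        flags.add("all_noise_catchall")
    if not long_clusters:
        baseline = _pseudo_baseline(short_clusters)
        flags.add("no_long_segments")
    else:
        try:
            baseline, bflags = estimate_baseline(long_clusters, tparams)
            flags |= bflags
        except NoBaselineError:
            baseline = _pseudo_baseline(long_clusters)
            flags.add("baseline_coverage_floor_failed")

    selection = TargetSelection(baseline=baseline, fallback_flags=flags)

    ranked_long = rank_by_length([c for c in long_clusters if c is not baseline])
    selection.low_dup, selection.low_del = select_low_targets(
        ranked_long, baseline, tparams
    )
    t_low_dup, t_low_del = low_thresholds(selection, tparams)

    eligible_short = [c for c in short_clusters if c is not baseline]
    selection.high_dup, selection.high_del = select_high_targets(
        eligible_short, selection, tparams
    )
    long_logrs = [s.logR for s in long_segs]
    t_high_dup, t_high_del = high_thresholds(selection, long_logrs, tparams)

    thresholds = ThresholdSet(
        T_low_dup=t_low_dup,
        T_low_del=t_low_del,
        T_high_dup=t_high_dup,
        T_high_del=t_high_del,
        baseline_V=baseline.V,
    )
    labels = assign_labels(profile.segments, thresholds)
    for seg, lab in zip(profile.segments, labels):
        seg.label = lab

    diagnostics = {
        "fallback_flags": sorted(selection.fallback_flags),
        "eps_long": long_a.eps,
        "eps_short": short_a.eps,
        "n_long_clusters": len(long_clusters),
        "n_short_clusters": len(short_clusters),
        "n_long_segments": len(long_segs),
        "n_short_segments": len(short_segs),
        "s1": selection.s1,
        "s2": selection.s2,
    }
    return CallResult(
        profile=profile,
        labels=labels,
        thresholds=thresholds,
        selection=selection,
        diagnostics=diagnostics,
    )


def call_profiles(
    profiles: list[SegmentProfile],
    cparams: ClusterParams | None = None,
    tparams: ThresholdParams | None = None,
    **kwargs,
) -> list[CallResult]:
    """Call every sample of a multi-sample file independently, in order."""
    return [call_sample(p, cparams, tparams, **kwargs) for p in profiles]


def fixed_threshold_labels(
    segments: list[Segment], low: float, high: float
) -> list[str]:
    """Baseline comparator: symmetric fixed cutoffs ``{±low, ±high}``.

    Mirrors the common practice of fixed empirical thresholds (e.g.
    ±0.15/±0.7 relaxed, ±0.3/±1 stringent) that the adaptive method is
    designed to replace.
    """
    ts = ThresholdSet(
        T_low_dup=low, T_low_del=-low, T_high_dup=high, T_high_del=-high,
        baseline_V=0.0,
    )
    return assign_labels(segments, ts)
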