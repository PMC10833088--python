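"""Per-sample calling-threshold estimation from logR clusters.

The method anchors everything on a *baseline* cluster of long segments
(copy-neutral state), then picks one *target cluster* per SCNA level and
converts its feature value V into a calling threshold:

* low-level duplication target: highest-ranked long cluster with
  ``baseline + 0.15 <= V < baseline + 0.7``; threshold ``V - 2σ``.
* low-level deletion target: highest-ranked long cluster with
  ``baseline - 1.5 < V <= baseline - 0.15``; threshold ``V + 2σ``.
* high-level targets come from short clusters whose distance to baseline,
  in units of the low-level step s1/s2, exceeds a purity-robust ratio cut
  (``2.2 - 0.6·s1`` for duplications, ``2`` for deletions); the resulting
  threshold is guarded so no long segment can ever be called high-level.

Window bounds (±0.15, 0.7, −1.5), the 2σ sensitivity margin and the ±0.01
long-segment guard are tunable via :class:`ThresholdParams`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .seg_io import Segment

logger = logging.getLogger(__name__)

INF = float("inf")


@dataclass
class Cluster:
    """A group of segments close in logR, with its summary statistics.

    ``V`` is the feature value: length-weighted mean logR for long-segment
    clusters, the member logR closest to 0 for short-segment clusters.
    """

    id: int
    kind: str  # "long" | "short"
    members: list[Segment]
    V: float = field(init=False)
    sigma: float = field(init=False)
    cum_length: int = field(init=False)
    cum_norm_length: float = field(init=False)
    coverage_frac: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.kind not in ("long", "short"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        self.V = feature_value(self.kind, self.members)
        logrs = np.array([s.logR for s in self.members])
        self.sigma = float(np.std(logrs)) if len(logrs) > 1 else 0.0
        self.cum_length = sum(s.length for s in self.members)
        self.cum_norm_length = float(sum(s.norm_length for s in self.members))


def feature_value(kind: str, members: list[Segment]) -> float:
    """Representative logR of a cluster.

    Long clusters: mean of member logRs weighted by normalised segment
    length. Short clusters: the member logR with the smallest absolute
    value (the minimum of an all-positive cluster, the maximum of an
    all-negative one).
    """
    if not members:
        raise ValueError("feature value of an empty cluster is undefined")
    if kind == "long":
        logrs = np.array([s.logR for s in members], dtype=float)
        if np.all(logrs == logrs[0]):
            # exact for constant clusters: the weighted mean must not pick
            # up rounding error, since the calling rule compares with >=
            return float(logrs[0])
        weights = np.array([s.norm_length for s in members], dtype=float)
        return float(np.average(logrs, weights=weights))
    return float(min((s.logR for s in members), key=abs))


def build_clusters(
    segments: list[Segment],
    labels,
    kind: str,
    total_measured_length: int,
) -> list[Cluster]:
    """Group segments by cluster id (noise id -1 excluded) into Clusters."""
    groups: dict[int, list[Segment]] = {}
    for seg, cid in zip(segments, labels):
        cid = int(cid)
        if cid < 0:
            continue
        groups.setdefault(cid, []).append(seg)
    clusters = []
    for cid in sorted(groups):
        c = Cluster(id=cid, kind=kind, members=groups[cid])
        c.coverage_frac = c.cum_length / total_measured_length
        clusters.append(c)
    return clusters


@dataclass
class ThresholdParams:
    """Tunable constants of the threshold-estimation step (logR units).

    Defaults are the method's published operating point: low-level target
    windows ``[baseline ± low_bound, baseline + dup_upper)`` /
    ``(baseline + del_lower, baseline − low_bound]``, a ``2σ`` sensitivity
    margin, high-level ratio cuts ``2.2 − 0.6·s1`` (dup) and ``2`` (del),
    a 0.01 guard above/below the long-segment range, and baseline coverage
    relaxation 40% → 20% in steps of 10%. ``default_s1``/``default_s2``
    approximate a one-copy gain/loss at ~50% purity and are used only when
    a high-level side must be evaluated without its low-level target.
    """

    low_bound: float = 0.15
    dup_upper: float = 0.7
    del_lower: float = -1.5
    sigma_mult: float = 2.0
    ratio_dup_const: float = 2.2
    ratio_dup_slope: float = 0.6
    ratio_del_min: float = 2.0
    guard_offset: float = 0.01
    baseline_cov_start: float = 0.40
    baseline_cov_floor: float = 0.20
    baseline_cov_step: float = 0.10
    baseline_shift: int = 0
    default_s1: float = 0.30
    default_s2: float = 0.35
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.low_bound < self.dup_upper:
            raise ValueError("require low_bound < dup_upper")
        if not self.del_lower < -self.low_bound:
            raise ValueError("require del_lower < -low_bound")
        if self.baseline_shift not in (-1, 0, 1):
            raise ValueError("baseline_shift must be -1, 0 or +1")


@dataclass
class TargetSelection:
    """Baseline and the (possibly absent) four target clusters."""

    baseline: Cluster
    low_dup: Cluster | None = None
    low_del: Cluster | None = None
    high_dup: Cluster | None = None
    high_del: Cluster | None = None
    s1: float | None = None
    s2: float | None = None
    fallback_flags: set[str] = field(default_factory=set)


@dataclass
class ThresholdSet:
    """The four per-sample calling thresholds plus the baseline V.

    A disabled call side is encoded as ±∞ so label assignment stays a pure
    threshold comparison. When all four are finite they satisfy
    ``T_high_del <= T_low_del < baseline_V < T_low_dup <= T_high_dup``.
    """

    T_low_dup: float
    T_low_del: float
    T_high_dup: float
    T_high_del: float
    baseline_V: float

    def is_ordered(self) -> bool:
        return (
            self.T_high_del <= self.T_low_del < self.baseline_V
            < self.T_low_dup <= self.T_high_dup
        )


class NoBaselineError(RuntimeError):
    """No long cluster qualifies as baseline even at the coverage floor."""


def rank_by_length(clusters: list[Cluster]) -> list[Cluster]:
    """Rank clusters by cumulative bp length descending (ties: |V| asc)."""
    return sorted(clusters, key=lambda c: (-c.cum_length, abs(c.V)))


def estimate_baseline(
    long_clusters: list[Cluster], params: ThresholdParams | None = None
) -> tuple[Cluster, set[str]]:
    """Pick the copy-neutral baseline cluster.

    Among clusters covering at least 40% of the measured genome, the one
    with feature value closest to 0 wins (ties: larger coverage, then
    smaller V). If none qualifies the coverage requirement is relaxed in
    10% steps down to 20%. ``baseline_shift`` = ±1 moves the selection to
    the nearest qualifying cluster with larger/smaller V; if none exists
    the unshifted baseline is kept with a warning.

    Returns (baseline, fallback flags); raises :class:`NoBaselineError`
    when nothing qualifies at the floor.
    """
    params = params or ThresholdParams()
    flags: set[str] = set()
    if not long_clusters:
        raise NoBaselineError("no long-segment clusters")

    cov = params.baseline_cov_start
    eligible: list[Cluster] = []
    while True:
        # small tolerance so stepped-down bounds (0.4 - 0.1 -> 0.30000...4)
        # do not exclude a cluster sitting exactly on the limit
        eligible = [c for c in long_clusters if c.coverage_frac >= cov - 1e-9]
        if eligible:
            break
        next_cov = cov - params.baseline_cov_step
        if next_cov < params.baseline_cov_floor - 1e-12:
            raise NoBaselineError(
                f"no long cluster covers >= {params.baseline_cov_floor:.0%} "
                "of the measured genome"
            )
        cov = next_cov
        flags.add("baseline_coverage_relaxed")

    baseline = min(eligible, key=lambda c: (abs(c.V), -c.coverage_frac, c.V))

    if params.baseline_shift:
        direction = params.baseline_shift
        candidates = [
            c for c in eligible
            if (c.V > baseline.V if direction > 0 else c.V < baseline.V)
        ]
        if candidates:
            baseline = min(candidates, key=lambda c: abs(c.V - baseline.V))
            flags.add("baseline_shifted")
        else:
            logger.warning(
                "baseline_shift=%+d requested but no qualifying cluster in "
                "that direction; keeping unshifted baseline", direction
            )
    return baseline, flags


def select_low_targets(
    ranked_long: list[Cluster],
    baseline: Cluster,
    params: ThresholdParams | None = None,
) -> tuple[Cluster | None, Cluster | None]:
    """First cluster in rank order inside each low-level target window.

    ``ranked_long`` must exclude the baseline and be ranked by cumulative
    length descending. Either target may be absent.
    """
    params = params or ThresholdParams()
    b = baseline.V
    low_dup = low_del = None
    for c in ranked_long:
        if low_dup is None and b + params.low_bound <= c.V < b + params.dup_upper:
            low_dup = c
        if low_del is None and b + params.del_lower < c.V <= b - params.low_bound:
            low_del = c
        if low_dup is not None and low_del is not None:
            break
    return low_dup, low_del


def low_thresholds(
    selection: TargetSelection, params: ThresholdParams | None = None
) -> tuple[float, float]:
    """Low-level thresholds ``V ∓ 2σ``; ±∞ when the target is absent.

    A crossing threshold (possible only when the adaptive-ε loop bottomed
    out with a cluster SD above its cap, so that 2σ exceeds the target's
    distance to baseline) is clamped to the midpoint between baseline V and
    target V, preserving the threshold ordering invariant.
    """
    params = params or ThresholdParams()
    b = selection.baseline.V
    t_dup, t_del = INF, -INF
    if selection.low_dup is not None:
        sig = max(selection.low_dup.sigma, params.sigma_floor)
        t_dup = selection.low_dup.V - params.sigma_mult * sig
        if t_dup <= b:
            t_dup = (b + selection.low_dup.V) / 2.0
            selection.fallback_flags.add("low_dup_threshold_clamped")
    if selection.low_del is not None:
        sig = max(selection.low_del.sigma, params.sigma_floor)
        t_del = selection.low_del.V + params.sigma_mult * sig
        if t_del >= b:
            t_del = (b + selection.low_del.V) / 2.0
            selection.fallback_flags.add("low_del_threshold_clamped")
    return t_dup, t_del


def select_high_targets(
    short_clusters: list[Cluster],
    selection: TargetSelection,
    params: ThresholdParams | None = None,
) -> tuple[Cluster | None, Cluster | None]:
    """Pick the high-level target clusters from the short-segment clusters.

    Short clusters are ranked by V ascending. The duplication target is the
    qualifying cluster with the smallest V among those beyond the low-dup
    target whose baseline distance ratio ``(V - b)/s1`` reaches
    ``2.2 - 0.6*s1``; the deletion target is the qualifying cluster with
    the largest V among those beyond the low-del target with
    ``(b - V)/s2 >= 2``. When a low-level target is missing, s1/s2 fall
    back to defaults and the corresponding flag is recorded.
    """
    params = params or ThresholdParams()
    b = selection.baseline.V

    if selection.low_dup is not None:
        s1 = selection.low_dup.V - b
        v_min_dup = selection.low_dup.V
    else:
        s1 = params.default_s1
        v_min_dup = b
        selection.fallback_flags.add("default_s1")
    if selection.low_del is not None:
        s2 = b - selection.low_del.V
        v_max_del = selection.low_del.V
    else:
        s2 = params.default_s2
        v_max_del = b
        selection.fallback_flags.add("default_s2")
    if s1 <= 0 or s2 <= 0:
        raise RuntimeError("low-level step s1/s2 must be positive")
    selection.s1, selection.s2 = s1, s2

    ranked = sorted(short_clusters, key=lambda c: c.V)
    dup_cut = params.ratio_dup_const - params.ratio_dup_slope * s1

    high_dup = high_del = None
    for c in ranked:  # ascending V: first qualifying = smallest V
        if c.V > v_min_dup and (c.V - b) / s1 >= dup_cut:
            high_dup = c
            break
    for c in ranked:  # ascending V: last qualifying = largest V
        if c.V < v_max_del and (b - c.V) / s2 >= params.ratio_del_min:
            high_del = c
    return high_dup, high_del


def high_thresholds(
    selection: TargetSelection,
    long_logrs,
    params: ThresholdParams | None = None,
) -> tuple[float, float]:
    """High-level thresholds with the long-segment guard.

    ``T_high_dup = max(V_target, max(V_L) + 0.01)`` and symmetrically for
    deletions, where V_L is the set of all long-segment logRs — no long
    segment can ever be called high-level. An absent target disables the
    side (±∞); with no long segments the guard term is omitted.
    """
    params = params or ThresholdParams()
    v_l = np.asarray(long_logrs, dtype=float)
    t_dup, t_del = INF, -INF
    if selection.high_dup is not None:
        t_dup = selection.high_dup.V
        if v_l.size:
            t_dup = max(t_dup, float(v_l.max()) + params.guard_offset)
    if selection.high_del is not None:
        t_del = selection.high_del.V
        if v_l.size:
            t_del = min(t_del, float(v_l.min()) - params.guard_offset)
    return t_dup, t_del
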