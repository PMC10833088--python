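"""One-dimensional density clustering of segment logR values.

Segments sharing a relative copy-number state concentrate around the same
logR value, so clusters in logR space are candidate copy-number states.
Long segments (broad events, many markers) have tighter logR distributions
than short segments, hence the two partitions are clustered separately with
different radii, and the neighborhood radius ε is shrunk adaptively until
every cluster's logR standard deviation falls below a cap.

Backends: exact DBSCAN (default), an OPTICS ordering cut at the same ε
(DBSCAN-equivalent extraction), and HDBSCAN — optionally as one *uniform*
clustering over all segments that is re-split into long/short views
afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass
class ClusterParams:
    """Parameters controlling the density clustering step.

    ``eps_init_long``/``eps_init_short`` are the starting DBSCAN radii for
    long- and short-segment clustering; the adaptive loop shrinks ε by
    ``eps_step`` until every cluster's logR SD is at most the corresponding
    cap (``sd_cap_long``/``sd_cap_short``) or ε reaches ``eps_floor``.
    ``minPts`` = 1 lets a single focal amplification form its own cluster.
    """

    backend: str = "dbscan"  # dbscan | optics | hdbscan
    minPts: int = 1
    eps_init_long: float = 0.05
    eps_init_short: float = 0.10
    sd_cap_long: float = 0.05
    sd_cap_short: float = 0.10
    eps_step: float = 0.01
    eps_floor: float = 0.01
    uniform: bool = False
    # HDBSCAN only: subclusters closer than this are merged at extraction
    # (logR states of interest differ by well over 0.05; prevents the eom
    # criterion from splitting one tight state into several clusters)
    hdbscan_selection_eps: float = 0.05

    def __post_init__(self) -> None:
        if self.backend not in ("dbscan", "optics", "hdbscan"):
            raise ValueError(f"unknown clustering backend {self.backend!r}")
        if self.uniform and self.backend != "hdbscan":
            raise ValueError("uniform clustering requires the hdbscan backend")
        if self.minPts < 1:
            raise ValueError("minPts must be >= 1")
        if not (0 < self.eps_floor <= self.eps_init_long):
            raise ValueError("require 0 < eps_floor <= eps_init_long")
        if not (0 < self.eps_floor <= self.eps_init_short):
            raise ValueError("require 0 < eps_floor <= eps_init_short")
        if self.sd_cap_long <= 0 or self.sd_cap_short <= 0:
            raise ValueError("SD caps must be positive")


@dataclass
class ClusterAssignment:
    """Per-point cluster ids (``NOISE`` = -1) plus the ε that produced them.

    Cluster ids are renumbered 0..k-1 in ascending order of cluster mean
    logR, so the assignment is invariant to input order.
    """

    labels: np.ndarray
    eps: float | None = None
    members: dict[int, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.members = {
            int(c): np.flatnonzero(self.labels == c)
            for c in np.unique(self.labels)
            if c != NOISE
        }

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    @property
    def noise_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NOISE)


def _canonical(values: np.ndarray, raw_labels: np.ndarray, eps: float | None) -> ClusterAssignment:
    """Renumber cluster ids by ascending cluster mean logR."""
    ids = [c for c in np.unique(raw_labels) if c != NOISE]
    ids.sort(key=lambda c: float(values[raw_labels == c].mean()))
    remap = {old: new for new, old in enumerate(ids)}
    out = np.full(len(raw_labels), NOISE, dtype=int)
    for old, new in remap.items():
        out[raw_labels == old] = new
    return ClusterAssignment(out, eps=eps)


def dbscan_1d(values, eps: float, min_pts: int = 1) -> ClusterAssignment:
    """Standard DBSCAN on scalar values (closed ε-ball, minPts incl. self).

    The fit runs on the values in sorted order so the assignment depends
    only on the multiset of values, never on input order (DBSCAN border
    points are otherwise claimed by whichever core point is scanned first).
    With ``min_pts`` = 1 every point is core and the result is exactly the
    sorted values split at every gap larger than ε.
    """
    from sklearn.cluster import DBSCAN

    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("dbscan_1d requires a non-empty input")
    if not np.all(np.isfinite(vals)):
        raise ValueError("dbscan_1d requires finite values")
    if eps <= 0:
        raise ValueError("eps must be positive")

    order = np.argsort(vals, kind="stable")
    sorted_labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        vals[order].reshape(-1, 1)
    )
    raw = np.empty(vals.size, dtype=int)
    raw[order] = sorted_labels
    return _canonical(vals, raw, eps)


def _optics_cut(values: np.ndarray, eps: float, min_pts: int) -> ClusterAssignment:
    """OPTICS ordering with a DBSCAN-equivalent cut at ε.

    The upper neighborhood limit is unbounded (max_eps = ∞) and clusters are
    extracted by thresholding reachability at ε, which reproduces DBSCAN's
    partition of core points. With minPts = 1 every point is core and the
    extraction coincides with :func:`dbscan_1d`, which is used directly.
    """
    if min_pts < 2:
        return dbscan_1d(values, eps, 1)
    from sklearn.cluster import OPTICS, cluster_optics_dbscan

    vals = np.asarray(values, dtype=float)
    if vals.size < min_pts:
        return ClusterAssignment(np.full(vals.size, NOISE), eps=eps)
    opt = OPTICS(min_samples=min_pts, max_eps=np.inf).fit(vals.reshape(-1, 1))
    raw = cluster_optics_dbscan(
        reachability=opt.reachability_,
        core_distances=opt.core_distances_,
        ordering=opt.ordering_,
        eps=eps,
    )
    return _canonical(vals, raw, eps)


def _hdbscan(values: np.ndarray, min_pts: int, selection_eps: float = 0.05) -> ClusterAssignment:
    """HDBSCAN over scalar values; minPts doubles as min cluster size."""
    from sklearn.cluster import HDBSCAN

    vals = np.asarray(values, dtype=float)
    mcs = max(2, min_pts)
    if vals.size < mcs:
        # too few points to form any cluster
        return ClusterAssignment(np.full(vals.size, NOISE), eps=None)
    hdb = HDBSCAN(
        min_cluster_size=mcs,
        min_samples=min_pts,
        allow_single_cluster=True,
        copy=True,
    )
    raw = np.array(hdb.fit_predict(vals.reshape(-1, 1)))
    # the eom criterion can split one tight logR state into subclusters;
    # merge value-adjacent clusters whose separating gap is <= selection_eps
    # (states of interest differ by well over that)
    if selection_eps > 0:
        ids = [c for c in np.unique(raw) if c != NOISE]
        ids.sort(key=lambda c: float(vals[raw == c].min()))
        rep = ids[0] if ids else None
        for cur in ids[1:]:
            gap = float(vals[raw == cur].min()) - float(vals[raw == rep].max())
            if gap <= selection_eps:
                raw[raw == cur] = rep
            else:
                rep = cur
    return _canonical(vals, raw, None)


def adaptive_cluster(
    values,
    eps_init: float,
    sd_cap: float,
    params: ClusterParams | None = None,
) -> ClusterAssignment:
    """Cluster with ε shrunk stepwise until every cluster SD ≤ ``sd_cap``.

    Starts at ``eps_init`` and reduces ε by ``eps_step`` (default 0.01)
    while some cluster's logR standard deviation (population SD; 0 for
    singletons) exceeds the cap and the floor has not been reached.
    """
    params = params or ClusterParams()
    vals = np.asarray(values, dtype=float)
    backend = _optics_cut if params.backend == "optics" else (
        lambda v, e, m: dbscan_1d(v, e, m)
    )

    eps = eps_init
    assignment = backend(vals, eps, params.minPts)
    while _max_cluster_sd(vals, assignment) > sd_cap and eps - params.eps_step >= params.eps_floor:
        eps = round(eps - params.eps_step, 10)
        assignment = backend(vals, eps, params.minPts)
        logger.debug("adaptive eps reduced to %.3f (%d clusters)", eps, assignment.n_clusters)
    return assignment


def _max_cluster_sd(values: np.ndarray, assignment: ClusterAssignment) -> float:
    worst = 0.0
    for idx in assignment.members.values():
        if idx.size > 1:
            worst = max(worst, float(np.std(values[idx])))
    return worst


def cluster_profile(
    long_logrs,
    short_logrs,
    params: ClusterParams | None = None,
) -> tuple[ClusterAssignment, ClusterAssignment]:
    """Cluster the long and short logR partitions of one sample.

    For the dbscan/optics backends the two partitions are clustered
    separately with their own (ε, SD-cap) pairs. For hdbscan with
    ``uniform=True`` a single joint clustering over all values is computed
    and re-split into long/short views (joint cluster ids are shared across
    the two views so downstream steps see consistent grouping).
    """
    params = params or ClusterParams()
    long_vals = np.asarray(long_logrs, dtype=float)
    short_vals = np.asarray(short_logrs, dtype=float)

    if params.backend == "hdbscan":
        if params.uniform:
            joint = np.concatenate([long_vals, short_vals])
            if joint.size == 0:
                return (ClusterAssignment(np.empty(0, int)),
                        ClusterAssignment(np.empty(0, int)))
            assignment = _hdbscan(joint, params.minPts, params.hdbscan_selection_eps)
            return (
                ClusterAssignment(assignment.labels[: long_vals.size]),
                ClusterAssignment(assignment.labels[long_vals.size:]),
            )
        long_a = (_hdbscan(long_vals, params.minPts, params.hdbscan_selection_eps) if long_vals.size
                  else ClusterAssignment(np.empty(0, int)))
        short_a = (_hdbscan(short_vals, params.minPts, params.hdbscan_selection_eps) if short_vals.size
                   else ClusterAssignment(np.empty(0, int)))
        return long_a, short_a

    long_a = (
        adaptive_cluster(long_vals, params.eps_init_long, params.sd_cap_long, params)
        if long_vals.size
        else ClusterAssignment(np.empty(0, int))
    )
    short_a = (
        adaptive_cluster(short_vals, params.eps_init_short, params.sd_cap_short, params)
        if short_vals.size
        else ClusterAssignment(np.empty(0, int))
    )
    return long_a, short_a
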