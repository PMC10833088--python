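"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from labelseg import Cluster, Segment, SegmentProfile

CHROM_LEN = 100_000_000


def make_segment(
    chrom: str,
    logr: float,
    norm_length: float,
    start: int = 1,
    chrom_len: int = CHROM_LEN,
) -> Segment:
    """Segment with coordinates consistent with the requested norm_length."""
    length = max(1, round(norm_length * chrom_len))
    return Segment(
        chrom=chrom,
        start=start,
        end=start + length - 1,
        logR=logr,
        norm_length=length / chrom_len,
    )


def make_profile(spec: list[tuple[str, float, float]], sample_id: str = "S1") -> SegmentProfile:
    """Profile from (chrom, logR, norm_length) triples, tiled left to right.

    Segments sharing a chromosome are laid out end to end so they never
    overlap.
    """
    cursor: dict[str, int] = {}
    segments = []
    for chrom, logr, norm_length in spec:
        start = cursor.get(chrom, 1)
        seg = make_segment(chrom, logr, norm_length, start=start)
        cursor[chrom] = seg.end + 1
        segments.append(seg)
    return SegmentProfile(sample_id, segments)


def make_cluster(
    kind: str,
    logrs: list[float],
    norm_lengths: list[float] | None = None,
    coverage: float | None = None,
    cid: int = 0,
) -> Cluster:
    """Cluster over synthetic members; coverage_frac set directly if given."""
    if norm_lengths is None:
        norm_lengths = [0.3] * len(logrs)
    members = [
        make_segment(str(i + 1), r, nl) for i, (r, nl) in enumerate(zip(logrs, norm_lengths))
    ]
    c = Cluster(id=cid, kind=kind, members=members)
    if coverage is not None:
        c.coverage_frac = coverage
    return c


# ---------------------------------------------------------------- oracles

def gap_split_oracle(values, eps: float) -> list[list[int]]:
    """Brute-force DBSCAN(minPts=1) oracle: sort, split at gaps > eps.

    Returns the member-index lists of each cluster, ordered by value.
    """
    idx = sorted(range(len(values)), key=lambda i: values[i])
    clusters: list[list[int]] = [[idx[0]]]
    for prev, cur in zip(idx, idx[1:]):
        if values[cur] - values[prev] > eps:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    return clusters


def confusion_oracle(truth, pred, classes):
    """Naive per-class precision/recall/F1 from explicit pair counting."""
    out = {}
    for c in classes:
        tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)
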