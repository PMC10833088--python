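"""Scoring of predicted SCNA labels and cohort-level frequency maps.

Per-sample scoring is one-vs-rest precision/recall/F1 per copy-number
state plus overall accuracy; the macro-F1 averages F1 over the states that
actually occur (in truth or prediction), so samples without high-level
events are not penalised for classes they cannot contain. Frequencies of
each SCNA class over fixed genomic bins (default 1 Mb) summarise a cohort:
the fraction of samples with at least one overlapping segment of that
class per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .caller import CallResult
from .seg_io import LABELS, GenomeTable, SegmentProfile


@dataclass
class ScoreReport:
    """Per-class and aggregate scores for one sample (or one cohort unit)."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_f1: float
    accuracy: float
    unit: str = "segment"


def score_sample(
    truth: Sequence[str],
    pred: Sequence[str],
    weights: Sequence[float] | None = None,
    strict_macro: bool = False,
) -> ScoreReport:
    """Score one sample's predicted labels against its truth.

    ``weights`` (typically segment bp lengths) switch to base-pair
    aggregation. ``strict_macro`` averages F1 over all five classes,
    scoring absent classes as 0, instead of the default exclusion of
    classes absent from both truth and prediction.
    """
    if len(truth) != len(pred):
        raise ValueError(
            f"truth and prediction differ in length ({len(truth)} vs {len(pred)})"
        )
    if weights is not None and len(weights) != len(truth):
        raise ValueError("weights must align with truth/pred")
    if not truth:
        raise ValueError("cannot score an empty sample")
    truth = list(truth)
    pred = list(pred)
    w = None if weights is None else np.asarray(weights, dtype=float)

    classes = [l for l in LABELS if strict_macro or l in set(truth) | set(pred)]
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=classes, sample_weight=w, zero_division=0.0
    )
    if w is None:
        accuracy = float(np.mean([t == p for t, p in zip(truth, pred)]))
        raw_support = {c: truth.count(c) for c in classes}
    else:
        hits = np.array([t == p for t, p in zip(truth, pred)], dtype=float)
        accuracy = float(np.average(hits, weights=w))
        raw_support = {
            c: int(sum(wi for t, wi in zip(truth, w) if t == c)) for c in classes
        }
    return ScoreReport(
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        support=raw_support,
        macro_f1=float(np.mean(f1)) if len(f1) else float("nan"),
        accuracy=accuracy,
        unit="segment" if w is None else "base-pair",
    )


@dataclass
class CohortSummary:
    """Cross-sample means plus the retained per-sample distributions."""

    mean_macro_f1: float
    mean_accuracy: float
    mean_f1: dict[str, float]
    per_sample_macro_f1: list[float] = field(repr=False, default_factory=list)
    per_sample_accuracy: list[float] = field(repr=False, default_factory=list)
    n_samples: int = 0


def score_cohort(reports: Sequence[ScoreReport]) -> CohortSummary:
    """Unweighted across-sample means of the per-sample scores."""
    if not reports:
        raise ValueError("cohort summary requires at least one sample report")
    macro = [r.macro_f1 for r in reports]
    acc = [r.accuracy for r in reports]
    per_class: dict[str, list[float]] = {}
    for r in reports:
        for c, v in r.f1.items():
            per_class.setdefault(c, []).append(v)
    return CohortSummary(
        mean_macro_f1=float(np.mean(macro)),
        mean_accuracy=float(np.mean(acc)),
        mean_f1={c: float(np.mean(v)) for c, v in sorted(per_class.items())},
        per_sample_macro_f1=list(map(float, macro)),
        per_sample_accuracy=list(map(float, acc)),
        n_samples=len(reports),
    )


def bin_frequency(
    results: Iterable[CallResult | SegmentProfile],
    genome: GenomeTable,
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Fraction of samples with an SCNA of each class per fixed genomic bin.

    Returns a tidy frame with one row per (chrom, bin) and columns
    ``freq_low_dup`` ("+1"), ``freq_low_del`` ("-1"), ``freq_high_dup``
    ("+2") and ``freq_high_del`` ("-2"). A segment straddling a bin
    boundary counts in every bin it overlaps; each sample counts at most
    once per (bin, class).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    profiles = [r.profile if isinstance(r, CallResult) else r for r in results]
    n_samples = len(profiles)
    if n_samples == 0:
        raise ValueError("bin_frequency requires at least one sample")

    columns = {"+1": "freq_low_dup", "-1": "freq_low_del",
               "+2": "freq_high_dup", "-2": "freq_high_del"}
    counts: dict[str, dict[str, np.ndarray]] = {}
    n_bins: dict[str, int] = {}
    for chrom, length in genome.sizes.items():
        nb = int(np.ceil(length / bin_size))
        n_bins[chrom] = nb
        counts[chrom] = {lab: np.zeros(nb, dtype=int) for lab in columns}

    for prof in profiles:
        seen: dict[str, dict[str, np.ndarray]] = {
            chrom: {lab: np.zeros(nb, dtype=bool) for lab in columns}
            for chrom, nb in n_bins.items()
        }
        for seg in prof.segments:
            if seg.label not in columns:
                continue
            chrom = seg.chrom
            if chrom not in counts:
                raise KeyError(f"segment chromosome {chrom!r} not in genome table")
            first = (seg.start - 1) // bin_size
            last = (seg.end - 1) // bin_size
            last = min(last, n_bins[chrom] - 1)
            seen[chrom][seg.label][first: last + 1] = True
        for chrom in counts:
            for lab in columns:
                counts[chrom][lab] += seen[chrom][lab]

    rows = []
    for chrom, nb in n_bins.items():
        for b in range(nb):
            row = {
                "chrom": chrom,
                "bin_start": b * bin_size + 1,
                "bin_end": min((b + 1) * bin_size, genome.sizes[chrom]),
            }
            for lab, col in columns.items():
                row[col] = counts[chrom][lab][b] / n_samples
            rows.append(row)
    return pd.DataFrame(rows)
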