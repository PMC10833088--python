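"""Reading and writing copy-number segment (SEG) files.

A segment profile is the per-sample output of a segmentation algorithm: a
list of genomic intervals, each carrying one log2 copy-ratio (logR) value.
Two common header dialects are recognised automatically: GISTIC-style
(``Sample, Chromosome, Start, End, Num_Probes, Segment_Mean``) and
DNAcopy-style (``ID, chrom, loc.start, loc.end, num.mark, seg.mean``).

Coordinates are stored 1-based closed internally, so a segment's length is
``end - start + 1``. Normalised length (the fraction of its chromosome a
segment covers) is derived from a chromosome-size table (:class:`GenomeTable`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("-2", "-1", "0", "+1", "+2")

#: chromosomes treated as sex chromosomes after name normalisation
SEX_CHROMS = frozenset({"X", "Y"})

# column-name synonyms accepted under dialect=auto (lower-cased, dots kept)
_SAMPLE_COLS = ("sample", "id", "sample_id", "sampleid", "sample.id")
_CHROM_COLS = ("chromosome", "chrom", "chr")
_START_COLS = ("start", "loc.start", "start.pos", "chromstart")
_END_COLS = ("end", "loc.end", "end.pos", "chromend")
_PROBE_COLS = ("num_probes", "num.mark", "num.probes", "probes", "nprobes")
_LOGR_COLS = ("segment_mean", "seg.mean", "log2", "logr", "log2ratio", "mean")


class SegFormatError(ValueError):
    """Raised when a segment file does not match the expected format."""


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name: strip ``chr`` prefix, upper-case X/Y.

    ``"chr1" -> "1"``, ``"CHRX" -> "X"``, ``"17" -> "17"``.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y"):
        return s.upper()
    return s


@dataclass
class Segment:
    """One genomic interval with a logR value.

    Coordinates are 1-based closed; ``length = end - start + 1``.
    ``norm_length`` is the fraction of the chromosome the segment covers.
    """

    chrom: str
    start: int
    end: int
    logR: float
    n_probes: int | None = None
    norm_length: float = float("nan")
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"segment end < start ({self.chrom}:{self.start}-{self.end})"
            )
        if not math.isfinite(self.logR):
            raise ValueError("segment logR must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_sex(self) -> bool:
        return self.chrom in SEX_CHROMS


@dataclass
class SegmentProfile:
    """All segments of one sample, sorted by (chrom, start)."""

    sample_id: str
    segments: list[Segment]
    genome: str = "custom"

    def __post_init__(self) -> None:
        self.segments.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
                logger.warning(
                    "sample %s: overlapping segments on chr%s (%d-%d vs %d-%d)",
                    self.sample_id, seg.chrom, prev.start, prev.end, seg.start, seg.end,
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_measured_length(self) -> int:
        return sum(s.length for s in self.segments)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)


@dataclass
class GenomeTable:
    """Mapping chromosome name -> length in bp, with normalised names."""

    sizes: dict[str, int]
    provenance: str = "user file"

    def __post_init__(self) -> None:
        norm: dict[str, int] = {}
        for name, length in self.sizes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"non-positive chromosome length for {name!r}")
            norm[normalize_chrom(name)] = length
        self.sizes = norm

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.sizes

    def __getitem__(self, chrom: str) -> int:
        key = normalize_chrom(chrom)
        if key not in self.sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.sizes[key]


def load_genome(
    source: str | Path,
    profiles: Iterable[SegmentProfile] | None = None,
) -> GenomeTable:
    """Load a chromosome-size table.

    ``source`` is one of the bundled assemblies (``"hg19"``/``"hg38"``), a
    path to a two-column whitespace-delimited chrom/length file, or
    ``"infer"`` to approximate lengths as ``max(end)`` per chromosome across
    the given profiles.
    """
    if source in ("hg19", "hg38"):
        text = (
            resources.files("labelseg.data").joinpath(f"{source}.chrom.sizes")
        ).read_text()
        sizes = _parse_sizes(text.splitlines())
        return GenomeTable(sizes, provenance=f"bundled {source}")
    if source in ("infer", "infer-from-data"):
        if not profiles:
            raise ValueError("genome inference requires at least one profile")
        sizes: dict[str, int] = {}
        for prof in profiles:
            for seg in prof.segments:
                key = normalize_chrom(seg.chrom)
                sizes[key] = max(sizes.get(key, 0), seg.end)
        logger.info("genome inferred from data (approximate): %d chromosomes", len(sizes))
        return GenomeTable(sizes, provenance="inferred")
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such genome source: {source}")
    sizes = _parse_sizes(path.read_text().splitlines())
    return GenomeTable(sizes, provenance="user file")


def _parse_sizes(lines: Iterable[str]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in lines:
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed chrom.sizes line: {line!r}")
        sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError("empty chromosome-size table")
    return sizes


def _resolve_columns(columns: list[str], dialect: str) -> dict[str, str | None]:
    """Map canonical roles to actual column names, or raise SegFormatError."""
    lowered = {c.lower(): c for c in columns}

    def find(cands: tuple[str, ...], role: str, required: bool = True) -> str | None:
        for cand in cands:
            if cand in lowered:
                return lowered[cand]
        if required:
            raise SegFormatError(
                f"missing required column for {role!r} "
                f"(accepted names: {', '.join(cands)})"
            )
        return None

    if dialect == "gistic":
        sample_c, chrom_c = _SAMPLE_COLS[:1], _CHROM_COLS[:1]
        start_c, end_c = ("start",), ("end",)
        probe_c, logr_c = ("num_probes",), ("segment_mean",)
    elif dialect == "dnacopy":
        sample_c, chrom_c = ("id",), ("chrom",)
        start_c, end_c = ("loc.start",), ("loc.end",)
        probe_c, logr_c = ("num.mark",), ("seg.mean",)
    else:  # auto
        sample_c, chrom_c = _SAMPLE_COLS, _CHROM_COLS
        start_c, end_c, probe_c, logr_c = _START_COLS, _END_COLS, _PROBE_COLS, _LOGR_COLS

    return {
        "sample": find(sample_c, "sample ID"),
        "chrom": find(chrom_c, "chromosome"),
        "start": find(start_c, "start position"),
        "end": find(end_c, "end position"),
        "probes": find(probe_c, "probe count", required=False),
        "logR": find(logr_c, "logR / segment mean"),
    }


def read_segments(
    path: str | Path,
    genome: GenomeTable | None = None,
    dialect: Literal["auto", "gistic", "dnacopy"] = "auto",
    coords: Literal["one-based-closed", "zero-based-half-open"] = "one-based-closed",
) -> list[SegmentProfile]:
    """Read a SEG file into one :class:`SegmentProfile` per sample.

    Rows with missing/NaN logR are dropped with a warning. Duplicate
    (sample, chrom, start, end) rows keep the first occurrence.
    If ``genome`` is None, chromosome lengths are inferred from the data
    (max end per chromosome) and logged as approximate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.empty:
        raise SegFormatError(f"empty segment file: {path}")
    cols = _resolve_columns(list(df.columns), dialect)

    n_nan = df[cols["logR"]].isna().sum()
    if n_nan:
        logger.warning("dropping %d row(s) with missing logR from %s", n_nan, path.name)
        df = df[df[cols["logR"]].notna()]
    if df.empty:
        raise SegFormatError(f"no rows with finite logR in {path}")

    df = df.copy()
    df["_chrom"] = df[cols["chrom"]].map(normalize_chrom)
    df["_start"] = df[cols["start"]].astype(int)
    df["_end"] = df[cols["end"]].astype(int)
    if coords == "zero-based-half-open":
        df["_start"] += 1

    dup_mask = df.duplicated(subset=[cols["sample"], "_chrom", "_start", "_end"])
    if dup_mask.any():
        logger.warning("dropping %d duplicate segment row(s)", int(dup_mask.sum()))
        df = df[~dup_mask]

    if genome is None:
        inferred = df.groupby("_chrom")["_end"].max().to_dict()
        genome = GenomeTable({k: int(v) for k, v in inferred.items()}, provenance="inferred")
        logger.info("chromosome lengths inferred from data (approximate)")
    else:
        unknown = sorted(set(df["_chrom"]) - set(genome.sizes))
        if unknown:
            raise SegFormatError(
                f"chromosome(s) not in genome table: {', '.join(unknown)}"
            )

    df["_logR"] = df[cols["logR"]].astype(float)
    if cols["probes"] is not None:
        df["_probes"] = df[cols["probes"]]
    else:
        df["_probes"] = None

    profiles: list[SegmentProfile] = []
    for sample_id, grp in df.groupby(cols["sample"], sort=False):
        segments = []
        for chrom, start, end, logr, probes in zip(
            grp["_chrom"], grp["_start"], grp["_end"], grp["_logR"], grp["_probes"]
        ):
            start, end = int(start), int(end)
            segments.append(
                Segment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    logR=float(logr),
                    n_probes=None if probes is None or pd.isna(probes) else int(probes),
                    norm_length=(end - start + 1) / genome[chrom],
                )
            )
        profiles.append(
            SegmentProfile(str(sample_id), segments, genome=genome.provenance)
        )
    return profiles


def write_labeled_segments(
    profiles: Iterable[SegmentProfile], path: str | Path
) -> None:
    """Write labeled profiles as a GISTIC-style SEG file plus a ``label`` column.

    Every segment must carry one of the five state labels; output rows follow
    profile and segment order so a re-read round-trips exactly.
    """
    rows = []
    for prof in profiles:
        for seg in prof.segments:
            if seg.label not in LABELS:
                raise ValueError(
                    f"segment {prof.sample_id} {seg.chrom}:{seg.start}-{seg.end} "
                    f"has invalid label {seg.label!r} (expected one of {LABELS})"
                )
            rows.append(
                {
                    "Sample": prof.sample_id,
                    "Chromosome": seg.chrom,
                    "Start": seg.start,
                    "End": seg.end,
                    "Num_Probes": "" if seg.n_probes is None else seg.n_probes,
                    "Segment_Mean": repr(seg.logR),
                    "label": seg.label,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["Sample", "Chromosome", "Start", "End", "Num_Probes",
                 "Segment_Mean", "label"],
    )
    df.to_csv(path, sep="\t", index=False)
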