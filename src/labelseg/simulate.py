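"""Synthetic tumor segment-profile generator with known ground truth.

Emulates the data a segmentation pipeline produces for an impure tumor
sample: a genome tiled by segments, each with an integer absolute copy
number in the tumor fraction, observed as a logR under the standard
two-population mixture

    logR = log2( (p*cn + (1-p)*2) / (p*psi + (1-p)*2) )

with tumor purity p and tumor ploidy psi. Broad (arm-scale) events carry
low copy changes, focal events can be high amplitude — the length–
amplitude structure the caller exploits. Additive Gaussian noise on the
segment-mean logR shrinks with segment length (longer segments average
more markers); optional over-segmentation splits segments into pieces that
share the truth but get independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .seg_io import GenomeTable, Segment, SegmentProfile

#: noise presets: base SD of the segment-mean logR for a segment of
#: normalised length 1/marker_density (i.e. one "marker unit")
NOISE_PRESETS = {"none": 0.0, "moderate": 0.10, "high": 0.25}

LOGR_FLOOR = -8.0  # reported logR for a pure homozygous deletion (cn=0, p=1)


def expected_logR(
    cn: int, purity: float, ploidy: float = 2.0, floor: float = LOGR_FLOOR
) -> float:
    """Noise-free logR of a clonal event under the purity/ploidy mixture."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    num = purity * cn + (1 - purity) * 2
    den = purity * ploidy + (1 - purity) * 2
    if num <= 0:
        return floor
    return float(np.log2(num / den))


def truth_label(cn: int, ploidy: float = 2.0) -> str:
    """Relative copy-number state implied by an absolute copy number.

    Relative to (rounded) ploidy: gain of 3+ copies -> "+2", gain of 1-2
    -> "+1", neutral -> "0", partial loss -> "-1", total absence -> "-2".
    """
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    base = round(ploidy)
    if cn >= base + 3:
        return "+2"
    if cn > base:
        return "+1"
    if cn == base:
        return "0"
    if cn == 0:
        return "-2"
    return "-1"


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults model a moderately rearranged tumor genome: 22 chromosomes of
    100 Mb, ~4 broad events (one-copy gain/loss spanning >= 20% of a
    chromosome) and ~3 focal events (homozygous deletion or 5-8 copy
    amplification, 1-10 Mb) per sample, at moderate segment-mean noise.
    """

    n_samples: int = 50
    purity: float | tuple[float, float] = 1.0
    ploidy: float = 2.0
    noise_sd: float | str = "moderate"
    n_chromosomes: int = 22
    chrom_length: int = 100_000_000
    broad_event_rate: float = 4.0
    focal_event_rate: float = 3.0
    focal_length_range: tuple[int, int] = (1_000_000, 10_000_000)
    broad_cn_states: tuple[int, ...] = (1, 3)
    focal_cn_states: tuple[int, ...] = (0, 5, 6, 7, 8)
    oversegmentation_splits: int = 0
    marker_density: float = 1000.0  # marker units per whole chromosome
    subclone_fraction: float = 0.0  # optional robustness knob, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.broad_event_rate < 0 or self.focal_event_rate < 0:
            raise ValueError("event rates must be >= 0")
        lo, hi = self.focal_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid focal_length_range")
        if hi >= 0.2 * self.chrom_length:
            raise ValueError("focal events must stay below 20% of a chromosome")
        if self.oversegmentation_splits < 0:
            raise ValueError("oversegmentation_splits must be >= 0")

    def noise_base(self) -> float:
        if isinstance(self.noise_sd, str):
            try:
                return NOISE_PRESETS[self.noise_sd]
            except KeyError:
                raise ValueError(
                    f"unknown noise preset {self.noise_sd!r}; "
                    f"known: {sorted(NOISE_PRESETS)}"
                ) from None
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        return float(self.noise_sd)


@dataclass
class SimTruth:
    """Ground truth for one simulated segment."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    purity: float
    ploidy: float
    true_label: str = field(init=False)

    def __post_init__(self) -> None:
        self.true_label = truth_label(self.cn, self.ploidy)


def _draw_purity(cfg: SimConfig, rng: np.random.Generator) -> float:
    if isinstance(cfg.purity, tuple):
        lo, hi = cfg.purity
        return float(rng.uniform(lo, hi))
    return float(cfg.purity)


def _place_events(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, list[tuple[int, int, int]]]:
    """Draw non-overlapping (start, end, cn) events per chromosome."""
    events: dict[str, list[tuple[int, int, int]]] = {
        str(i + 1): [] for i in range(cfg.n_chromosomes)
    }
    L = cfg.chrom_length

    n_broad = rng.poisson(cfg.broad_event_rate)
    n_focal = rng.poisson(cfg.focal_event_rate)

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(not (end < s or start > e) for s, e, _ in events[chrom])

    for kind, count in (("broad", n_broad), ("focal", n_focal)):
        for _ in range(count):
            placed = False
            for _attempt in range(200):
                chrom = str(rng.integers(1, cfg.n_chromosomes + 1))
                if kind == "broad":
                    frac = rng.uniform(0.2, 1.0)
                    length = max(int(frac * L), int(0.2 * L))
                    cn = int(rng.choice(cfg.broad_cn_states))
                else:
                    length = int(rng.integers(*cfg.focal_length_range))
                    cn = int(rng.choice(cfg.focal_cn_states))
                start = int(rng.integers(1, L - length + 2))
                end = start + length - 1
                if not overlaps(chrom, start, end):
                    events[chrom].append((start, end, cn))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place a {kind} event without overlap after "
                    "200 attempts; reduce event rates or lengths"
                )
    for chrom in events:
        events[chrom].sort()
    return events


def _tile_chromosome(
    chrom: str, length: int, events: list[tuple[int, int, int]], neutral_cn: int
) -> list[tuple[int, int, int]]:
    """Fill the gaps between events with neutral segments; full coverage."""
    tiles: list[tuple[int, int, int]] = []
    pos = 1
    for start, end, cn in events:
        if start > pos:
            tiles.append((pos, start - 1, neutral_cn))
        tiles.append((start, end, cn))
        pos = end + 1
    if pos <= length:
        tiles.append((pos, length, neutral_cn))
    return tiles


def _split_tiles(
    tiles: list[tuple[str, int, int, int]],
    n_splits: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, int]]:
    """Apply ``n_splits`` random over-segmentation cuts genome-wide."""
    tiles = list(tiles)
    for _ in range(n_splits):
        candidates = [i for i, (_, s, e, _) in enumerate(tiles) if e - s >= 1]
        if not candidates:
            break
        i = int(rng.choice(candidates))
        chrom, s, e, cn = tiles[i]
        cut = int(rng.integers(s, e))  # cut after position `cut`
        tiles[i: i + 1] = [(chrom, s, cut, cn), (chrom, cut + 1, e, cn)]
    return tiles


def simulate_sample(
    sample_id: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[SegmentProfile, list[SimTruth]]:
    """Simulate one sample: place events, tile the genome, add noise."""
    purity = _draw_purity(cfg, rng)
    ploidy = cfg.ploidy
    neutral_cn = round(ploidy)
    base_sd = cfg.noise_base()
    L = cfg.chrom_length

    events = _place_events(cfg, rng)
    tiles: list[tuple[str, int, int, int]] = []
    for chrom in (str(i + 1) for i in range(cfg.n_chromosomes)):
        tiles.extend(
            (chrom, s, e, cn)
            for s, e, cn in _tile_chromosome(chrom, L, events[chrom], neutral_cn)
        )
    if cfg.oversegmentation_splits:
        tiles = _split_tiles(tiles, cfg.oversegmentation_splits, rng)

    segments: list[Segment] = []
    truths: list[SimTruth] = []
    for chrom, start, end, cn in tiles:
        norm_len = (end - start + 1) / L
        logr = expected_logR(cn, purity, ploidy)
        if base_sd > 0:
            # segment-mean noise shrinks with the number of markers,
            # itself proportional to normalised length; at least one
            # marker so arbitrarily small gaps keep finite noise
            sd = base_sd / np.sqrt(max(1.0, norm_len * cfg.marker_density))
            logr += float(rng.normal(0.0, sd))
        segments.append(
            Segment(chrom=chrom, start=start, end=end, logR=logr,
                    norm_length=norm_len)
        )
        truths.append(
            SimTruth(sample_id, chrom, start, end, cn, purity, ploidy)
        )
    profile = SegmentProfile(sample_id, segments, genome="simulated")
    # SegmentProfile sorts by (chrom, start); keep truths aligned
    truths.sort(key=lambda t: (_sim_chrom_key(t.chrom), t.start))
    return profile, truths


def _sim_chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, chrom)


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[list[SegmentProfile], list[list[SimTruth]], GenomeTable]:
    """Simulate ``cfg.n_samples`` independent samples, reproducibly.

    Each sample draws from its own child stream of the seed so cohorts are
    reproducible and per-sample streams independent.
    """
    root = np.random.default_rng(cfg.seed)
    child_seeds = root.bit_generator._seed_seq.spawn(cfg.n_samples)
    profiles: list[SegmentProfile] = []
    truths: list[list[SimTruth]] = []
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        prof, tr = simulate_sample(f"sim_{i:04d}", cfg, rng)
        profiles.append(prof)
        truths.append(tr)
    genome = GenomeTable(
        {str(i + 1): cfg.chrom_length for i in range(cfg.n_chromosomes)},
        provenance="simulated",
    )
    return profiles, truths, genome


def truth_frame(truths: Iterable[list[SimTruth]]) -> pd.DataFrame:
    """Flatten per-sample truth lists into one tidy table."""
    rows = [
        {
            "sample": t.sample_id, "chrom": t.chrom, "start": t.start,
            "end": t.end, "cn": t.cn, "purity": t.purity, "ploidy": t.ploidy,
            "true_label": t.true_label,
        }
        for sample in truths
        for t in sample
    ]
    return pd.DataFrame(rows)
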