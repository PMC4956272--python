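"""The chrY mismapping-region mask and per-chromosome UMR percentages.

Six regions of hg19 chrY recurrently attract mis-mapped reads regardless of
fetal sex: in female-fetus pregnancies (no true chrY material) about 92% of
chrY UMRs fall inside them, versus about 20% in male-fetus pregnancies.
Excluding them before computing the chrY percentage widens the male/female
separation by roughly five-fold. Coordinates are 1-based inclusive; each
region is an exact union of default-width bins anchored at position 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import BinTable
from .filtering import AlignedReadRecord
from .genome import CANONICAL_CHROMS, DEFAULT_BIN_WIDTH


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenomicRegionSet:
    """A set of non-overlapping 1-based inclusive regions with optional weights."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(f"overlapping regions: {a} / {b}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def chroms(self) -> set[str]:
        return {r.chrom for r in self.regions}

    @property
    def total_span(self) -> int:
        return sum(r.length for r in self.regions)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(r.contains(chrom, pos) for r in self.regions)

    # -- BED I/O (0-based half-open on disk) ------------------------------
    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicRegionSet":
        regions = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            weight = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else None
            regions.append(Region(chrom, start0 + 1, end, weight))
        return cls(regions)

    def to_bed(self, path: str | Path) -> None:
        lines = [
            "\t".join(
                [
                    r.chrom,
                    str(r.start - 1),
                    str(r.end),
                    f"region{i + 1}",
                    "." if r.weight is None else f"{r.weight:g}",
                ]
            )
            for i, r in enumerate(self.regions)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


#: The six hg19 chrY regions with recurrent cross-sex mismapping, with their
#: relative coverage weights (used as noise weights by the simulator).
DEFAULT_Y_MASK_TABLE: tuple[tuple[int, int, float], ...] = (
    (3_681_127, 3_740_499, 0.016),
    (9_915_292, 10_093_410, 0.023),
    (13_240_180, 13_299_552, 0.008),
    (13_418_299, 13_537_044, 0.039),
    (58_957_390, 59_016_762, 0.167),
    (59_016_763, 59_076_135, 0.014),
)


def default_mask() -> GenomicRegionSet:
    """The built-in six-region chrY mask (hg19, 1-based inclusive)."""
    return GenomicRegionSet(
        [Region("chrY", start, end, weight) for start, end, weight in DEFAULT_Y_MASK_TABLE]
    )


def mask_reads(
    reads: Iterable[AlignedReadRecord], mask: GenomicRegionSet
) -> list[AlignedReadRecord]:
    """Drop reads whose 1-based start lies inside any mask region."""
    return [r for r in reads if not mask.contains(r.chrom, r.pos)]


def mask_counts(bins: BinTable, mask: GenomicRegionSet) -> BinTable:
    """Zero the counts of bins fully contained in a mask region.

    With the default bin width the mask regions are exact unions of bins, so
    containment removes precisely the masked span. Bins only partially
    overlapping a region are left untouched (and a warning is raised, since
    that indicates a width/mask mismatch).
    """
    out = bins.copy()
    df = out.df
    present = set(df["chrom"])
    absent = mask.chroms - present
    if absent:
        warnings.warn(f"mask chromosomes absent from data: {sorted(absent)}")
    contained = np.zeros(len(df), dtype=bool)
    partial = 0
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for region in mask:
        on_chrom = chroms == region.chrom
        full = on_chrom & (starts >= region.start) & (ends <= region.end)
        overlap = on_chrom & (starts <= region.end) & (ends >= region.start)
        partial += int(overlap.sum() - full.sum())
        contained |= full
    if partial:
        warnings.warn(
            f"{partial} bins only partially overlap the mask and were not zeroed; "
            "use the default bin width for exact containment"
        )
    df.loc[contained, ["raw_count", "corrected_count"]] = 0
    return out


@dataclass
class ChromPercentages:
    """Per-chromosome UMR fractions for one sample."""

    fractions: dict[str, float]
    variant: str  # "original" | "masked"
    total_umr: float

    def __getitem__(self, chrom: str) -> float:
        return self.fractions[chrom]


def _count_column(bins: BinTable, column: str | None) -> str:
    if column is not None:
        return column
    return "corrected_count" if bins.df["corrected_count"].sum() > 0 else "raw_count"


def chrom_percentage(bins: BinTable, chrom: str, column: str | None = None) -> float:
    """Fraction of total UMRs (chr1-22, X, Y) mapped to ``chrom``.

    Uses corrected counts when present, else raw counts.
    """
    column = _count_column(bins, column)
    df = bins.df[bins.df["chrom"].isin(CANONICAL_CHROMS)]
    total = float(df[column].sum())
    if total <= 0:
        raise ValueError("total UMR count is zero; cannot compute a percentage")
    return float(df.loc[df["chrom"] == chrom, column].sum()) / total


def chrom_percentages(
    bins: BinTable, variant: str = "original", column: str | None = None
) -> ChromPercentages:
    """All per-chromosome fractions for one sample; they sum to 1."""
    column = _count_column(bins, column)
    df = bins.df[bins.df["chrom"].isin(CANONICAL_CHROMS)]
    totals = df.groupby("chrom", sort=False)[column].sum()
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("total UMR count is zero; cannot compute percentages")
    return ChromPercentages(
        fractions={c: float(v) / grand for c, v in totals.items()},
        variant=variant,
        total_umr=grand,
    )


def discover_noisy_bins(
    cohort: Sequence[BinTable],
    fetal_sex: Sequence[str] | None = None,
    *,
    share_threshold: float = 0.02,
    sample_fraction: float = 0.9,
    chrom: str = "chrY",
    column: str = "raw_count",
    min_female_samples: int = 5,
) -> tuple[GenomicRegionSet, pd.DataFrame]:
    """Recover recurrently over-covered chrY bins from a female-fetus cohort.

    A bin is flagged in one sample when it holds more than ``share_threshold``
    (default 2%) of that sample's chrY UMRs; bins flagged in at least
    ``sample_fraction`` (default 90%) of female samples are kept and adjacent
    kept bins are merged into regions. Returns the region set and a
    per-bin table of exceedance frequencies.

    ``fetal_sex`` gives the known fetal sex per sample ("female"/"male");
    when omitted, all samples are assumed to be female-fetus pregnancies.
    """
    if fetal_sex is None:
        females = list(cohort)
    else:
        females = [b for b, s in zip(cohort, fetal_sex) if s.lower().startswith("f")]
    if len(females) < min_female_samples:
        raise ValueError(
            f"need at least {min_female_samples} female-fetus samples, got {len(females)}"
        )
    ref = females[0].df[females[0].df["chrom"] == chrom]
    starts = ref["start"].to_numpy()
    ends = ref["end"].to_numpy()
    exceed = np.zeros(len(ref), dtype=float)
    for sample in females:
        sub = sample.df[sample.df["chrom"] == chrom]
        if len(sub) != len(ref):
            raise ValueError("cohort samples must share one binning of " + chrom)
        counts = sub[column].to_numpy(float)
        total = counts.sum()
        if total <= 0:
            continue
        exceed += (counts / total) > share_threshold
    freq = exceed / len(females)
    flagged = freq >= sample_fraction
    regions: list[Region] = []
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            regions.append(Region(chrom, int(starts[i]), int(ends[j])))
            i = j + 1
        else:
            i += 1
    table = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "exceedance_frequency": freq}
    )
    return GenomicRegionSet(regions), table
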