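"""Alignment filtering: from mapped reads to uniquely mapped reads (UMRs).

Four exclusion rules are applied, in this order, and each removed read is
charged to the first rule it violates:

1. PCR duplicates (identical chromosome, 1-based start and strand; the
   best-quality read of each group is kept),
2. short alignments (< 35 aligned bases),
3. multi-mapped reads (secondary/supplementary records, or a read name with
   more than one reported alignment),
4. low mapping quality (MAPQ < 10).

A read surviving all four rules is a UMR, the unit every downstream
percentage is computed in.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam

MIN_ALIGNED_LENGTH = 35
MIN_MAPQ = 10


@dataclass(frozen=True)
class AlignedReadRecord:
    """Minimal view of one mapped single-end read.

    ``pos`` is the 1-based leftmost mapping coordinate. ``aligned_length`` is
    the number of aligned bases. ``strand`` is '+' or '-' and participates in
    the duplicate key.
    """

    chrom: str
    pos: int
    aligned_length: int
    mapq: int
    strand: str = "+"
    is_duplicate: bool = False
    is_multimapped: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.aligned_length < 0:
            raise ValueError(f"aligned_length must be >= 0, got {self.aligned_length}")
        if self.mapq < 0:
            raise ValueError(f"mapq must be >= 0, got {self.mapq}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class FilterStats:
    """Disjoint bookkeeping of the four exclusion rules.

    Every input read is charged to exactly one category, so
    ``n_input == n_umr_kept + sum(removals)`` always holds.
    """

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_short_removed: int = 0
    n_multimapped_removed: int = 0
    n_lowq_removed: int = 0
    n_umr_kept: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_duplicates_removed
            + self.n_short_removed
            + self.n_multimapped_removed
            + self.n_lowq_removed
        )

    def check(self) -> None:
        if self.n_input != self.n_umr_kept + self.n_removed:
            raise AssertionError("FilterStats conservation violated")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_short_removed": self.n_short_removed,
            "n_multimapped_removed": self.n_multimapped_removed,
            "n_lowq_removed": self.n_lowq_removed,
            "n_umr_kept": self.n_umr_kept,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def mark_duplicates(reads: Iterable[AlignedReadRecord]) -> list[AlignedReadRecord]:
    """Mark PCR duplicates on a ``(chrom, pos, strand)`` key.

    Within each key group exactly one read ends up with
    ``is_duplicate=False``: preferring uniquely-mapped copies, then the
    highest MAPQ, then the longest alignment (earliest input position breaks
    exact ties). Choosing the keeper by content rather than encounter order
    makes the surviving (chrom, pos, strand, length, mapq) set independent
    of input order.
    Output cardinality equals input cardinality. Idempotent: reads already
    marked as duplicates stay marked and do not claim the keeper slot.
    """
    read_list = list(reads)
    best: dict[tuple[str, int, str], tuple[tuple[int, int, int], int]] = {}
    for i, read in enumerate(read_list):
        if read.is_duplicate:
            continue
        key = (read.chrom, read.pos, read.strand)
        rank = (not read.is_multimapped, read.mapq, read.aligned_length, -i)
        if key not in best or rank > best[key][0]:
            best[key] = (rank, i)
    keep = {i for _, i in best.values()}
    return [
        read
        if i in keep or read.is_duplicate
        else replace(read, is_duplicate=True)
        for i, read in enumerate(read_list)
    ]


def filter_alignments(
    reads: Iterable[AlignedReadRecord],
    *,
    min_aligned_length: int = MIN_ALIGNED_LENGTH,
    min_mapq: int = MIN_MAPQ,
    mark_dups: bool = True,
) -> tuple[list[AlignedReadRecord], FilterStats]:
    """Apply the four exclusion rules and return (UMRs, stats).

    Removal is charged to the first violated rule in the order
    duplicate -> short -> multimapped -> low-quality, keeping the stats
    categories disjoint. With ``mark_dups=False`` the pre-set
    ``is_duplicate`` flags are trusted as-is (count-table and pre-marked BAM
    inputs).
    """
    read_list = list(reads)
    if mark_dups:
        read_list = mark_duplicates(read_list)
    stats = FilterStats(n_input=len(read_list))
    kept: list[AlignedReadRecord] = []
    for read in read_list:
        if read.is_duplicate:
            stats.n_duplicates_removed += 1
        elif read.aligned_length < min_aligned_length:
            stats.n_short_removed += 1
        elif read.is_multimapped:
            stats.n_multimapped_removed += 1
        elif read.mapq < min_mapq:
            stats.n_lowq_removed += 1
        else:
            kept.append(read)
    stats.n_umr_kept = len(kept)
    stats.check()
    return kept, stats


def _record_from_segment(
    seg: pysam.AlignedSegment, multi_names: set[str] | None, index: int
) -> AlignedReadRecord:
    if seg.reference_name is None or seg.reference_start is None or seg.reference_start < 0:
        raise ValueError(f"malformed alignment record at index {index}: missing position")
    if seg.mapping_quality is None:
        raise ValueError(f"malformed alignment record at index {index}: missing MAPQ")
    multimapped = seg.is_secondary or seg.is_supplementary
    if multi_names is not None and seg.query_name in multi_names:
        multimapped = True
    return AlignedReadRecord(
        chrom=seg.reference_name,
        pos=seg.reference_start + 1,
        aligned_length=seg.query_alignment_length or 0,
        mapq=seg.mapping_quality,
        strand="-" if seg.is_reverse else "+",
        is_duplicate=seg.is_duplicate,
        is_multimapped=multimapped,
    )


def read_sam(
    path: str | Path, *, detect_multimap_by_name: bool = True
) -> Iterator[AlignedReadRecord]:
    """Stream mapped records from a SAM/BAM file as :class:`AlignedReadRecord`.

    Unmapped records are dropped silently (the filters operate on mapped
    reads). With ``detect_multimap_by_name`` a first pass collects read names
    with more than one mapped record; all their records are flagged
    multimapped, in addition to records carrying secondary/supplementary
    flags.
    """
    path = str(path)
    multi_names: set[str] | None = None
    if detect_multimap_by_name:
        counts: Counter[str] = Counter()
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for seg in fh:
                if not seg.is_unmapped and seg.query_name is not None:
                    counts[seg.query_name] += 1
        multi_names = {name for name, n in counts.items() if n > 1}
    index = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            yield _record_from_segment(seg, multi_names, index)
            index += 1


def filter_sam(
    path: str | Path,
    *,
    min_aligned_length: int = MIN_ALIGNED_LENGTH,
    min_mapq: int = MIN_MAPQ,
) -> tuple[list[AlignedReadRecord], FilterStats]:
    """Read a SAM/BAM file and return its UMRs plus filter statistics."""
    return filter_alignments(
        read_sam(path), min_aligned_length=min_aligned_length, min_mapq=min_mapq
    )
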