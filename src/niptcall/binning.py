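"""Fixed-width genome bins, UMR counting and LOESS GC correction.

Bin ``k`` (1-based) on a chromosome spans ``[(k-1)*width + 1, min(k*width,
chrom_length)]``, 1-based inclusive on both ends. Counts are read starts per
bin; GC correction divides each bin by the LOESS-fitted expected count at its
GC fraction and rescales so the genome-wide total is conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .filtering import AlignedReadRecord
from .genome import AUTOSOMES, DEFAULT_BIN_WIDTH

BIN_COLUMNS = ["chrom", "start", "end", "gc", "raw_count", "corrected_count"]


@dataclass
class BinTable:
    """Fixed-width genome bins with GC fraction and raw/corrected UMR counts.

    Backed by a pandas DataFrame with columns ``chrom, start, end, gc,
    raw_count, corrected_count`` (coordinates 1-based inclusive; ``gc`` is
    NaN for bins without usable reference sequence).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BIN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"BinTable missing columns: {missing}")

    # -- construction / IO ------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df[BIN_COLUMNS].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def copy(self) -> "BinTable":
        return BinTable(self.df.copy())

    # -- basic queries -----------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def n_bins(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self.df)
        return int((self.df["chrom"] == chrom).sum())

    def total(self, column: str = "corrected_count") -> float:
        return float(self.df[column].sum())

    def chrom_total(self, chrom: str, column: str = "corrected_count") -> float:
        return float(self.df.loc[self.df["chrom"] == chrom, column].sum())

    def counts(self, chrom: str, column: str = "raw_count") -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, column].to_numpy()


def make_bins(chrom_sizes: Mapping[str, int], width: int = DEFAULT_BIN_WIDTH) -> BinTable:
    """Tile each chromosome with fixed-width bins (last bin may be short)."""
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    frames = []
    for chrom, length in chrom_sizes.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n = -(-length // width)  # ceil
        starts = np.arange(n, dtype=np.int64) * width + 1
        ends = np.minimum(starts + width - 1, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "gc": np.nan,
                    "raw_count": 0,
                    "corrected_count": 0.0,
                }
            )
        )
    return BinTable(pd.concat(frames, ignore_index=True))


def count_reads_in_bins(
    umrs: Iterable[AlignedReadRecord],
    bins: BinTable,
    *,
    on_unknown_chrom: str = "error",
) -> BinTable:
    """Assign each read to the bin containing its 1-based start position.

    ``on_unknown_chrom`` is ``"error"`` (default) or ``"skip"`` (drop with a
    warning). Returns a new BinTable; raw counts accumulate on top of any
    counts already present.
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError("on_unknown_chrom must be 'error' or 'skip'")
    out = bins.copy()
    df = out.df
    # per-chromosome row offset and width; bins are contiguous from pos 1
    offsets: dict[str, tuple[int, int, int]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        width = int(sub["end"].iloc[0] - sub["start"].iloc[0] + 1)
        chrom_end = int(sub["end"].iloc[-1])
        offsets[chrom] = (int(sub.index[0]), width, chrom_end)
    counts = np.zeros(len(df), dtype=np.int64)
    n_skipped = 0
    for read in umrs:
        info = offsets.get(read.chrom)
        if info is None:
            if on_unknown_chrom == "error":
                raise ValueError(f"read on unknown chromosome {read.chrom!r}")
            n_skipped += 1
            continue
        row0, width, chrom_end = info
        if read.pos > chrom_end:
            if on_unknown_chrom == "error":
                raise ValueError(
                    f"read position {read.chrom}:{read.pos} beyond chromosome end {chrom_end}"
                )
            n_skipped += 1
            continue
        counts[row0 + (read.pos - 1) // width] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} reads on unknown chromosomes/positions")
    df["raw_count"] = df["raw_count"].to_numpy() + counts
    return out


def gc_from_fasta(
    bins: BinTable, fasta_path: str | Path, *, max_n_fraction: float = 0.5
) -> BinTable:
    """Fill the ``gc`` column from a reference FASTA.

    GC is computed over non-N bases; a bin with more than ``max_n_fraction``
    N bases gets NaN and is excluded from the LOESS fit downstream.
    """
    from pyfaidx import Fasta

    out = bins.copy()
    gc = np.full(len(out.df), np.nan)
    with Fasta(str(fasta_path)) as fasta:
        for i, row in enumerate(out.df.itertuples(index=False)):
            if row.chrom not in fasta:
                continue
            seq = str(fasta[row.chrom][row.start - 1 : row.end]).upper()
            if not seq:
                continue
            n_n = seq.count("N")
            if n_n > max_n_fraction * len(seq):
                continue
            acgt = len(seq) - n_n
            if acgt == 0:
                continue
            gc[i] = (seq.count("G") + seq.count("C")) / acgt
    out.df["gc"] = gc
    return out


class GCCorrector(BaseEstimator, TransformerMixin):
    """LOESS GC-bias correction for bin counts.

    The expected count as a function of GC, ``f(gc)``, is fitted by LOESS of
    raw counts on GC fraction over autosomal bins with defined GC (sex
    chromosomes carry the dosage signal of interest and are excluded from the
    fit but corrected by the same curve). Each bin is corrected
    multiplicatively, ``corrected = raw * m / f(gc)`` with ``m`` the median
    fitted value, then all correctable bins are rescaled so their corrected
    sum equals their raw sum. Bins with missing GC pass through unchanged.

    Parameters
    ----------
    span : float
        LOESS smoothing fraction (default 0.75).
    min_bins : int
        Minimum number of autosomal bins with defined GC and nonzero counts
        required to fit; below this the correction is skipped with a warning
        and corrected = raw.
    fit_chroms : tuple of str, optional
        Chromosomes used for the fit (default: autosomes).
    """

    def __init__(self, span: float = 0.75, min_bins: int = 30, fit_chroms=AUTOSOMES):
        self.span = span
        self.min_bins = min_bins
        self.fit_chroms = fit_chroms

    def fit(self, X: BinTable, y=None) -> "GCCorrector":
        df = X.df
        in_fit = df["chrom"].isin(self.fit_chroms) & df["gc"].notna()
        gc = df.loc[in_fit, "gc"].to_numpy(float)
        counts = df.loc[in_fit, "raw_count"].to_numpy(float)
        n_usable = int(((counts > 0) & np.isfinite(gc)).sum())
        self.n_fit_bins_ = n_usable
        if n_usable < self.min_bins or np.ptp(gc) == 0 or counts.sum() == 0:
            warnings.warn(
                f"GC correction skipped: {n_usable} usable bins (< {self.min_bins}) "
                "or no GC variation; corrected counts equal raw counts"
            )
            self.curve_x_ = None
            self.curve_y_ = None
            self.median_fit_ = None
            return self
        delta = 0.01 * float(np.ptp(gc))
        fitted = lowess(counts, gc, frac=self.span, it=1, delta=delta, return_sorted=True)
        self.curve_x_ = fitted[:, 0]
        self.curve_y_ = fitted[:, 1]
        self.median_fit_ = float(np.median(np.interp(gc, self.curve_x_, self.curve_y_)))
        return self

    def expected_count(self, gc: np.ndarray) -> np.ndarray:
        """Evaluate the fitted LOESS curve f(gc)."""
        if self.curve_x_ is None:
            raise RuntimeError("GCCorrector not fitted or fit was skipped")
        return np.interp(np.asarray(gc, float), self.curve_x_, self.curve_y_)

    def transform(self, X: BinTable) -> BinTable:
        out = X.copy()
        df = out.df
        raw = df["raw_count"].to_numpy(float)
        if getattr(self, "curve_x_", None) is None:
            df["corrected_count"] = raw
            return out
        correctable = df["gc"].notna().to_numpy()
        f = self.expected_count(df.loc[correctable, "gc"].to_numpy(float))
        floor = 1e-6 * max(self.median_fit_, 1e-300)
        if np.any(f <= 0):
            warnings.warn("non-positive LOESS fit values clamped to a positive floor")
            f = np.maximum(f, floor)
        corrected = raw.copy()
        corrected[correctable] = raw[correctable] * self.median_fit_ / f
        # conserve the total count over correctable bins
        raw_sum = raw[correctable].sum()
        corr_sum = corrected[correctable].sum()
        if corr_sum > 0:
            corrected[correctable] *= raw_sum / corr_sum
        df["corrected_count"] = corrected
        return out


def gc_correct(bins: BinTable, span: float = 0.75, min_bins: int = 30) -> BinTable:
    """Fit and apply :class:`GCCorrector` in one step."""
    return GCCorrector(span=span, min_bins=min_bins).fit(bins).transform(bins)
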