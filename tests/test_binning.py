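"""Bin construction, read counting and LOESS GC correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from niptcall import (
    AlignedReadRecord,
    BinTable,
    GCCorrector,
    count_reads_in_bins,
    gc_correct,
    make_bins,
)
from niptcall.binning import gc_from_fasta
from niptcall.genome import DEFAULT_BIN_WIDTH, HG19_CHROM_SIZES


def _read(chrom, pos):
    return AlignedReadRecord(chrom=chrom, pos=pos, aligned_length=100, mapq=60)


class TestMakeBins:
    def test_chrY_default_width(self):
        bins = make_bins({"chrY": HG19_CHROM_SIZES["chrY"]}, DEFAULT_BIN_WIDTH)
        assert bins.n_bins("chrY") == 1001
        last = bins.df.iloc[-1]
        assert last["start"] == 1000 * DEFAULT_BIN_WIDTH + 1
        assert last["end"] == HG19_CHROM_SIZES["chrY"]  # short final bin

    def test_bin_63_starts_at_first_mask_region(self):
        """Bin 63 of chrY starts exactly at 3,681,127 under the default width."""
        bins = make_bins({"chrY": HG19_CHROM_SIZES["chrY"]}, DEFAULT_BIN_WIDTH)
        assert bins.df.iloc[62]["start"] == 3_681_127

    def test_width_equal_to_length_gives_one_bin(self):
        bins = make_bins({"chr1": 500}, 500)
        assert bins.n_bins() == 1
        assert (bins.df.iloc[0]["start"], bins.df.iloc[0]["end"]) == (1, 500)

    @pytest.mark.parametrize("width", [0, -5])
    def test_invalid_width(self, width):
        with pytest.raises(ValueError):
            make_bins({"chr1": 100}, width)


class TestCounting:
    def test_boundary_assignment(self):
        bins = make_bins({"chrY": 200_000}, 59_373)
        reads = [_read("chrY", 1), _read("chrY", 59_373), _read("chrY", 59_374)]
        counted = count_reads_in_bins(reads, bins)
        assert counted.counts("chrY").tolist()[:3] == [2, 1, 0]
        assert counted.total("raw_count") == 3

    def test_empty_stream(self):
        bins = make_bins({"chr1": 1000}, 100)
        counted = count_reads_in_bins([], bins)
        assert counted.total("raw_count") == 0

    def test_unknown_chromosome(self):
        bins = make_bins({"chr1": 1000}, 100)
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_reads_in_bins([_read("chrZ", 5)], bins)
        with pytest.warns(UserWarning, match="skipped 1"):
            counted = count_reads_in_bins([_read("chrZ", 5)], bins, on_unknown_chrom="skip")
        assert counted.total("raw_count") == 0


def _biased_table(n_bins=5000, mean_count=80.0, seed=7, monotone_slope=2.0):
    """Counts ~ Poisson(lambda * g(gc)) with monotone g(gc) = 1 + slope*(gc-0.4)."""
    rng = np.random.default_rng(seed)
    gc = np.clip(rng.normal(0.42, 0.06, n_bins), 0.25, 0.65)
    g = 1.0 + monotone_slope * (gc - 0.4)
    counts = rng.poisson(mean_count * g)
    width = 1000
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * width + 1,
            "end": (np.arange(n_bins) + 1) * width,
            "gc": gc,
            "raw_count": counts,
            "corrected_count": 0.0,
        }
    )
    return BinTable(df)


class TestGCCorrection:
    def test_removes_gc_trend(self):
        """A strong monotone GC bias is flattened: |corr| < 0.1 afterwards."""
        bins = _biased_table()
        raw_corr = np.corrcoef(bins.df["raw_count"], bins.df["gc"])[0, 1]
        assert raw_corr > 0.3  # the bias is real before correction
        corrected = gc_correct(bins)
        after = np.corrcoef(corrected.df["corrected_count"], corrected.df["gc"])[0, 1]
        assert abs(after) < 0.1

    def test_count_conservation(self):
        bins = _biased_table(n_bins=2000)
        corrected = gc_correct(bins)
        raw_sum = bins.df["raw_count"].sum()
        assert abs(corrected.df["corrected_count"].sum() - raw_sum) <= 1e-6 * raw_sum

    def test_scale_equivariance(self):
        bins = _biased_table(n_bins=1500)
        scaled = bins.copy()
        scaled.df["raw_count"] = scaled.df["raw_count"] * 3
        c1 = gc_correct(bins).df["corrected_count"].to_numpy()
        c3 = gc_correct(scaled).df["corrected_count"].to_numpy()
        np.testing.assert_allclose(c3, 3 * c1, rtol=1e-9)

    def test_constant_gc_passthrough(self):
        bins = _biased_table(n_bins=200)
        bins.df["gc"] = 0.45
        with pytest.warns(UserWarning, match="skipped"):
            corrected = gc_correct(bins)
        np.testing.assert_array_equal(
            corrected.df["corrected_count"], bins.df["raw_count"].astype(float)
        )

    def test_all_zero_counts(self):
        bins = _biased_table(n_bins=200)
        bins.df["raw_count"] = 0
        with pytest.warns(UserWarning, match="skipped"):
            corrected = gc_correct(bins)
        assert corrected.df["corrected_count"].sum() == 0

    def test_too_few_bins_skips(self):
        bins = _biased_table(n_bins=20)
        with pytest.warns(UserWarning, match="skipped"):
            corrected = gc_correct(bins)
        np.testing.assert_array_equal(
            corrected.df["corrected_count"], bins.df["raw_count"].astype(float)
        )

    def test_missing_gc_bins_pass_through(self):
        bins = _biased_table(n_bins=1000)
        bins.df.loc[:9, "gc"] = np.nan
        corrected = gc_correct(bins)
        np.testing.assert_array_equal(
            corrected.df.loc[:9, "corrected_count"],
            bins.df.loc[:9, "raw_count"].astype(float),
        )

    def test_sklearn_estimator_contract(self):
        est = GCCorrector(span=0.5)
        assert clone(est).get_params()["span"] == 0.5
        fitted = est.fit(_biased_table(n_bins=500))
        assert fitted.n_fit_bins_ == 500
        assert fitted.median_fit_ > 0

    def test_sex_chromosomes_corrected_but_not_fit(self):
        """chrY bins are corrected by the autosomal curve, not fitted on."""
        bins = _biased_table(n_bins=1000)
        y = bins.df.iloc[:50].copy()
        y["chrom"] = "chrY"
        table = BinTable(pd.concat([bins.df, y], ignore_index=True))
        est = GCCorrector().fit(table)
        assert est.n_fit_bins_ == 1000
        corrected = est.transform(table)
        assert (corrected.df["chrom"] == "chrY").sum() == 50


def test_gc_from_fasta(tmp_path):
    """GC fraction from sequence; N-heavy bins get missing GC."""
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">chrT\n" + "GGCC" * 5 + "ATAT" * 5 + "N" * 20 + "\n")
    bins = make_bins({"chrT": 60}, 20)
    out = gc_from_fasta(bins, fasta)
    gc = out.df["gc"].tolist()
    assert gc[0] == 1.0
    assert gc[1] == 0.0
    assert np.isnan(gc[2])


def test_bintable_tsv_roundtrip(tmp_path, toy_bins):
    path = tmp_path / "bins.tsv"
    toy_bins.to_tsv(path)
    back = BinTable.from_tsv(path)
    pd.testing.assert_frame_equal(back.df, toy_bins.df, check_dtype=False)
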