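"""The six-region chrY mask, chromosome percentages and region discovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from niptcall import (
    AlignedReadRecord,
    BinTable,
    GenomicRegionSet,
    Region,
    chrom_percentage,
    chrom_percentages,
    default_mask,
    discover_noisy_bins,
    mask_counts,
    mask_reads,
)
from niptcall.genome import DEFAULT_BIN_WIDTH
from conftest import random_bin_table


class TestDefaultMask:
    def test_six_regions_total_span(self):
        mask = default_mask()
        assert len(mask) == 6
        assert mask.total_span == 534_357  # nine default-width bins
        assert mask.total_span == 9 * DEFAULT_BIN_WIDTH

    def test_regions_five_and_six_adjacent(self):
        r5, r6 = list(default_mask())[4:]
        assert r6.start == r5.end + 1

    def test_regions_are_exact_bin_unions(self):
        """Every region boundary sits on the default bin grid anchored at 1."""
        for region in default_mask():
            assert (region.start - 1) % DEFAULT_BIN_WIDTH == 0
            assert region.end % DEFAULT_BIN_WIDTH == 0
            assert region.length % DEFAULT_BIN_WIDTH == 0

    def test_bed_roundtrip(self, tmp_path):
        mask = default_mask()
        path = tmp_path / "mask.bed"
        mask.to_bed(path)
        first = path.read_text().splitlines()[0].split("\t")
        assert first[:3] == ["chrY", "3681126", "3740499"]  # 0-based half-open
        back = GenomicRegionSet.from_bed(path)
        assert [(r.chrom, r.start, r.end) for r in back] == [
            (r.chrom, r.start, r.end) for r in mask
        ]

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenomicRegionSet([Region("chrY", 1, 100), Region("chrY", 50, 150)])


class TestMaskReads:
    def _read(self, pos):
        return AlignedReadRecord(chrom="chrY", pos=pos, aligned_length=100, mapq=60)

    def test_boundaries(self):
        mask = default_mask()
        kept = mask_reads(
            [self._read(3_700_000), self._read(3_681_126), self._read(3_681_127)], mask
        )
        assert [r.pos for r in kept] == [3_681_126]

    def test_empty_mask_is_identity(self):
        reads = [self._read(p) for p in (1, 3_700_000)]
        assert mask_reads(reads, GenomicRegionSet([])) == reads


class TestMaskCounts:
    def test_zeroes_contained_bins_only(self, default_genome):
        bins = default_genome.template.copy()
        bins.df["raw_count"] = 1
        masked = mask_counts(bins, default_mask())
        removed = bins.total("raw_count") - masked.total("raw_count")
        assert removed == 9  # nine fully-contained chrY bins

    def test_missing_chromosome_warns(self, toy_bins):
        autosomes_only = BinTable(toy_bins.df[toy_bins.df["chrom"] == "chr1"].copy())
        with pytest.warns(UserWarning, match="absent"):
            out = mask_counts(autosomes_only, default_mask())
        pd.testing.assert_frame_equal(out.df, autosomes_only.df)

    def test_monotone_on_random_samples(self):
        """Masked chrY count and %chrY never exceed the originals (1000 draws)."""
        rng = np.random.default_rng(42)
        mask = GenomicRegionSet([Region("chrY", 501, 900)])  # bins 6-9 of width 100
        for _ in range(1000):
            bins = random_bin_table(rng)
            if bins.total("raw_count") == 0:
                continue
            masked = mask_counts(bins, mask)
            y0 = bins.chrom_total("chrY", "raw_count")
            y1 = masked.chrom_total("chrY", "raw_count")
            assert y1 <= y0
            p0 = chrom_percentage(bins, "chrY", column="raw_count")
            p1 = chrom_percentage(masked, "chrY", column="raw_count")
            assert p1 <= p0 + 1e-12


class TestChromPercentage:
    def test_all_reads_on_one_chromosome(self, toy_bins):
        only_y = toy_bins.copy()
        only_y.df.loc[only_y.df["chrom"] == "chr1", "raw_count"] = 0
        assert chrom_percentage(only_y, "chrY", column="raw_count") == 1.0

    def test_simple_arithmetic(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chrY"],
                "start": [1, 1],
                "end": [100, 100],
                "gc": [0.4, 0.4],
                "raw_count": [999_900, 100],
                "corrected_count": [0.0, 0.0],
            }
        )
        assert chrom_percentage(BinTable(df), "chrY") == pytest.approx(1e-4)

    def test_fractions_sum_to_one(self, toy_bins):
        pcts = chrom_percentages(toy_bins, column="raw_count")
        assert sum(pcts.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert pcts.total_umr == toy_bins.total("raw_count")

    def test_zero_total_errors(self, toy_bins):
        empty = toy_bins.copy()
        empty.df["raw_count"] = 0
        with pytest.raises(ValueError, match="zero"):
            chrom_percentage(empty, "chrY", column="raw_count")

    def test_corrected_preferred_over_raw(self, toy_bins):
        toy_bins.df["corrected_count"] = toy_bins.df["raw_count"] * 2.0
        assert chrom_percentage(toy_bins, "chrY") == pytest.approx(
            chrom_percentage(toy_bins, "chrY", column="raw_count")
        )


def _female_like_table(rng, hot_bins: dict[int, float], n_bins=50, chry_reads=2000):
    """chrY-only table: `hot_bins` maps bin index -> expected share of chrY reads."""
    width = 100
    shares = np.full(n_bins, (1 - sum(hot_bins.values())) / n_bins)
    for idx, share in hot_bins.items():
        shares[idx] += share
    counts = rng.poisson(chry_reads * shares)
    df = pd.DataFrame(
        {
            "chrom": "chrY",
            "start": np.arange(n_bins) * width + 1,
            "end": (np.arange(n_bins) + 1) * width,
            "gc": 0.4,
            "raw_count": counts,
            "corrected_count": 0.0,
        }
    )
    return BinTable(df)


class TestDiscoverNoisyBins:
    def test_single_hot_bin_gives_one_bin_region(self):
        rng = np.random.default_rng(0)
        cohort = [_female_like_table(rng, {10: 0.5}) for _ in range(8)]
        regions, table = discover_noisy_bins(cohort)
        assert [(r.start, r.end) for r in regions] == [(1001, 1100)]
        assert table["exceedance_frequency"].iloc[10] == 1.0

    def test_adjacent_hot_bins_merge(self):
        rng = np.random.default_rng(1)
        cohort = [_female_like_table(rng, {10: 0.3, 11: 0.3}) for _ in range(8)]
        regions, _ = discover_noisy_bins(cohort)
        assert [(r.start, r.end) for r in regions] == [(1001, 1200)]

    def test_uniform_noise_gives_empty_set(self):
        rng = np.random.default_rng(2)
        cohort = [_female_like_table(rng, {}) for _ in range(8)]
        regions, _ = discover_noisy_bins(cohort)
        assert len(regions) == 0

    def test_requires_female_samples(self):
        rng = np.random.default_rng(3)
        cohort = [_female_like_table(rng, {}) for _ in range(8)]
        with pytest.raises(ValueError, match="female"):
            discover_noisy_bins(cohort, fetal_sex=["male"] * 8)

    def test_uses_only_female_samples(self):
        rng = np.random.default_rng(4)
        females = [_female_like_table(rng, {5: 0.5}) for _ in range(6)]
        males = [_female_like_table(rng, {}) for _ in range(6)]
        regions, _ = discover_noisy_bins(
            females + males, fetal_sex=["female"] * 6 + ["male"] * 6
        )
        assert [(r.start, r.end) for r in regions] == [(501, 600)]
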