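"""hg19 canonical chromosome sizes and binning constants.

The default bin width of 59,373 bp reconstructs the implicit windowing of the
chrY mismapping regions: every region boundary satisfies
``(start - 1) % 59373 == 0`` and every region is an exact union of such bins
anchored at position 1.
"""

from __future__ import annotations

#: hg19 (GRCh37) canonical chromosome lengths in bp.
HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("chrX", "chrY")
#: Chromosomes entering the UMR-percentage denominator (chr1-22, X, Y).
CANONICAL_CHROMS: tuple[str, ...] = AUTOSOMES + SEX_CHROMS

#: Default fixed bin width (bp); see module docstring.
DEFAULT_BIN_WIDTH: int = 59_373
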