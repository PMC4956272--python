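"""Synthetic maternal-plasma shallow-WGS cohorts with known truth.

The generator works at bin-count level (the calling method consumes only bin
counts): each sample is a Poisson draw around a per-bin expectation built
from

* a synthetic hg19-like genome — per-bin GC fractions drawn once from a
  fixed ``genome_seed`` so every sample shares the same "reference";
* a smooth GC bias multiplying bin expectations within each chromosome
  (chromosome totals are preserved, so GC bias perturbs bins, not dosage);
* chromosome dosage: autosomes and chrX proportional to length (chrX reduced
  by F/2 for a 45,X fetus);
* chrY mismapping noise present in EVERY sample: a fixed share of total
  reads (default 4.22e-5, the female-cohort chrY level), 92% of it placed in
  the six mask regions according to their coverage weights and 8% uniformly
  over the rest of chrY;
* true fetal chrY signal for male fetuses: ``fetal_fraction *
  chrY_share_adult_male`` of total reads (default 1.73e-3, the adult-male
  chrY percentage), spread uniformly over unmasked chrY bins.

Defaults reproduce the reference cohort levels: female-fetus unmasked %chrY
≈ 4.22e-5 with ≈92% of chrY reads in-region and masked %chrY ≈ 3e-6;
male-fetus unmasked %chrY ≈ 4.22e-5 + F·1.73e-3 with ≈20% in-region at
F ≈ 0.1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinTable, make_bins
from .genome import DEFAULT_BIN_WIDTH, HG19_CHROM_SIZES
from .mask import GenomicRegionSet, default_mask

#: Relative coverage weights of the six mask regions (noise allocation).
_REGION_WEIGHTS = np.array([0.016, 0.023, 0.008, 0.039, 0.167, 0.014])


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Fetal fractions are drawn uniformly from ``[ff_low, ff_high]`` unless
    ``ff_fixed`` pins them (e.g. 0.01 for a low-fetal-fraction stress arm).
    ``seed`` fully determines the output; ``genome_seed`` fixes the shared
    synthetic genome (GC landscape) and is normally left alone.
    """

    n_female: int = 50
    n_male: int = 42
    n_xo: int = 0
    reads_per_sample: float = 5_000_000
    ff_low: float = 0.04
    ff_high: float = 0.20
    ff_fixed: float | None = None
    chrY_share_adult_male: float = 1.73e-3
    region_noise_total: float = 4.22e-5
    in_region_share: float = 0.92
    region_weights: tuple[float, ...] = tuple(_REGION_WEIGHTS / _REGION_WEIGHTS.sum())
    gc_bias: bool = True
    gc_peak: float = 0.42
    gc_curvature: float = 6.0
    bin_width: int = DEFAULT_BIN_WIDTH
    genome_seed: int = 1_000_003
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("region_noise_total", "in_region_share", "chrY_share_adult_male"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ff_fixed is None and not 0 <= self.ff_low <= self.ff_high <= 1:
            raise ValueError("need 0 <= ff_low <= ff_high <= 1")
        w = np.asarray(self.region_weights, float)
        if len(w) != 6 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("region_weights must be six non-negative values")
        self.region_weights = tuple(float(x) for x in w / w.sum())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def gc_bias_curve(gc: np.ndarray, peak: float = 0.42, curvature: float = 6.0) -> np.ndarray:
    """Smooth unimodal efficiency curve in GC, 1 at the peak, floored at 0.1."""
    return np.maximum(0.1, 1.0 - curvature * (np.asarray(gc, float) - peak) ** 2)


class GenomeModel:
    """Shared per-cohort genome: bins, GC landscape, chrY geometry.

    Building this once and drawing many samples from it keeps the cohort
    internally consistent (all samples see the same GC values and bin grid).
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.template = make_bins(HG19_CHROM_SIZES, config.bin_width)
        df = self.template.df
        rng = np.random.default_rng(config.genome_seed)
        gc = np.clip(rng.normal(0.41, 0.05, len(df)), 0.25, 0.70)
        df["gc"] = gc
        self.chroms = list(HG19_CHROM_SIZES)
        self.chrom_slices = {
            chrom: slice(int(sub.index[0]), int(sub.index[-1]) + 1)
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        self.bin_lengths = (df["end"] - df["start"] + 1).to_numpy(float)
        self.bias = (
            gc_bias_curve(gc, config.gc_peak, config.gc_curvature)
            if config.gc_bias
            else np.ones(len(df))
        )
        self._build_chrY_weights()

    def _build_chrY_weights(self) -> None:
        cfg = self.config
        sl = self.chrom_slices["chrY"]
        df = self.template.df.iloc[sl]
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        n = len(df)
        mask = default_mask()
        in_mask = np.zeros(n, dtype=bool)
        noise_w = np.zeros(n)
        for region, weight in zip(mask, cfg.region_weights):
            rows = (starts >= region.start) & (ends <= region.end)
            if not rows.any():
                raise ValueError(
                    "mask region not representable at this bin width; "
                    "use the default width for region-exact simulation"
                )
            in_mask |= rows
            noise_w[rows] = weight / rows.sum()
        out_lengths = self.bin_lengths[sl] * ~in_mask
        out_w = out_lengths / out_lengths.sum()
        #: per-bin share of IN-REGION noise (region weights split over bins)
        self.chrY_mask_noise_w = noise_w
        #: true fetal signal (and out-of-region noise) lives uniformly
        #: outside the mask
        self.chrY_signal_w = out_w
        self.chrY_in_mask = in_mask

    #: config fields baked into the genome; a config passed at draw time may
    #: differ in any other (rate / cohort-size) field
    _GEOMETRY_FIELDS = (
        "bin_width",
        "genome_seed",
        "gc_bias",
        "gc_peak",
        "gc_curvature",
        "region_weights",
    )

    def compatible_with(self, config: SimulationConfig) -> bool:
        return all(
            getattr(self.config, f) == getattr(config, f) for f in self._GEOMETRY_FIELDS
        )

    def expected_fractions(
        self, sex: str, fetal_fraction: float, config: SimulationConfig | None = None
    ) -> np.ndarray:
        """Per-bin expected fraction of total reads for one sample."""
        cfg = config or self.config
        share = cfg.in_region_share
        chrY_noise_w = share * self.chrY_mask_noise_w + (1 - share) * self.chrY_signal_w
        p_signal = fetal_fraction * cfg.chrY_share_adult_male if sex == "male" else 0.0
        p_y = cfg.region_noise_total + p_signal
        chrom_w = {}
        for chrom in self.chroms:
            if chrom == "chrY":
                continue
            w = float(HG19_CHROM_SIZES[chrom])
            if chrom == "chrX" and sex == "xo":
                w *= 1.0 - fetal_fraction / 2.0
            chrom_w[chrom] = w
        norm = (1.0 - p_y) / sum(chrom_w.values())
        p = np.empty(len(self.template.df))
        for chrom in self.chroms:
            sl = self.chrom_slices[chrom]
            bias = self.bias[sl]
            if chrom == "chrY":
                # GC bias is renormalized per component so mismapping noise
                # and fetal signal keep their exact shares and the signal
                # stays strictly outside the mask
                noise = chrY_noise_w * bias
                noise *= cfg.region_noise_total / noise.sum()
                signal = self.chrY_signal_w * bias
                signal *= p_signal / signal.sum() if p_signal > 0 else 0.0
                p[sl] = noise + signal
            else:
                lengths = self.bin_lengths[sl]
                base = lengths / lengths.sum()
                # GC bias modulates bins within a chromosome, not its dosage
                biased = base * bias
                p[sl] = chrom_w[chrom] * norm * biased / biased.sum()
        return p


def simulate_sample(
    config: SimulationConfig,
    sex: str,
    fetal_fraction: float,
    rng: np.random.Generator | int,
    genome: GenomeModel | None = None,
    sample_id: str = "sample",
) -> tuple[BinTable, dict]:
    """Draw one sample; ``sex`` is "female", "male" or "xo" (45,X fetus).

    Returns the bin table (raw counts filled, corrected zeroed) and a truth
    record. ``rng`` may be a Generator or an integer seed.
    """
    sex = sex.lower()
    if sex not in ("female", "male", "xo"):
        raise ValueError(f"sex must be 'female', 'male' or 'xo', got {sex!r}")
    if not 0 <= fetal_fraction <= 1:
        raise ValueError(f"fetal_fraction must be in [0, 1], got {fetal_fraction}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if genome is None:
        genome = GenomeModel(config)
    elif not genome.compatible_with(config):
        raise ValueError("provided GenomeModel was built with a different genome geometry")
    p = genome.expected_fractions(sex, fetal_fraction, config)
    counts = rng.poisson(config.reads_per_sample * p)
    bins = genome.template.copy()
    bins.df["raw_count"] = counts
    truth = {
        "sample_id": sample_id,
        "fetal_sex": "female" if sex == "xo" else sex,
        "karyotype": {"female": "46,XX", "male": "46,XY", "xo": "45,X"}[sex],
        "fetal_fraction": fetal_fraction,
    }
    return bins, truth


def simulate_cohort(
    config: SimulationConfig, genome: GenomeModel | None = None
) -> tuple[list[tuple[BinTable, dict]], pd.DataFrame]:
    """Draw a full cohort; returns samples and a manifest DataFrame.

    Per-sample seeds are spawned deterministically from ``config.seed`` and
    recorded in the manifest, so any single sample can be regenerated.
    """
    if genome is None:
        genome = GenomeModel(config)
    arms = (
        [("female", i) for i in range(config.n_female)]
        + [("male", i) for i in range(config.n_male)]
        + [("xo", i) for i in range(config.n_xo)]
    )
    children = np.random.SeedSequence(config.seed).spawn(len(arms) + 1)
    ff_rng = np.random.default_rng(children[-1])
    samples: list[tuple[BinTable, dict]] = []
    rows = []
    for (sex, i), child in zip(arms, children):
        if config.ff_fixed is not None:
            ff = float(config.ff_fixed)
        else:
            ff = float(ff_rng.uniform(config.ff_low, config.ff_high))
        sample_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        sample_id = f"{sex}_{i:04d}"
        bins, truth = simulate_sample(
            config, sex, ff, sample_seed, genome=genome, sample_id=sample_id
        )
        truth["seed"] = sample_seed
        samples.append((bins, truth))
        rows.append(truth)
    manifest = pd.DataFrame(rows)
    return samples, manifest


def write_cohort(
    samples: Sequence[tuple[BinTable, dict]],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write per-sample bin TSVs and the manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for bins, truth in samples:
        bins.to_tsv(out / f"{truth['sample_id']}.bins.tsv")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def write_sam(
    bins: BinTable,
    path: str | Path,
    rng: np.random.Generator | int,
    read_length: int = 140,
    mapq: int = 60,
) -> None:
    """Emit one SAM read per counted UMR, uniformly placed within its bin.

    Exists to exercise the SAM-parsing path on small simulations; not meant
    for full-depth samples.
    """
    import pysam

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chrom_lengths = {
        chrom: int(sub["end"].max()) for chrom, sub in bins.df.groupby("chrom", sort=False)
    }
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    refs = {c: i for i, c in enumerate(chrom_lengths)}
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for row in bins.df.itertuples(index=False):
            count = int(row.raw_count)
            if count == 0:
                continue
            hi = max(row.start, row.end - read_length + 1)
            positions = rng.integers(row.start, hi + 1, size=count)
            for pos in np.sort(positions):
                seg = pysam.AlignedSegment()
                seg.query_name = f"read{n}"
                seg.reference_id = refs[row.chrom]
                seg.reference_start = int(pos) - 1
                seg.mapping_quality = mapq
                seg.cigarstring = f"{read_length}M"
                seg.flag = 16 if rng.random() < 0.5 else 0
                out.write(seg)
                n += 1
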