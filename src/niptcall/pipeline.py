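"""End-to-end sample processing: counts -> GC correction -> %chrY -> call.

`call_sample` runs one sample through GC correction, computes the chrY
percentage in both the original (unmasked) and optimized (six-region-masked)
variants, classifies fetal sex with the panel matching each variant, and
optionally screens female calls for chrX depletion (suspected 45,X).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinTable, gc_correct
from .inference import (
    PANELS,
    ReferencePanel,
    SexCallResult,
    classify_sex,
    derive_cutoff,
    estimate_fetal_fraction,
    flag_turner,
)
from .mask import GenomicRegionSet, chrom_percentage, default_mask, mask_counts


@dataclass
class FemaleXReference:
    """Normal-female chrX-percentage reference (mean, SD) for 45,X screening."""

    mean: float
    sd: float

    @classmethod
    def from_cohort(cls, pct_chrX_values: Sequence[float]) -> "FemaleXReference":
        values = np.asarray(pct_chrX_values, float)
        return cls(mean=float(values.mean()), sd=float(values.std(ddof=1)))


def prepare_sample(
    bins: BinTable,
    *,
    span: float = 0.75,
    mask: GenomicRegionSet | None = None,
    skip_gc: bool = False,
) -> dict:
    """GC-correct one sample and compute both chrY percentage variants.

    Returns a dict with the corrected BinTable and the original/masked
    chrY and chrX percentages.
    """
    if mask is None:
        mask = default_mask()
    corrected = bins if skip_gc else gc_correct(bins, span=span)
    if skip_gc and corrected.df["corrected_count"].sum() == 0:
        corrected = corrected.copy()
        corrected.df["corrected_count"] = corrected.df["raw_count"].astype(float)
    masked = mask_counts(corrected, mask)
    return {
        "bins": corrected,
        "pct_chrY_original": chrom_percentage(corrected, "chrY"),
        "pct_chrY_masked": chrom_percentage(masked, "chrY"),
        "pct_chrX": chrom_percentage(corrected, "chrX"),
    }


def call_sample(
    bins: BinTable,
    sample_id: str = "sample",
    *,
    panel_original: ReferencePanel | None = None,
    panel_masked: ReferencePanel | None = None,
    mask: GenomicRegionSet | None = None,
    span: float = 0.75,
    skip_gc: bool = False,
    female_x_ref: FemaleXReference | None = None,
) -> dict:
    """Full per-sample result row (both variants; masked call is primary).

    The optimized (masked) variant drives the reported fetal sex; the
    original variant is carried alongside for comparison. The fetal fraction
    for a male call is estimated from the unmasked percentage with the
    original panel (the scale the estimation formula was established on).
    """
    if panel_original is None:
        panel_original = PANELS["paper2016-original"]
    if panel_masked is None:
        panel_masked = PANELS["paper2016-optimized"]
    prep = prepare_sample(bins, span=span, mask=mask, skip_gc=skip_gc)
    cutoff_orig = derive_cutoff(panel_original)
    cutoff_mask = derive_cutoff(panel_masked)
    call_orig = classify_sex(prep["pct_chrY_original"], cutoff_orig)
    call_mask = classify_sex(prep["pct_chrY_masked"], cutoff_mask)
    fetal_fraction = (
        estimate_fetal_fraction(prep["pct_chrY_original"], panel_original)
        if call_mask == "male"
        else None
    )
    flags: set[str] = set()
    if female_x_ref is not None:
        flags = flag_turner(
            prep["pct_chrX"], female_x_ref.mean, female_x_ref.sd, call_mask
        )
    return {
        "sample_id": sample_id,
        "pct_chrY_original": prep["pct_chrY_original"],
        "pct_chrY_masked": prep["pct_chrY_masked"],
        "pct_chrX": prep["pct_chrX"],
        "call_original": call_orig,
        "call_masked": call_mask,
        "call": call_mask,
        "fetal_fraction": fetal_fraction,
        "sca_flags": ",".join(sorted(flags)),
        "cutoff_original": cutoff_orig,
        "cutoff_masked": cutoff_mask,
    }


def result_for_variant(row: dict, variant: str) -> SexCallResult:
    """View one `call_sample` row as a single-variant :class:`SexCallResult`."""
    if variant == "masked":
        pct, call, cutoff = row["pct_chrY_masked"], row["call_masked"], row["cutoff_masked"]
    elif variant == "original":
        pct, call, cutoff = row["pct_chrY_original"], row["call_original"], row["cutoff_original"]
    else:
        raise ValueError(f"variant must be 'original' or 'masked', got {variant!r}")
    return SexCallResult(
        sample_id=row["sample_id"],
        pct_chrY=pct,
        call=call,
        cutoff_used=cutoff,
        variant=variant,
        fetal_fraction=row["fetal_fraction"],
        sca_flags=set(row["sca_flags"].split(",")) - {""},
    )


def call_cohort(
    samples: Sequence[tuple[BinTable, str]],
    **kwargs,
) -> pd.DataFrame:
    """Run `call_sample` over (bins, sample_id) pairs; one row per sample."""
    return pd.DataFrame([call_sample(b, sid, **kwargs) for b, sid in samples])
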