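# Methods

## Model

A maternal-plasma sample is a mixture of maternal and fetal cell-free DNA.
With fetal fraction `F` and a male fetus, the expected chrY UMR percentage
is a linear mixture between two reference levels,

    %chrY_MF = %chrY_FF + F · (%chrY_AM − %chrY_FF),

where `%chrY_FF` (female-fetus median) measures the chrY *mismapping
background* present in every sample and `%chrY_AM` (adult-male median) the
level of a 100% male genome. Inverting the mixture gives the fetal-fraction
estimator; evaluating it at an assumed minimal detectable fetal fraction
`F* = 0.01` gives the sex-call cutoff. Both operations are exact algebraic
inverses of each other (round-trip tested to 1e-12).

The background term is dominated by six hg19 chrY regions (p11.2 ×2, q11.1,
q11.21, q12 ×2; 534,357 bp in total, exactly nine 59,373-bp bins anchored
at position 1) that collect mis-mapped reads regardless of fetal sex. The
"optimized" variant removes reads/bins in these regions before computing
`%chrY`, shrinking the background by roughly 12× while costing male samples
only ~20% of their chrY signal. Each variant uses its own panel medians.

Two masked-variant cutoffs ship: the formula-derived value from the
published masked medians (6.73e-6, the default) and the value printed
alongside them in the original publication (`PUBLISHED_OPTIMIZED_CUTOFF =
2e-5`), which does not follow from the printed medians by the stated
formula. The formula value is preferred because it keeps the cutoff's
meaning (the expected level at F = F*) and, at 5e6 reads, sits ~4σ above
female background noise and ~7σ below a 1%-fetal-fraction male — whereas
2e-5 sits essentially on top of the 1% male level.

## Pipeline conventions

* **UMR filtering.** Rules applied in order duplicate → short (<35 bp) →
  multi-mapped → MAPQ<10, each read charged to the first rule it violates
  so the statistics are disjoint and conserve the input count. Duplicates
  are defined on (chromosome, 1-based start, strand); the kept copy is the
  best one (unique mapping, then MAPQ, then aligned length) so the
  surviving read set does not depend on input order.
* **Binning.** Fixed width 59,373 bp, bin k spanning
  [(k−1)·w+1, min(k·w, L)], 1-based inclusive; reads assigned by start
  position. This width is the unique grid on which all six mask regions are
  exact bin unions, and is configurable.
* **GC correction.** LOESS (span 0.75, one robustifying iteration, `delta`
  interpolation at 1% of the GC range for near-linear cost) of raw count on
  GC over autosomal bins with defined GC; sex chromosomes are corrected by
  the same curve but never fitted on, because their dosage is the signal of
  interest. Correction is multiplicative (ratio of median fitted value to
  the bin's fitted value) followed by a global rescale conserving the total
  over correctable bins to 1e-6. Bins with missing GC (>50% N in the
  reference) pass through unchanged. Fewer than 30 usable bins, zero
  counts, or zero GC variation skip the correction with a warning. Fit
  values ≤0 are clamped to a positive floor. The correction is
  scale-equivariant, so downstream percentages are invariant to depth
  rescaling.
* **Masking.** Bin-level masking zeroes bins fully contained in a region
  (exact on the default grid; partial overlaps warn). Read-level masking
  drops reads whose start lies in a region, ends inclusive. After masking,
  the denominator is recomputed over the remaining UMRs; at the ~3e-5 scale
  of the removed mass the distinction from keeping the original denominator
  is negligible, but the convention is fixed for reproducibility. Only the
  chrY percentage is ever masked.
* **Ties and edge cases.** A sample exactly at the cutoff is called male
  (conservative toward flagging chrY presence). Negative fetal-fraction
  estimates are reported unclamped for QC; estimates >1.5 warn about a
  mis-specified panel. The 45,X flag requires a female call and
  z = (pct_chrX − μ_female)/σ_female < −3; the threshold and the gating are
  this package's operationalization (no published numeric criterion
  exists), exposed as a parameter.

## Region discovery

`discover_noisy_bins` flags a chrY bin when it holds >2% of a sample's chrY
UMRs, keeps bins flagged in ≥90% of female-fetus samples, and merges
adjacent kept bins (so the two published regions that abut at 59,016,762/3
merge into one interval; comparisons are therefore done on base-pair
interval sets). The 2%/90% thresholds operationalize "recurrently,
extraordinarily over-covered" and are configurable.

A statistical caveat: at the default female depth (~210 chrY reads per
sample) the two weakest of the nine mask bins carry only ~2.6–2.9% of chrY
reads in expectation, so the per-sample exceedance of the 2% threshold is a
coin flip with a ~1σ margin and exact recovery at q = 0.9 is not
achievable. The round-trip test therefore uses a designated high-noise
discovery cohort (chrY noise share 1e-3 of reads, 95% in-region) where
per-bin exceedance is unambiguous; it demonstrates that the heuristic
recovers an injected mask exactly when the signal is resolvable, not that
six regions are discoverable from ~50 samples at 5e6 reads with these
exact thresholds.

## Simulator

The simulator emulates what the calling method consumes — bin counts — not
reads (a small SAM emitter exists to exercise the parsing path). Per
sample, expected bin counts are `reads · p_bin` with independent Poisson
draws, where `p_bin` is built from:

* chromosome dosage proportional to hg19 length (chrX scaled by 1 − F/2
  for a 45,X fetus);
* chrY mismapping noise in every sample: `region_noise_total = 4.22e-5` of
  reads (the female-cohort unmasked chrY level), 92% placed in the six
  regions proportional to their published coverage weights and 8% uniform
  over unmasked chrY;
* fetal chrY signal for male fetuses: `F · 1.73e-3` of reads (the
  adult-male chrY percentage) uniform over unmasked chrY bins — no finer
  map of true fetal chrY coverage is available, and placing it outside the
  mask reproduces the observed ~80% retention of male chrY signal after
  masking and the ~20% male in-region share at F ≈ 0.1;
* a synthetic GC landscape: per-bin GC ~ N(0.41, 0.05) clipped to
  [0.25, 0.70], drawn once from a fixed `genome_seed` so all samples share
  one "reference genome", and a quadratic efficiency curve peaking at
  GC = 0.42 (floor 0.1). The bias is renormalized within each chromosome —
  and within each chrY component — so it perturbs bins, not chromosome
  dosage; GC correction is still exercised because percentages are computed
  from corrected bin counts.

Defaults are the reference study conditions: 5e6 reads/sample (the reported
mean unique yield), fetal fraction uniform on [0.04, 0.20] (the reported
male-group range), cohort arms of 50 female / 42 male. Cohort seeds spawn
per-sample generators deterministically; the manifest records each
sample's seed so any sample is individually reproducible, and identical
seeds give byte-identical TSV output.

What the simulator does **not** model: overdispersion beyond Poisson (the
real female masked-%chrY SD is ~2× Poisson), mappability structure inside
chromosomes, fragment-length and sequencing-error effects, maternal X-copy
variation, mosaicism, and multi-fetal pregnancies. Passing tests therefore
demonstrate the pipeline's correctness and the mask's effect under the
stated mixture model, not clinical performance.

## Known limitations

* The published masked adult-male median (3.74e-4) is mutually inconsistent
  with the published male-group masked levels and the ~20% male in-region
  share (which imply a masked adult-male level of ~1.4e-3). The simulator
  follows the male-group levels; consequently fetal-fraction estimates are
  computed on the unmasked scale with the original panel (recovery within
  ~3% in expectation), and masked-scale estimates with the published
  masked panel would be biased for any simulator honoring the male-group
  levels.
* With the formula-derived masked cutoff at 5e6 reads, the female
  background sits ~4σ below the cutoff: across 200 females there is a ~6%
  chance of one Poisson-tail false positive. The error-free-cohort test
  runs at the default seed; it demonstrates the typical behaviour, not a
  zero-FPR guarantee.
* XXY/XXX/XYY genotyping is out of scope (the sex call is the dependency
  they would build on); only the 45,X depletion flag is provided. No CNV
  segmentation, mappability correction, or assembly liftover.
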