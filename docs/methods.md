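# Methods

## The measurement model

A barcoded reporter library couples each candidate enhancer (120 nt) to `k`
unique 16-nt barcodes through a fixed 27-nt linker. After delivery, barcode
abundance in genomic DNA reflects how much library reached a tissue;
abundance in RNA additionally reflects the enhancer's transcriptional
activity there. The quantity of interest is the per-enhancer, per-sample
activity

    α_e,s = (Σ_b RNA_eb / R_s + ε) / (Σ_b DNA_eb / D_s + ε)

where the sums run over the enhancer's barcodes with DNA count ≥ a floor
(default 1; a barcode never seen in DNA carries no usable RNA signal), R and
D are the samples' accepted-read totals (library-size normalization, which
makes α invariant to global depth changes), and ε is a pseudocount (default
10⁻⁶ on normalized units) that keeps α positive and finite. α is a ratio
estimator, not a GLM fit: it is fully closed-form, and its semantics —
activity relative to the negative-control null — are carried by the scoring
step rather than by a count model.

**MAD score.** Activities are compared through a robust z-score of log α
against the negative-control population of the same group:

    score = (log α − median(neg)) / (1.4826 · MAD(neg))

The constant 1.4826 makes the MAD consistent with a normal standard
deviation, so scores read like z-values when the null is roughly log-normal.
Negative controls are scored against the full negative set (including
themselves). A degenerate null (MAD = 0) is an error, not a silent NaN.

**Empirical p-value.** One-sided, add-one:
`p = (1 + #{neg ≥ score}) / (1 + N_neg)`. Ties count against the candidate;
the smallest attainable p is 1/(N+1), so the null size bounds resolution
(a warning fires below 20 negatives).

**Aggregation.** Per-sample log α values are averaged across animals within
a tissue (or tissue type: brain = the five brain regions, liver, HMC3,
other), and scores/p-values are recomputed on the aggregated values. A
`consistent` flag marks enhancers whose per-sample scores disagree in sign
across replicates; nothing is filtered silently.

## Library design

* **Composition** (full default, 461 members): 3 cross-tissue viral
  controls, 30 tissue positive controls (10 each brain / liver / immune),
  10 published-style negatives plus 30 GC-stratified random negatives
  (10 each at 30/50/70% GC, exact G+C counts by construction), 144
  cortical/striatal candidates, 28 MEF2-motif loci each with a
  motif-shuffled and a motif+5-nt-flank-shuffled version, 27 SNP loci as
  ref/alt pairs (8 with an additional local region-disrupt version), and
  labelled placeholder candidates filling the remainder. Scaled-down totals
  shrink categories proportionally while keeping every lineage represented.
* **Coordinates** are 0-based, half-open. Motif shuffles permute the window
  `[start−flank, end+flank)` with a seeded Fisher–Yates draw, redrawing (≤10
  times) if the permutation reproduces a polymorphic window — a disruption
  design should actually disrupt.
* **Barcodes** are rejection-sampled to be globally unique, pairwise Hamming
  distance ≥ 3, and free of the extraction-anchor restriction site. Neither
  constraint follows from the assay itself; they are engineering choices
  that make exact extraction unambiguous and single-error rescue safe.

## Synthetic experiment

The generator's defaults are the study conditions, not tuning knobs:

* **Cloning dropout**: each barcode survives independently with probability
  0.43, matching the measured plasmid-library complexity (57% dropout).
  At k = 20 this gives 8.6 expected barcodes/enhancer and a ~1.3 × 10⁻⁵
  chance that an enhancer loses all barcodes.
* **Tissue panel**: M1, cortex, striatum, hippocampus, hypothalamus, liver,
  kidney, lung, muscle, heart, plus the cultured HMC3 microglia-like line.
  Transduction is 0.95 of surviving barcodes per animal × tissue, reduced
  to 0.5 in muscle and heart to mimic poor viral delivery there.
* **Counts**: DNA counts are gamma–Poisson (negative-binomial-type) with
  shape `dispersion` (default 10, moderate overdispersion) around an even
  share of the sample depth (default 2 × 10⁵ reads/sample, a desk-scale
  choice; tests and examples use 10⁴–10⁵). RNA counts are gamma–Poisson
  around (expected DNA mean) × α_true / baseline scaled to the RNA depth —
  RNA depends on DNA through its mean only, the standard conditional-
  independence assumption for MPRA generative models. Consequently the
  total RNA yield scales with mean activity rather than being renormalized,
  which keeps "doubling α_true doubles the expected RNA mean" exactly true.
* **Activity structure** (default strong-effect model): active classes sit
  at 10 × baseline in their target tissues (cortical and MEF2-baseline in
  brain, liver positives in liver, immune positives in HMC3); motif-shuffled
  variants drop to baseline; the first 8 SNP loci gain a 4 × alt-allele
  effect in brain/HMC3 but not liver.
* **Reads**: `anchor ∥ adjacent bases ∥ barcode ∥ adjacent bases ∥ adapter
  tail` with independent per-base substitutions; no indels, PCR jackpots,
  UMIs or paired ends. Emission is deterministic per seed, to the byte.

What the simulation does **not** emulate: real enhancers' sequence-driven
activity (activities are assigned by class, not predicted from sequence),
PCR amplification noise beyond the gamma–Poisson dispersion, sample-quality
failures, and batch effects across sequencing runs. Passing tests therefore
demonstrate that the pipeline recovers what this generative model encodes —
estimator correctness and calibration — not that it would resolve the
subtler biology of a real screen.

## Quantification

A read is accepted iff the anchor (restriction site + context, 12 nt)
matches at the read start, the 3 nt adjacent to the barcode on each side
match, and the extracted 16-mer resolves uniquely against the whitelist —
each within its configured mismatch allowance, all 0 by default (the
strictest reading of a "matched anchor and adjacent bases" rule). Every
rejection is tallied by reason (`too_short`, `anchor_fail`, `flank_fail`,
`barcode_unmatched`, `barcode_ambiguous`), so accepted + rejected = total
per sample, by construction and by test. With per-base error e and exact
matching, acceptance is (1−e)^34 for the 34 checked positions.

Complexity metrics define "detected" as count ≥ `detection_threshold`
(default 1; the data gives no principled cutoff). Per-sample detection
proportions are reported relative to the cross-sample union of detected
barcodes; note the union itself shrinks as the threshold rises, so only
detected counts, union size and coverage are monotone in the threshold.
The transduction rate follows the convention
`union / (n_enhancers × effective_barcodes_per_enhancer)`, with the
effective number defaulting to the rounded observed mean per enhancer.

## Tests of effects

* **Motif disruption**: per baseline, each brain sample (M1, cortex,
  striatum by default) contributes the pair (baseline MAD score, mean over
  shuffled versions); paired t across samples; BH across baselines. Effect
  is the mean score difference baseline − shuffled.
* **Allelic**: paired ref vs alt per SNP (and ref vs region-disrupt where
  present), liver excluded by default; BH within each comparison family.
  Effect sign distinguishes gain-of-binding alternatives (alt > ref gives a
  negative effect).
* **Group vs negatives**: one-sided Welch t-test; the unequal-variance form
  is the safer default because candidate groups and the negative null have
  no reason to share a variance.
* **Degenerate pairs**: a paired test whose differences are all zero is
  defined as t = 0, p = 1 instead of the NaN a naive implementation
  returns.
* **Correlations**: Spearman rho on pairwise-complete enhancer activities
  per group pair, NA below 10 shared enhancers, large-sample p-values.
* **Prediction interface**: sequences are centered in Ns to the predictor's
  input length (odd remainders put the extra N on the 5' side — arbitrary,
  documented); forward and reverse-complement predictions are averaged
  before correlating with activity. Training or running predictors is out
  of scope.

The t-test unit is the sample; an animal-mean analysis can be had by
aggregating first and testing the aggregated table.

## Numerical and design choices

* Logs are natural; scores are shift-invariant by construction.
* All randomness flows from one master seed through
  `numpy.random.default_rng`; identical config + seed reproduces every
  artifact byte-for-byte (manifests contain no timestamps).
* The MAD-score flag level 1.3 used in reporting is a configurable operating
  point, not a calibrated threshold.
* `effective_barcodes_per_enhancer` is configurable because normalizing a
  union by a rounded per-enhancer mean is a convention, not an identity;
  with the default it can exceed 1 − dropout slightly.

## Limitations

* The ratio estimator ignores barcode-level random effects; with few
  surviving barcodes per enhancer, α is noisy and the empirical p-value's
  resolution is bounded by the negative-control count.
* Amplicon simulation covers substitutions only; indel robustness of the
  extraction is untested by design.
* Transduction is drawn per animal × tissue independently; real animals
  share injection-level variation.
* The acceptance analysis exercises desk-scale problem sizes (full design,
  ~10⁴–10⁵ reads/sample in tests); the same code paths scale to deeper data
  but runtimes will grow linearly in total reads.
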