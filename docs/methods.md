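# Methods

This note documents the statistical model behind `mosatin`, its
assumptions, the defaults that matter, and the numerical choices, in the
order the pipeline applies them.

## Purity estimation

Two independent estimates are combined by taking their maximum.

**From somatic VAFs.** Tumor VAFs of somatic SNVs/indels are clustered
with a one-dimensional Gaussian mixture. Settings: equal-variance (tied)
components — the 1-D analogue of mclust's "E" model — fitted by EM with
k-means initialisation (3 restarts, fixed seed), component count chosen
over 1..5 by BIC with a parsimony rule: a model with more components is
accepted only when it improves BIC by at least 10, "very strong" evidence
on the Kass–Raftery scale. Two failure modes motivated these choices.
Component-specific variances let the mixture place near-zero-width
components on the lattice that fixed-depth read counts impose on VAFs
(depth 100 yields VAFs on a 0.01 grid), tiling a single clonal peak with
spikes; and plain argmin-BIC will split one slightly skewed binomial peak
into two overlapping Gaussians. Both artifacts bias the top cluster mean
— and hence purity — upward. The clonal peak *u* is the highest component
mean below 0.5 (clonal diploid het variants sit at VAF *f*/2 < 0.5);
purity is *f* = 2*u*. If every component mean is ≥ 0.5, the SNV estimate
is reported as unavailable rather than guessed.

**From copy-number/LOH segments.** A heterozygous-loss segment with log2
coverage ratio *r* implies *f* = 2 − 2^(r+1) (at *r* = −1 the tumor is
pure; at *r* = 0 there is no loss signal). A copy-neutral LOH segment
with B-allele fraction *b* has allelic imbalance AI = |*b* − 0.5| and
implies *f* = 2·AI. The segment with the largest |log ratio| (among
het-loss) and the largest AI (among CN-LOH) are used; "largest magnitude"
is the stated proxy for segment strength since no other score is defined
for input segments. Estimates are clipped into [0, 1] with a warning —
noisy log ratios can otherwise exceed the physical range — and the final
purity is the maximum of the available candidates, accounting for clonal
evolution scenarios in which one data type understates purity.

## Contamination estimation

Diploid clonal markers are somatic variants whose tumor VAF falls in
(0.8·*f*/2, 0.6). The lower bound is 80% of the expected clonal diploid
VAF; the 0.6 ceiling excludes LOH-affected and likely-germline sites. On
top of the VAF window, markers overlapping any non-diploid segment are
vetoed: the window alone cannot guarantee diploidy, and the marker set is
meaningful only where two copies are present. Summing the markers'
mutant reads (*M*) and depths (*T*) in the **normal** sample gives the
contamination level.

Two conventions are exposed because the ratio is ambiguous as published:

* `literal_MT` (default): *c* = *M*/*T*, the marker-VAF reading.
* `cell_fraction`: *c* = min(1, 2*M*/*T*). Since the markers are
  heterozygous in the contaminating tumor cells, *M*/*T* measures about
  half of the contaminating cell fraction; the expected-VAF formulas of
  the mosaicism test treat *c* as a cell fraction, so this convention is
  the self-consistent one and is what the simulator's ground truth uses.

The default follows the literal definition; the flag (`--convention`)
makes the factor-of-2 question empirically explorable rather than silently
resolved.

## Mosaicism versus contamination versus inheritance

For a candidate variant with *x* mutant reads of *n* in the normal
sample, the expected VAF under pure contamination at cell fraction *c*
depends on the variant's local copy-number state in the tumor:

| local state | expected VAF *e* | reading |
|---|---|---|
| one-copy loss + LOH | *c*/(2 − *c*) | 1 mutant copy per *c* + 2(1 − *c*) copies |
| copy-neutral LOH | *c* | 2 mutant copies per 2 copies in contaminating cells |
| diploid | *c*/2 | heterozygous in contaminating cells |

The diploid row is an extension so the test is total over inputs; the
LOH rows cover the cases that arise for *TP53* in practice.

Two one-sided exact binomial tests are run per candidate: the
**contamination test** P(X ≥ x | n, e) — upper-tailed because mosaicism
adds mutant reads above *e* — and the **inheritance test**
P(X ≤ x | n, 0.5) — lower-tailed because a mosaic fraction sits below
heterozygous dosage. Sidedness is a design choice (the directional logic
*e* < VAF_mosaic < 0.5); a two-sided variant is available by flag. Both
p-values are Bonferroni-corrected at α = 0.01; the family defaults to all
candidates in the run, with a per-sample option, since the original
family definition is not specified. Verdicts: both tests reject →
**mosaic**; only contamination rejects → **germline**; only inheritance
rejects → **contamination-consistent**; neither → indeterminate. Samples
with no tumor data fall back to a threshold rule: normal VAF ≥ 0.2 is
germline; below 0.2 with supportive clinical history, mosaic; otherwise
indeterminate. Germline and somatic mosaicism cannot be distinguished by
this test.

Tail probabilities are computed in log space by summing `logpmf` terms
with logsumexp, summing the small-probability side directly and
complementing otherwise — scipy's `logsf` saturates to −inf once the
linear survival function underflows, and p-values of order 10⁻⁴⁰ and
below are routine at amplicon depths. log10 p-values are reported
alongside linear ones.

## Signature refitting and per-mutation attribution

Catalogs are SBS-96 counts in the conventional pyrimidine-centred
channel order (substitution major C>A…T>G; 5' then 3' context, A<C<G<T);
purine-reference substitutions are reverse-complemented during channel
assignment, and N-context sites are excluded with a warning.

Exposures are fitted by non-negative least squares and rescaled so that
Σs_k equals the catalog total, making s_k the number of mutations
attributed to signature k (the rescaling is a reporting normalisation;
whether to constrain the sum exactly was an open choice). Signature
presence is decided by greedy forward selection on reconstruction cosine
similarity with a required gain of **0.02** per accepted signature, ties
broken lexicographically for determinism. Three QC rules follow:
signatures never exceeding **150** mutations in any one sample are pruned
cohort-wide (and the per-sample fits re-run on the retained set);
catalogs under **30** SNVs are excluded for any assay, since so few
counts cannot support a stable cosine fit; exome catalogs with
reconstruction cosine below **0.9** are excluded.

Given a sample's detected signatures, the posterior that mutation *m* at
channel *c* arose from signature *i* is s_i·P_{c,i} / Σ_k s_k·P_{c,k},
the denominator running over exactly the detected signatures (the
normalisation forces this set). When no detected signature has mass on
the channel, the attribution is flagged undefined rather than forced.

## Cohort statistics

* **Modal substitution class.** Per-sample 6-class spectra
  (pyrimidine-collapsed); the cohort count of samples whose modal class
  is C>T is tested against a null of p₀ = 1/6 — the chance a given class
  is modal under uniformity — with an upper-tail exact binomial test
  (p₀ is a parameter, not hard-coded). Ties for modal class are reported
  as no modal class and excluded with a warning.
* **Clopper–Pearson** intervals by beta-quantile inversion (exact
  binomial CI).
* **Fisher exact** 2×2, two-sided by hypergeometric enumeration; a zero
  margin yields p = 1. Sidedness of the published comparisons was
  unstated; both reported bounds hold under either.
* **Gene significance across lesion types.** Per-gene p-values for five
  lesion types (SNV, heterozygous deletion, fusion breakpoint, CN-LOH,
  amplification) are combined as p_overall = 1 − (1 − min p)⁵, the CDF
  of the minimum of five independent U(0,1) draws. Independence across
  lesion types is an assumption of this construction. FDR is
  Benjamini–Hochberg (the output labels it as such); computing the
  per-lesion p-values themselves is out of scope — they are inputs.
* **Germline candidate filter:** normal VAF ≥ 0.2, coverage > 20×,
  population MAF < 0.001 (or absent), REVEL > 0.5 for missense variants.
  A missense variant lacking a REVEL score is flagged for manual review
  instead of silently failing, and an optional gene allow-list restricts
  candidates to a curated panel.
* **Flags:** hypermutators are samples with burden > mean + 2·sd (sample
  sd, n − 1 denominator; ≥ 3 samples required); expression class is
  "high" iff FPKM strictly exceeds 5.

## Synthetic cohorts

The generator inverts the estimators' model. Tumor VAF expectations per
SNV: *f*/2 (diploid), *f*/(2 − *f*) (het loss, mutation on the retained
copy), *f* (CN-LOH, mutant allele duplicated). Normal VAF expectations:
the state-specific contamination dosage (*c*/2, *c*/(2 − *c*), *c*; *c*
is the contaminating **cell fraction** in ground truth) plus
mosaic_fraction/2 at designated mosaic loci. Allele counts are binomial
at fixed or Poisson depths, with optional beta-binomial overdispersion;
signature catalogs draw each mutation's causal signature from the
exposure mixture and its channel from that signature's profile, recording
the true cause for calibration benchmarks. All generators are pure
functions of (config, seed).

Defaults mirror the study conditions the estimators face: 200 somatic
SNVs per pair, tumor depth 100, normal depth 500, binomial noise. What
the simulator does **not** emulate: sequencing error, mapping artifacts,
GC-dependent coverage, subclonal structure beyond the planned segment
states, and indels. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under its own model, not
robustness to real-data artifacts.

## Problem sizes used in the validation suites

The recovery suites run 200-SNV pairs over f ∈ {0.3, 0.5, 0.8} ×
c ∈ {0, 0.02, 0.05} with 20 seeds per condition; type-I error of the
contamination test uses 5000 simulated nulls; attribution calibration
uses a 10⁵-mutation catalog; the minimum-p combination is checked against
a 10⁵-draw Monte-Carlo CDF. These sizes give Monte-Carlo standard errors
comfortably below the tolerances being asserted.

## Known limitations

* The factor-of-2 ambiguity between the literal *M*/*T* contamination
  level and its use as a cell fraction is surfaced, not resolved; results
  should state the convention used.
* Purity from VAF clustering assumes a detectable clonal diploid peak
  below 0.5; heavily aneuploid tumors without diploid clonal variants
  need the segment-based estimate or manual purity.
* The mosaicism test treats the contamination level *c* as known; its
  sampling error (typically small, as *T* sums tens of thousands of
  reads) is not propagated.
* Signature forward selection is greedy; strongly collinear signature
  profiles can trade exposure between themselves even when the selected
  set is right. The 150-mutation cohort rule assumes cohort sizes where
  that count is attainable.
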