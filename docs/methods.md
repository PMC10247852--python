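# Methods

This note documents the models and procedures implemented in `ffpewes`,
the defaults they ship with, and what the synthetic cohort does and does
not emulate.

## Coordinates and variant identity

All interval arithmetic is 0-based half-open (BED convention); variant
positions are 1-based (VCF convention), so a variant's anchor base is
`pos − 1`. Region sets are normalized on construction — sorted, with
overlapping *and book-ended* intervals merged — so base counts are
independent of representation.

Variant identity is a normalized `(chrom, pos, ref, alt)` key: multiallelic
records are split, alleles are parsimony-trimmed and, when reference
sequence is available, left-aligned to the canonical leftmost anchored
representation (the usual shift-and-trim fixed point; idempotent by
construction). All comparisons are made on these keys, allele-aware but
genotype-blind: the validation questions here concern whether a variant is
called at all, not whether its genotype matches. Membership of a variant in
a region uses the anchor base only, not the full REF span, matching how
interval tools typically intersect VCF records; an indel whose anchor sits
one base left of a region boundary is therefore outside it.

## Ensemble consensus

A variant enters the ensemble call set when at least `min_callers` (default
2) of the configured callers report it. Consensus is site-level. Where
callers disagree on genotype the genotype of the first supporting caller in
configured order is kept; quality is the maximum across supporting callers
(deterministic and order-independent); annotations merge
first-non-missing-wins. Raising `min_callers` can only shrink the set
(monotonicity is property-tested).

## Concordance and stratification

Against a truth set (reference catalogue, or the blood sample of a matched
pair), TP = keys in both, FN = truth-only, FP = test-only, with
sensitivity = TP/(TP+FN) and PPV = TP/(TP+FP). A ratio with a zero
denominator is reported as missing, never coerced to 0, and missing ratios
are excluded from cohort means. Report tables round half-up (3 decimals for
per-sample benchmark tables, 2 for cohort summaries); cohort summaries
report per-field means and min–max ranges, plus "pooled" ratios recomputed
from the mean counts, the convention of published cohort tables.

The stratification ladder evaluates one comparison over successively
restricted regions: raw target → bases ≥20X in *both* matched samples →
confident regions → cumulative exclusion of difficult-context region sets,
ending with the internally derived problematic regions. The rung order is
configurable; restriction rungs can never increase TP, FP or FN
(asserted in tests).

## Problematic-region discovery

Discordant (FP ∪ FN) positions pooled across samples are clustered per
chromosome by single linkage with gap ≤ `window_bp` (default 100 bp) — the
fixed point of repeatedly sliding a 100 bp window and merging, hence
order-independent. Each cluster becomes the interval
`[min_pos − 1, max_pos)`. Clusters need `min_variants_per_region` members
(default 2 — a lone discordant call is noise, a cluster is a region
enriched for them) and support from `min_samples` distinct samples
(default 1; the analysis drivers use 2). Enrichment is structural, not
statistical: no background-mutation-rate test is performed.

## Coverage QC

fold80 base penalty follows the Picard convention: mean target depth
divided by the depth at the 20th percentile of the sorted per-base depth
vector (nearest rank, `ceil(0.2·n)`). It is exactly 1 on uniform coverage
and undefined (reported missing) when the 20th-percentile depth is 0.

Sequencing success: ≥90% of target bases at ≥20X, boundary inclusive.
Joint low-coverage detection flags a base when ANY of four criteria holds:
≥25% of samples at zero depth (inclusive), maximum depth < 20, summed depth
< 100, or median depth < 20 (all strict). The sum threshold is an absolute
default (calibrated for cohorts of ~24 samples) rather than a per-sample
quantity; all four are configurable in `QCThresholds`.

Gene coverage uses a sliding completeness threshold: a gene counts as
covered at (depth d, fraction f) when at least f of its target bases reach
depth d; the resulting curve is monotone non-increasing in both arguments.

QC-metric correlation reports Spearman's rho and p-value of each
pre-library metric against %≥20X, plus a logistic fit of %≥20X/100 on the
metric — a binomial GLM with a quasi-likelihood (Pearson χ²/df) dispersion
estimate, since per-sample proportions over ~10⁵ bases are far more
dispersed than a unit binomial — with r² reported as the squared Pearson
correlation of fitted versus observed values.

Lab advisories encode the operational rules: sequencing is predicted to
fail above qPCR 10; the enzymatic-fragmentation library protocol is chosen
when average fragment length > 1000 bp or DIN > 3 (strict inequalities);
cohorts are pooled for sequencing in batches of 8 after sorting by qPCR so
each pool shares amplification potential.

## Tiered triage

The frequency filter removes variants at population AF ≥ 5% with no
pathogenic assertion, then keeps variants at AF < 1% plus asserted
pathogenic/likely-pathogenic variants of any frequency; a missing AF counts
as 0 (rare until proven common, mirroring clinical practice of retaining
variants unseen in population databases). The filter is idempotent.
Pathogenicity is consumed as an input annotation; no classification is
computed here.

Referral categories: a familial-variant query reports present/absent
whenever the queried position reaches 20X locally (configurable), *without*
applying the whole-exome success rule — a failed exome can still answer a
positional question; a specified-gene or disease-panel request restricts
the filtered calls accordingly; the general sudden-death strategy runs the
84-gene first-line panel and expands to the 166-gene panel only when the
first tier yields nothing pathogenic.

Yield arithmetic: failed-sequencing cases leave the denominator. The
strict yield counts cases with a pathogenic finding or a confirmed familial
variant; likely-pathogenic and phenotype-relevant VUS findings enter the
inclusive yield only. A knob (`likely_pathogenic_is_positive`) moves
likely-pathogenic calls into the strict count for laboratories that report
them as positive. Strict yield prints half-up to 1 decimal, inclusive to an
integer.

The shipped gene panels are synthetic placeholder lists (plausible
cardiac/RASopathy/aorta gene symbols) with enforced sizes 84/166/27 and
CDGP ⊂ SDGP; real deployments substitute their curated panels.

## Synthetic cohort

The generator provides every pipeline input as a pure function of
`(config, seed)`, at a scale (two 140 kb chromosomes, 1000 exons of 150 bp
with 10 bp flanks → 170 kb target; 10,000 truth variants; 35 FFPE cases, 13
with matched blood) chosen so the entire suite runs in well under a minute
per cohort.

* **Truth catalogue** — variant positions uniform over the target; 10%
  short indels (1–3 bp), SNVs at transition:transversion 2.8 (typical for
  exome-wide human calls); all keys normalized against the simulated
  reference.
* **Planted errors** — each material's call set is the truth minus
  false-negative draws plus novel false positives. FFPE rates default to
  fp ≈ 0.0235 and fn ≈ 0.0305 per truth variant (the matched-cohort
  calibration); blood is an order of magnitude cleaner (0.005/0.001).
  Errors are spatially enriched ×100 inside 50 designated problematic
  exons (~5% of the target), placing ~84% of discordance inside an
  excludable 5% of the exome — the qualitative structure that stratified
  evaluation is designed to expose. Each caller then independently misses
  calls (1–2%) and adds a small private FP set (0.5%), so 2-of-3 consensus
  recovers the material set with fewer private errors than any single
  caller.
* **Coverage** — per-base depth is negative binomial with mean
  220·exp(−0.18·qPCR) and size max(2, 20 − 1.2·qPCR): the expected %≥20X
  crosses the 90% success rule exactly at qPCR 10, so the qPCR>10 failure
  rule emerges from the depth model rather than being asserted. Each sample
  draws a mean-one lognormal (σ = 0.4) library-efficiency multiplier,
  reproducing the scatter real cohorts show around the qPCR trend. Five
  capture-poor exons have expected depth scaled ×0.02 for every sample and
  material, giving the joint low-coverage detector a real target. Blood
  coverage is qPCR-independent (mean 100, size 25).
* **QC table** — qPCR ~ Uniform(0.8, 14.8) (the plausible range for
  archival FFPE extracts; this alone yields ~65% of samples under the
  qPCR≤10 rule), with DIN in [1.2, 6.1] and fragment length in
  [266, 3296] bp negatively coupled to qPCR plus noise, and mapped reads
  decaying exponentially in qPCR.
* **Clinical findings** — 12.5% of cases carry a planted pathogenic variant
  in a first-line-panel gene and 16.7% a phenotype-relevant VUS in the
  expanded panel, with rare planted AF; remaining annotations draw AF from
  a mixture (70% common ≥5%, 15% 1–5%, 15% rare).

### What the generator does not emulate

Error placement is sequence-context free: no C>T deamination strand bias
is planted (switchable in principle; off by default because protocol-level
artifact signatures are not assumed). Coverage is independent across bases
apart from the planted capture-poor exons — no GC, mappability or
probe-tiling autocorrelation — so fold80 values are milder than real
capture data. The toy exome compresses ~40 Mb of real target into 170 kb
while keeping per-sample error *counts* realistic, which inflates pooled
discordance density ~200-fold; consequently the learned blacklist
over-extends beyond the planted regions more than it would at real scale
(visible in the analysis driver's spillover report). Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
planted structure, not performance claims about real FFPE exomes.

## Numerical and design choices

* Half-up decimal rounding for all printed ratios and percentages.
* Undefined ratios propagate as missing, never as 0 or 1.
* Nearest-rank percentiles (no interpolation) for fold80.
* The per-variant FN drop probability is `rate·w/mean(w)` (w = enrichment
  weight), keeping the overall planted rate exact while concentrating
  errors spatially; FP positions are drawn from the same weights over
  non-truth target bases, with alleles uniform over non-reference bases.
* Contig names are canonicalized ("1" ≡ "chr1") at parse time; records on
  unknown contigs are dropped with a logged warning rather than silently
  mismatching.
* Determinism: every generator and the whole pipeline are pure functions of
  the configuration and seed; rerunning with the same config produces
  byte-identical reports (tested), and the run log records a hash of the
  analysis configuration with the output location excluded.

## Problem sizes

Default analysis scale: 170 kb target, 10,000 truth variants, 35 cases
(13 matched pairs), ~50 call sets of ~10,000 variants each. The test suite
uses a reduced cohort (60 kb genome, 1,500 variants, 6 samples) for most
fixtures and the full default cohort for parameter-recovery and
stratification checks.
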