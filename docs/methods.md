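# Methods

This note documents the statistical model behind `cnvburden`, the
choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Study design being modeled

The pipeline targets SNP-array CNV case-control studies: per-individual
CNV calls (deletions at copy number 0–1, duplications at 3–4) from an
HMM-based caller, a gene/exon annotation, and a sample manifest with
array QC metrics and optional trio links. The scientific questions are
(i) whether patients carry a heavier genome-wide burden of rare genic
CNVs than controls, stratified by CNV size, gene content and per-genome
count; (ii) which individual patient CNVs are credible candidates
(patient-specific, independently confirmed, *de novo*); and (iii)
whether patient *de novo* CNVs preferentially overlap an external
reference set of *de novo* CNVs.

## Filtering and merging

Sample QC keeps individuals with call rate > 0.98 (strict), SD(LRR)
< 0.30, GC wave factor strictly inside (−0.04, 0.04) and raw call count
< 100; the first violated rule is recorded. Call retention requires
≥ 10 SNPs, length ≥ 30 kb, caller confidence ≥ 10 (all inclusive) and
≥ 1 bp of exon overlap, evaluated in that first-fail order. UTR exons
count like coding exons.

Merging operates within one (individual, chromosome, copy state) group:
calls < 50 kb apart fuse, as do calls ≤ 200 kb apart when one exceeds
1 Mb; overlapping calls always fuse. Two semantics were possible for
the 1 Mb condition in chains: evaluating it on the original pre-merge
lengths, or on the current (possibly merged) spans. The first is not
idempotent — a merged span can pass 1 Mb and only then reach a
neighbour 50–200 kb away — so this package iterates to a fixed point
re-evaluating lengths on current spans. The result is idempotent,
invariant under input order, and identical to a naive all-pairs
fixed-point closure (both properties are tested against that oracle).
Merged calls span the union, sum SNP counts, keep the minimum
confidence, and take the more extreme copy number of their parts.
Deletions are never merged with duplications: a copy-state-mixing merge
has no coherent dosage interpretation.

## Rare CNVs and the burden scan

A gene's carrier frequency is computed over the combined population of
the analyzed patient group plus controls, each individual counted at
most once per gene per copy mode; a CNV is rare when ≥ 1 of its genes
is strictly below the 1% threshold. Frequencies are recomputed per copy
mode: the joint table from all calls, the deletion and duplication
tables from the respective subsets.

The scan tests 33 hypotheses per size class — (5 gene bins + 6 count
bins) × 3 copy modes — across 5 size classes (165 tests). Size-class
bounds are lower-inclusive, upper-exclusive; CNV lengths are
`end − start`, the convention under which the package reproduces
published interval lengths (chr5:116416478-120055246 → 3.64 Mb). A
patient satisfies a gene bin when ≥ 1 in-class rare CNV has an in-bin
exon-overlap gene count (carrier semantics). The Bonferroni multiplier
is fixed at 33 per size class regardless of degenerate categories; the
residual scan-wide type-I rate is discussed under *Limitations*.

The two-tailed Fisher p-value follows the point-probability convention:
the sum of hypergeometric probabilities of all tables with the observed
margins whose point probability is ≤ that of the observed table, with a
1e-7 relative tie slack. This matches `scipy.stats.fisher_exact` and
R's `fisher.test` and is verified against exhaustive enumeration for
every margin configuration with N ≤ 40. Odds-ratio CIs use the Woolf
log method; a zero cell triggers the Haldane–Anscombe +0.5 correction
and is flagged. Per-gene tests exclude genes impacted only in controls
(testing the enrichment direction only) and control FDR by
Benjamini–Hochberg (`statsmodels` implementation, verified against the
brute-force step-up definition on 1,000 random p-vectors).

## Patient-specific CNVs and scoring

Specificity is gene-based: for each patient CNV, every control
individual's same-copy-state calls are pooled and the shared fraction of
the patient CNV's genes computed; the CNV is patient-specific iff the
maximum over controls is < 100%. A control CNV of the opposite copy
state never disqualifies. CNVs ≥ 50%-covered by blacklist regions, or
recurrent in > 5% of individuals in *both* cohorts, are excluded as
polymorphic.

The pathogenicity score is additive with configurable weights (defaults:
size ≥ 1 Mb +4 / 500 kb–1 Mb +3 / 100–500 kb +2 / 30–100 kb +1;
*de novo* +6 / unknown +2 / inherited +0; > 20 genes +4 / 11–20 +3 /
6–10 +2 / 2–5 +1; known-region overlap +6; blacklist overlap −4; floor
at 0). The published weights behind comparable scores are not
recoverable, so only the ranking behavior (component additivity,
monotonicity, invariance under positive rescaling) is asserted, not any
particular printed score.

## qPCR model

RQ = 2^(−ΔΔCt) per (primer, reference gene, calibrator) combination,
with ΔCt = mean target Ct − mean reference Ct over triplicates and the
calibrator's ΔCt subtracted; a panel yields ≥ 8 RQ values. The
copy-state call uses the t-distribution CI of the mean RQ (n is small,
8–16) against the (0.7, 1.3) window; a CI straddling a threshold
supports no call and is reported inconclusive rather than forced. The
published decision text is ambiguous between CI-based and per-value
thresholds; the four-way CI rule was chosen because it makes the
inconclusive state explicit. Homozygous-deletion wells are censored at
Ct 40 and still called deletions; integer copy-number estimation is out
of scope.

## Exact power

Power is the exact probability of rejection under independent binomials:
k1 ~ Bin(n1, p1), k2 ~ Bin(n2, p2), rejecting when the Fisher p of
(k1, n1−k1, k2, n2−k2) is ≤ α (inclusive, matching standard exact-power
tools). Binomial tail terms below 1e-12 are truncated; the truncation
error is bounded by the number of dropped grid points × 1e-12 (< 1e-6
here) and empirically < 1e-8. One-tailed power uses the enrichment
direction p1 > p2. At the published cohort sizes this reproduces the
reported achieved powers 0.96 (two-tailed, 205 vs 1,953) and 0.87
(one-tailed, 121 vs 1,953) to ±0.01, and 0.95 for the 180-patient
one-tailed case.

## Synthetic-data generator

The generator emulates: 30 shared polymorphic genic loci at population
frequencies log-uniform on (0.005, 0.08) — these exercise the rare rule
and the specificity filter; Poisson(3.5) background calls per genome
with log-normal sizes (median 60 kb, σ = 1.20); and case-injected large
CNVs (uniform 1–4 Mb, ≥ 2 genes, unique random positions). σ and the
background rate were calibrated once so the *post-filter* control
statistics match the cohort being emulated: ~1.35 rare genic CNVs per
control genome, ~2.3% of rare control CNVs ≥ 1 Mb, ~3% control carrier
rate for large genic CNVs (the filters condition on length and genic
content, so the raw log-normal tail sits below the post-filter one).

Case enrichment is solved against the *realized* control carrier rate
q: p1 = OR·q/(1 − q + OR·q), and the injection probability is
(p1 − q)/(1 − q) on top of the cases' own background rate, so the
target odds ratio holds marginally whatever q materializes. Trios copy
every non-*de novo* case CNV into exactly one parent; case-injected
CNVs become *de novo* with probability 0.25 (the fraction observed among
assessable confirmed CNVs in this class of study). QC metrics fail each
rule independently with probability 0.02 (~8% overall sample loss,
similar to real array QC attrition). The qPCR forward model shifts the
target Ct by −log2(dosage/2) with Gaussian replicate noise (σ = 0.1
cycles by default, a typical SYBR-green triplicate spread).

All randomness flows from one config seed through per-stage
`numpy.random.Generator` streams (genome, cohort, trios) with a fixed
draw order documented in the docstrings; a fixed seed gives
byte-identical outputs.

What the generator does **not** model: SNP-marker-level LRR/BAF tracks,
ethnicity structure, X-dosage, locus-specific mutation/recurrence
hotspots, correlated QC failures, or amplification-efficiency artifacts
in qPCR. Tests passing on this simulator therefore establish the
correctness and calibration of the *analysis* under its assumptions,
not robustness to every artifact of real array data.

## Problem sizes used in the test suite

Recovery and type-I experiments run 20 seeds each at the full study
scale (205 cases vs 1,953 controls) on a reduced genome (10 chromosomes
× 30 Mb, 1,200 genes); the exhaustive Fisher oracle covers every margin
configuration with N ≤ 40; BH and merge oracles use 1,000 random
instances; qPCR recovery uses 1,000 noisy panels per dosage. The whole
suite completes in well under five minutes on one CPU.

## Known limitations

* The ×33 per-size-class Bonferroni correction leaves a residual
  scan-wide false-positive expectation of ~0.25 categories per null
  scan (165 tests); across 20 null seeds the observed number of fully
  clean scans ranged from 17 to 20 depending on the seed batch. A
  scan-wide correction was deliberately not added, to keep the
  published testing scheme.
* Several published p-values in this study design's literature are
  internally inconsistent with the stated two-tailed Fisher test (they
  correspond to hypergeometric point probabilities or one-tailed
  cumulative tails); this package always reports the standard two-tailed
  value.
* Specificity scanning is O(patients × controls) on pooled gene sets;
  adequate to a few thousand individuals, not biobank scale.
* The merge rule's fixed-point semantics can fuse chains slightly more
  aggressively than a single-pass reading of the 200 kb rule; the
  difference did not affect any simulated analysis.
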