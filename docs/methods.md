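# Methods

This note records the models behind each stage, the defaults and why, what
the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Germination traits

A dish is a cumulative census: counts of germinated seeds at days 2, 4, 6,
8 out of `sown` (default 20). GR is the final-census fraction, GP the
day-4 fraction, and the germination index

GI = Σₜ GRₜ / Dₜ

sums the germination rate at each census over the days elapsed, so earlier
germination earns more. Two conventions for GRₜ circulate in seed science:
the cumulative rate at day t, or the fraction newly germinated since the
previous census. The cumulative reading is the default
(`germination_index(..., convention="cumulative")`); the interval variant
is a switch. With the cumulative convention GI is monotone non-decreasing
in every census count, and full immediate germination on the 2/4/6/8
schedule gives GI = 25/24.

Relative traits divide the replicate-mean under salt by the replicate-mean
under control. Dishes carry no pairing key, so ratios of per-replicate
pairs would be arbitrary; the ratio of means is used. A zero control mean
makes the ratio undefined: the value is emitted as missing with a warning
and the membership step excludes it.

## Seedling traits

Growth rate is (final − initial height)/duration in cm·day⁻¹; the stress
window defaults to 6 days but duration is a column, not a constant.
Chlorophyll uses the Arnon total-chlorophyll relation for DMSO extracts,
8.02·A663 + 20.21·A645 mg·L⁻¹. The coefficients are module constants;
because only salt/control ratios reach the evaluation, any fixed linear
combination of the two absorbances cancels out of the final scores, so the
exact coefficient choice (total vs a+b computed separately) does not
affect rankings when extraction volume and sample mass are constant.
K⁺/Na⁺ is a plain quotient; Na⁺ = 0 flags the value missing rather than
producing an infinity.

## Fuzzy comprehensive evaluation

Membership is min–max rescaling within one evaluation group × trait across
accessions, hence invariant to affine transforms of the raw trait.
Degenerate traits (max = min) carry no information; all memberships are
set to 0.5 with a warning rather than forcing 0 or 1.

Aggregation is the **sum** of memberships over traits, not the mean: the
published per-concentration scores reach 3.85 over four traits, which a
mean could never produce. The same sum convention is applied to the
five-trait germination stage. Totals sum the per-group scores; an
accession missing a group is excluded rather than silently rescaled.

Ranks are descending competition ranks ("1224"): ties share the smallest
rank and the following rank is skipped. Selection of the tolerant/
sensitive extremes takes the top-k and bottom-k by score with
lexicographic tie-breaks; k_top = 5 and k_bottom = 13 are parameters
matching the screening design, not a rule derived from the scores.

The published 18-accession score table ships with the package
(`data/reference_scores.tsv`) as a verification input. Re-adding its
per-concentration scores reproduces every printed total within 0.01
(exactly for seven accessions), and re-ranking the totals reproduces all
18 printed total ranks. Re-ranking the *printed per-concentration scores*
reproduces the printed rank column only at 0.13 mol·L⁻¹: at 0.17 and 0.22
the printed ranks are internally inconsistent with the printed
(two-decimal) scores — e.g. at 0.22, a score of 0.71 is ranked below a
0.67 — which is what one expects when ranks were computed on unrounded
scores and the table then rounded. The corresponding acceptance test
asserts the full reproduction and therefore fails for those two columns;
this is a property of the published table, not of the ranking code.

## Differential expression

The DE stage is deliberately a minimal NB Wald test, not a DESeq
re-implementation:

* **Normalization** — median-of-ratios size factors (reference = per-gene
  geometric mean over samples; genes with any zero drop out of the
  reference), with a total-count fallback if no gene is expressed
  everywhere.
* **Dispersion** — one α shared by all genes, Var = μ + αμ². Since the
  unbiased within-condition variance satisfies E[s²] = μ + αμ², the excess
  s² − m is regressed through the origin on m² across all genes and both
  conditions; the estimate is clipped at 10⁻⁸.
* **Effect and test** — log₂FC = log₂((m_B+1)/(m_A+1)) on normalized
  condition means (pseudocount 1 keeps zero-count genes finite). The Wald
  statistic is the log-mean difference over its delta-method standard
  error, referred to the standard normal; with α pooled over thousands of
  genes the dispersion is effectively known and the null statistic is
  empirically very close to N(0,1) (simulated null: z-std ≈ 1.008, false
  positive rate ≈ 0.011 at p < 0.01 with 3 replicates per group). At very
  large matrices (≈ 20 000 genes) a KS test can resolve this ~1% residual
  inflation, so the uniformity property test runs at 5 000 genes, where
  the approximation is statistically indistinguishable from uniform.
  p-values are floored at 10⁻¹⁵; BH-adjusted values are reported.
* **Calling** — strict |log₂FC| > 1 and p < 0.01 on the **raw** p-value by
  default (`use_adjusted=True` switches to BH), matching a threshold rule
  stated in terms of p rather than FDR. All-zero genes are ns with p = 1.

This test is not expected to reproduce any specific published DEG list
obtained from real reads with a different tool; what is preserved is the
thresholding logic, the up/down/total bookkeeping identity, planted-effect
recovery (≥ 90 % at a 4-unit log₂ effect) and null calibration (≈ 1 % of
null genes called at p < 0.01, within the ≤ 3 % contract).

FPKM = count·10⁹/(length·library size); library size defaults to the
sample's total counts, giving the identity Σ(FPKM·length) = 10⁹ per
sample.

## Enrichment and TF profiling

Term enrichment is the plain upper-tail hypergeometric test
P(X ≥ k | N, K, n), with the universe per namespace restricted to genes
annotated to that namespace — the same denominator as the cluster
frequency k/n (share of annotated DEGs falling in the term). No
length-bias (GOseq-style) correction is applied; the reported quantities
(significance cut at adjusted p < 0.01, cluster frequency) are
test-family-agnostic. Multiple testing uses Benjamini–Hochberg within each
namespace, an explicit choice where "corrected p" alone would be
ambiguous. TF tallies count up- and down-regulated DEGs per annotated
family; DEGs without TF annotation are simply not TFs.

## Network hubs

Edge lists accept both confidence dialects (0–1 and 0–1000, auto-detected
by any value exceeding 1) and are thresholded at 0.900 by default, the
"highest confidence" STRING convention. Maximal cliques come from
Bron–Kerbosch with pivoting (networkx `find_cliques`), canonicalised to a
deterministic order. MCC(v) = Σ over maximal cliques containing v of
(|C|−1)! is accumulated in exact integer arithmetic — a 14-clique already
scores 13! ≈ 6.2·10⁹ and larger cliques overflow 64-bit floats' integer
range. Isolated nodes score 0 (the singleton "clique" reported by the
enumerator is excluded; (1−1)! = 1 would contradict the convention).
Hub selection is top-k by score with lexicographic tie-breaks, plus the
subnetwork induced by hubs and their direct interactors.

## Synthetic data

The generator provides every input at the screening design's scale:
104 accessions × {control, salt} × 3 dishes of 20 seeds censused on days
2/4/6/8; a shortlist re-screened at 0.13/0.17/0.22 mol·L⁻¹; 20 000-gene
count matrices with 3 replicates per condition; 200 annotation terms over
four namespaces; a PPI graph over 300 nodes with planted cliques of sizes
14/5/3 (the 14-clique mirrors the tied ≈ 13! scores typical of ribosomal-
protein hub tables) on a 1 % Erdős–Rényi background kept below the 0.9
confidence threshold.

* **Germination** — each dish draws its final germinated count
  Binomial(20, p) where the asymptote p is the accession's control level
  (≈ 0.9) times a salt retention factor drawn per accession around 0.85
  (tolerant) or 0.35 (sensitive); germination times follow a logistic
  curve (t₅₀ ≈ 3.5 d, delayed 1 d under salt), and censuses count times ≤
  each census day — monotone and bounded by construction. Between-
  replicate variability is binomial plus the time draw; published tables
  report no replicate variances, so the noise scales are free parameters
  chosen to look like a clean growth-chamber assay.
* **Seedling** — severity rises linearly with concentration to a class
  peak (tolerant 0.2, sensitive 0.6 of the trait lost at the top
  concentration); Na⁺ rises with severity while biomass, growth,
  absorbances and K⁺ fall; multiplicative noise with σ = 0.05 on the log
  scale. Raw absorbances are emitted, not concentrations, so the pipeline
  exercises the chlorophyll conversion.
* **Counts** — NB with a common dispersion (default α = 0.05, a typical
  bulk-RNA-seq value), baselines 10^U(0.5, 3.5), a 5 % planted DEG
  fraction at ±2 log₂ units by default (tests use ±4 for the recovery
  contract), gene lengths uniform on 200–10 000 nt. The full pipeline
  plants a smaller DEG set for the tolerant contrast (40 % of the
  sensitive one, 30 % shared), reproducing the sensitive-perturbed-more
  structure.
* All streams spawn from one root seed with fixed per-generator spawn
  keys, so outputs are byte-reproducible and adding a generator never
  perturbs another.

What the generator does **not** emulate: read-level artifacts (mapping
bias, length-dependent power — hence no GOseq correction is needed on
synthetic data), correlated gene–gene expression, annotation structure
(terms are random gene sets, so enrichment of random DEG sets is null by
construction), and any real genome's gene catalogue. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated models, not performance on real sequencing data.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: DE calibration
and recovery use 5 000-gene matrices over 10 seeds, the end-to-end
pipeline runs the full 20 000-gene default (≈ 1 s), and the clique oracle
checks 200 random graphs of ≤ 12 nodes against exhaustive subset
enumeration. All randomness is seeded; reruns are byte-identical, and
outputs use tab-separated UTF-8 text with "NA" for missing values.
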