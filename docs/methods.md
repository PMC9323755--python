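# Methods

## The generative model

The synthetic generator is the package's study bench: it plants known causal
architectures and reduces them to exactly the marginal summary statistics the
inference modules see in real use.

**Genotypes.** One synthetic chromosome of `n_blocks × snps_per_block` SNPs at
fixed 1 kb spacing, 1-based positions. Within a block, a latent Gaussian AR(1)
process with parameter `rho` (default 0.8) is dichotomized at the MAF-quantile
threshold once per haplotype and the two haplotypes are summed to 0/1/2
dosages; blocks are independent. MAFs are uniform on (0.05, 0.5). The closed
form for the dosage correlation implied by a latent correlation (bivariate
normal orthant probability) is inverted with Brent's method to calibrate the
linkage scenario: the two causal SNPs of a linkage locus share a MAF (the
target correlation is otherwise unreachable after double dichotomization) and
their block's latent parameter is solved so the *dosage* correlation hits
`linkage_r` (default 0.7). Four cohorts (LD reference, GWAS, eQTL, mQTL) are
drawn from this population with disjoint seeded RNG streams, so cross-cohort
genotype correlation is zero by construction — the independent-samples
assumption of summary-data MR.

**Phenotypes.** Per locus, one methylation probe and one expression gene;
scenario semantics:

| scenario   | methylation | expression | trait contribution |
|------------|-------------|------------|--------------------|
| chain      | `m = β_xm g + ε` | `e = β_me m + ε` | `β_ey e` |
| direct     | noise | `e = β_xe g + ε` | `β_ey e` |
| pleiotropy | noise | `e = β_xe g + ε` | `β_xy g` (no e→y path) |
| linkage    | noise | `e = β_xe g₁ + ε` | `β_xy g₂`, corr(g₁,g₂) = `linkage_r` |
| null       | noise | noise | none |

Defaults: `β_xm = β_me = 0.5`, `β_ey = 0.3`, `β_xe = 0.4`, `β_xy = 0.12`
(SD units per SD, or per allele where the regressor is a dosage). Noise
variances default to the complement that makes each phenotype's population
variance one, so the mandatory per-column standardization is a no-op in
expectation and SMR's scale-free ratio recovers path coefficients directly
(e.g. `b_xy → β_ey` under the chain). If planted genetic variance exceeds 0.9
of the trait's unit variance the generator warns and floors the residual at
0.1 — effects are then diluted by the standardization, which is almost never
what an experiment wants; the evaluation experiments are configured to stay
below the bound. Single-locus trait contributions above 10% also warn.

**Summary statistics.** Simple linear regression per SNP (slope, SE,
t-reference p clipped away from exact zero, counted-allele frequency, n),
vectorized and chunked so genome-sized scans never materialize large float
matrices. cis-QTL tables pair each probe with its own LD block only — between
blocks LD is zero, so all omitted trans signal is null by construction.
Alleles are coded A1 = G (effect/counted), A2 = A throughout the generator;
harmonization for externally supplied files (swap detection with sign/frequency
flips, strand-ambiguous A/T–C/G drops when |freq − 0.5| < 0.15,
irreconcilable-pair drops) lives in `postgwas.io` and is involutive.

## Statistical machinery

**SMR.** Top instrument = smallest exposure p below 5×10⁻⁸ within ±2 Mb of
the probe (ties: larger |z|, then smaller bp). Delta-method variance
`var(b_xy) ≈ se_zy²/b_zx² + b_zy² se_zx²/b_zx⁴`. The Bonferroni threshold is
always `α / probes actually tested in the run` — mirroring how dataset-specific
cutoffs arise in practice.

**HEIDI.** Candidates: cis SNPs with exposure p < 1.57×10⁻³ and r² with the
top SNP in [0.05, 0.9], capped at the 20 most significant; fewer than 3 ⇒ not
testable, and such probes are retained with a flag rather than discarded. The
vector of ratio differences `d_i = b_xy(i) − b_xy(top)` gets its full
delta-method covariance, with LD-induced covariance `r_ij se_i se_j` within
the outcome and within the exposure (cohorts are independent, so no
cross-covariance). `T_HEIDI = Σ z_d²` is referred to a `Σ λ_k χ²₁` mixture
with λ the eigenvalues of the z_d correlation matrix. The mixture tail is
computed by Imhof's characteristic-function inversion — implemented as a
vectorized Simpson rule over a grid fine enough to resolve the phase
oscillation, truncated where Imhof's bound puts the tail below 10⁻⁸ — with
Satterthwaite two-moment matching as numerical fallback. Accuracy against
χ² special cases and Monte Carlo is ~10⁻⁸ at ~10 ms per call. Singular
difference covariances are ridge-regularized by 10⁻⁶ and logged.

**TWAS.** Ridge (not elastic-net) prediction weights on cis dosages — closed
form and deterministic, which the synthetic bench values more than sparsity;
penalty chosen on a small grid by 5-fold CV with seeded fold assignment, and
the out-of-fold squared correlation is the reported performance R²
(filter: R² > 0.01 and p < 0.05). Model SNPs missing from the GWAS are
dropped with σ_g recomputed; a gene is skipped when over half its absolute
weight mass is lost. COLOC priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵,
W = 0.15²; the colocalization pass is PP4 ≥ 0.5 (configurable — "acceptable
evidence" has no canonical threshold).

**Mediation.** Chains are the strict join of the three pass sets (gene passes
trait~eQTL, site passes trait~mQTL, pair passes mQTL~eQTL within 2 Mb); a
chain cannot exist with a missing leg. Direction consistency
(`sign(b_m→y) = sign(b_m→e · b_e→y)`) is reported, never filtered on — the
sign bookkeeping is informative but a causal chain with measurement noise can
legitimately wobble. Nearest-gene distances use 1-based inclusive intervals,
distance 0 inside a gene body, ties to the smaller start coordinate, and the
with/without-evidence comparison is summarized by medians and quartiles
(descriptive only).

**Scoring and enrichment.** Base list membership requires one of the four
merge sources (coding consequence, multilayer, TWAS, coregulation); the score
counts six (MX and SMR separately, plus mediation), with the
most-highly-prioritized tier at score ≥ 4. "Novel" is relative to a
caller-supplied known-gene list. Replication takes the minimum p across
methods and traits of evidence; genes missing from replication models count
as not replicated by default (conservative, configurable). Fisher enrichment
is exact hypergeometric (no approximation); the two-sided p uses the
point-probability convention; fold change is observed overlap over its
hypergeometric expectation; the default universe is the genes with any tested
evidence in the run — a genome-wide universe would overstate enrichment of
any GWAS-adjacent set.

## Evaluation experiments (`postgwas.validate`)

Fixed study conditions: GWAS n = 20,000, molecular QTL n = 5,000, LD
reference n = 2,000 — a desk-scale emulation of a large consortium GWAS
instrumented with blood QTL panels. Specifics per experiment:

* *SMR calibration*: 2000 probes, heritable expression, genetically null
  trait (pleiotropy scenario with `β_xy = 0`); rejection rate at 0.05 and KS
  uniformity at the 1% level.
* *SMR recovery*: 200 single-chain replicates, `β_ey = 0.3`. Top-instrument
  selection induces a small winner's-curse deflation of `b_xy` that is ~10%
  at n = 2,000/1,000 but ~0.2% at the study conditions; the consistency
  property test checks the bias shrinks with n.
* *HEIDI discrimination*: 150 linkage (r = 0.7) vs 150 chain replicates,
  30-SNP blocks at rho 0.85; rejection at P < 0.01.
* *TWAS oracle*: 100 genes (half signal at `β_ey = 0.1` so fifty signal loci
  fit in unit trait variance, half null), summary Z computed with LD from the
  same cohort as the GWAS so the comparison isolates the summary-vs-individual
  algebra.
* *COLOC*: shared = direct scenario, distinct = linkage at r = 0.5, plus
  null; modal-hypothesis rates over 100 replicates.
* *3×SMR*: 10 chains among 25 non-chain loci with `β_xm = β_me = 0.6`,
  `β_ey = 0.22` (summed trait variance < 1); recall and false chains.
* *Tissue ranking*: 8 tissues × 3 traits × 2 methods × 200 genes, one tissue's
  Z at 1.5× SD; top-rank rate.
* *Fisher*: exhaustive equivalence with integer-arithmetic enumeration over
  all 635,375 tables with N ≤ 60.
* *Curated tables*: the bundled published evidence and replication tables are
  pushed through the package's scoring filter and replication threshold.

What passing shows — and does not. The generator's LD is blockwise AR(1)
with clean 0/1/2 dosages: no imputation dosage noise, no MAF-LD coupling, no
relatedness, no sample overlap between exposure and outcome cohorts, no
trans effects, one trait. Calibration and recovery on this bench validate the
statistical machinery and its implementation, not robustness to those
real-data complications; the harmonization and threshold logic is exercised,
but allele-frequency mismatch between cohorts is not simulated.

## Numerical and degenerate-input choices

Zero-variance SNPs are dropped from summary statistics (logged) and raise on
direct LD queries. Underflowing p-values clip to the smallest subnormal, so
perfect associations survive validation. Probes without an eligible
instrument are skipped, not errors; empty inputs yield empty tables
end-to-end. The chain intersection on empty scans is empty. Eigenvalues below
10⁻¹² are dropped from the mixture. The per-stage RNG streams derive from
`SeedSequence([seed, stream])` with fixed stream ids per cohort and
experiment, so adding a stage cannot silently shift another stage's draws.

## Known limitations

Single chromosome and single trait per simulated study (the prioritization
layer accepts per-trait gene sets from repeated runs); ridge rather than
elastic-net weights diverges from PredictDB practice and yields denser
models; no proportion-mediated decomposition; no sample-overlap correction;
HEIDI is a conservative screen and its not-testable probes pass by
convention, which slightly favors retention at sparse loci.
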