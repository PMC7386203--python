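# Methods

## Model

### Variant effect scores

Every protein-affecting variant carries an effect score *s* ∈ [0, 1]
interpreted as the probability that the gene product retains its
function given the variant.  Nonsense, frameshift and canonical
splice-site variants are assumed to be complete loss-of-function and
are fixed at *s* = 0.  Missense scores are an external input: a
machine-learning damage predictor produces them in practice, and the
package accepts them pre-computed in the variant table or through a
pluggable scorer callable; the synthetic cohorts draw them from a Beta
distribution.  In-frame indels use a rule based on the numbers of
substituted, inserted and deleted amino acids:

    s = max(0, 1 − (n_sub·w_sub + n_ins·w_ins + n_del·w_del))

with all three weights defaulting to 0.05 and exposed in the TOML
config.  The rule is monotone decreasing in each count, exactly 1 when
no residue is affected, and saturates at 0; it is deliberately simple —
any monotone rule with those anchor points would serve, and the weights
are configuration, not science.

### Per-variant aggregation quantities

For variant *i* with genotype probabilities (p₀, p₁, p₂) (alternate
allele present 0, 1 or 2 times) the gene-retention probability is

    x_i = p0 + p1·s_i + p2·(μ·s_i + (1−μ)·s_i²)

The parameter μ ∈ [0, 1] is the probability that the two allele copies
of a homozygous genotype act as one event (μ = 1: damage is s_i, as in
the heterozygous case) rather than independently (μ = 0: s_i²).  The
probability that variant *i* damages exactly one of the two gene
copies is

    y_i = p1·(1−s_i) + p2·(1−μ)·2·s_i·(1−s_i)

— a fully dependent homozygous variant cannot hit exactly one copy,
hence the (1−μ) factor.

### Gene scores

The dominant score softens the independence product ∏xᵢ through a
p-norm:

    D = exp(−‖(log 1/x₁, …, log 1/x_k)‖_p)

p = 1 recovers the product (independent variants); p = ∞ gives min xᵢ
(the most damaging variant dominates).  The recessive score expresses
P(at most one hit): with ζ_q = ‖(yᵢ/xᵢ)‖_q,

    R = (1 + ζ_q)·D_p

extended by continuity when retention probabilities vanish:

| condition | R |
| --- | --- |
| two or more xᵢ = 0 | 0 |
| exactly one xᵢ = 0, p > 1 | yᵢ |
| exactly one xᵢ = 0, p = 1 | yᵢ·∏_{j≠i} xⱼ |
| all xᵢ ≠ 0 | (1 + ζ_q)·D_p |

Genes with no variants in a sample score exactly 1 in both matrices.
Because genotypes are unphased, distinct variants are assumed to hit
distinct gene copies; compound heterozygosity (two heterozygous
loss-of-function variants in one gene) therefore drives R to 0, which
is the recessive signal per-variant tests cannot see.

### Parameters

| parameter | range | default | meaning |
| --- | --- | --- | --- |
| μ_D | [0, 1] | 1 | homozygous dependence in the dominant x |
| p_D | [1, ∞] | 1.25 | inter-variant dependence norm for D |
| μ_R | [0, 1] | 0.5 | homozygous dependence in the recessive x and y |
| p_R | [1, ∞] | ∞ | inter-variant dependence norm inside R |
| q_R | [1, ∞] | 3 | norm of the single-hit correction ζ |

The defaults are the published values fitted on known gene–disease
associations; the package treats them as configuration (a `[aggregation]`
TOML section; `"inf"` is the sentinel for ∞) and does not refit them.
x is computed with μ_D for the dominant matrix and recomputed with μ_R
for the recessive matrix; y always uses μ_R.

### Association testing

Continuous phenotypes: ordinary least squares of y on
[covariates | score column(s)], Wald t-test for the 1-df dominant and
recessive models, F-test on the two score coefficients for the
generalized model.  Binary phenotypes: logistic regression, Wald z /
likelihood-ratio χ²(2).  Categorical phenotypes are split one-vs-rest
into binary phenotypes first.  Benjamini–Hochberg q-values are computed
separately within each model column.  Effect sizes: Cohen's *d* of the
score column between cases and controls (binary), or the Pearson
correlation between the covariate-residualized score and phenotype
(continuous); the score column used is the one of the single-inheritance
model with the smaller p-value, so the reported effect size matches the
better-supported inheritance pattern.

## Numerical choices

* **Norms.** p-norms are computed after factoring out the row maximum,
  so p as large as 10⁶ neither under- nor overflows; x = 0 is
  short-circuited before any log (no IEEE infinities enter the norms),
  and p = ∞ / q = ∞ dispatch to explicit max/min branches.
* **Clipping.** With finite q the product form (1 + ζ_q)·D_p can exceed
  1 in some parameter corners; since downstream code treats scores as
  probabilities, R is clipped to [0, 1] and clipping is logged.
  Perturbed variant scores are likewise clipped to [0, 1].
* **Genotype hygiene.** Probability triplets are renormalized on ingest
  when their sum deviates from 1 by ≤ 10⁻⁶ and rejected beyond
  [0.99, 1.01]; missing calls become (1, 0, 0) — an ungenotyped variant
  is treated as absent, which can hide damage but never invent it.
* **Degenerate and unstable fits.** A score column with zero variance,
  perfect separation, or a non-converged logistic fit (IRLS capped at
  100 iterations) is flagged and reported with p = 1.  This sacrifices
  power, never type-I validity.  Covariate matrices are reduced to full
  column rank (with a warning) before fitting; if D and R are collinear
  in the generalized model the test degrades to 1 df and then equals the
  corresponding single-score test.

## Design choices that were genuinely open

* **FDR procedure.** "FDR control" is implemented as
  Benjamini–Hochberg, applied per model column, since each inheritance
  model yields its own p-value family.
* **Generalized test statistic.** The joint null β_D = β_R = 0 is
  tested by the nested-model F-test (linear) and likelihood-ratio
  χ²(2) (logistic) — the standard choices for joint nulls in these
  families.
* **Additive inheritance.** Composed as the standardized sum of the
  standardized dominant and recessive columns — the simplest symmetric
  composition; tested with the generalized (2-df) model.
* **Binary phenotype simulation.** Liability thresholding of
  y = βx + N(0, 1) at the theoretical 1−prevalence quantile of
  N(0, 1+β²); default prevalence 0.1.
* **Shuffle granularity.** The score-shuffle control permutes scores
  globally across all variants, not within genes: the point of the
  control is to destroy the score–variant correspondence before
  aggregation while preserving the score distribution and the
  variant–gene map.

## Synthetic cohorts

The fixtures module emulates exome-like cohorts: per-gene variant
counts log-normal with mean ≈ 36 (σ = 0.75 on the log scale, floor 1),
mirroring the typical number of non-synonymous variants per
protein-coding gene in a large imputed cohort; consequence mix
dominated by missense (85%) with small loss-of-function and in-frame
indel minorities; missense scores Beta(2, 2) (symmetric spread over
[0, 1]); alternate-allele frequencies log-uniform on [0.001, 0.05]
(rare to low-frequency coding variation); genotypes in Hardy–Weinberg
proportions, independent across variants; covariates standard normal
plus an intercept.

What this does **not** emulate: linkage disequilibrium, population
structure and relatedness, imputation uncertainty correlated with
frequency, covariates correlated with genotype (confounding), and
realistic phenotype architectures with many small-effect genes.
Passing tests on these cohorts therefore validate the aggregation
mathematics, the statistical calibration of the tests under exchangeable
nulls, and the power machinery — not robustness to confounding or LD.

## Validation problem sizes

The validation suite uses scaled-down cohorts chosen to make the Monte
Carlo assertions sharp while keeping the whole suite fast: exact
enumeration checks over all genes with ≤ 3 variants on a 5-point score
grid; null calibration on 500 testable genes at n = 2000 with 5
covariates; planted-signal recovery on n = 5000, 200 genes, recessive
β = 0.5 over 20 replicates; power tables over n ∈ {500, 2000, 8000},
β ∈ {0.1, 0.3}, ε ∈ {0, 0.25}, 50 replicates per cell.  For the null
calibration, genes whose dominant or recessive column is constant in
the cohort are excluded: such genes are untestable by construction
(they are flagged and reported with p = 1), so including them would
distort the uniformity diagnostic without saying anything about
calibration.

A note on the shuffle control: shuffling effect scores cannot erase a
sample's carrier burden (who carries how many variants is
score-independent), so a causal gene's shuffled score column retains a
weak real correlation with a phenotype generated from its true scores.
At a planted β = 0.5 and n = 5000 that residue is occasionally
detectable.  The control therefore asserts what shuffling actually
guarantees: genes other than the causal one stay at the null
false-discovery expectation, and recovery of the causal gene collapses
(a binomial test against the unshuffled recovery rate).

## Known limitations

* Autosomal inheritance only: no sex-chromosome or mitochondrial
  recessive logic, no structural/copy-number variants, no non-canonical
  splice effects.
* Phased genotypes are not exploited; the different-copies assumption
  overestimates compound heterozygosity when variants are in cis.
* No mixed-model or relatedness correction — cohorts are assumed
  unrelated.
* The in-frame indel rule is a configurable placeholder, not a fitted
  model.
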