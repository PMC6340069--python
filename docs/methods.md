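# Methods

`gxescore` implements a candidate-gene gene–environment (G×E) interaction
analysis for hospital-based case-control studies of non-Hodgkin lymphoma
(NHL): data quality control, additive-model association, construction of an
environmental risk score (ERS) by semi-supervised binary co-clustering and
of genetic risk scores (GRS) from allele dosages, and multiplicative-scale
interaction models. The motivating Shanghai study (169 NHL cases, 421
hospital controls, 29 candidate SNPs in immune-regulatory and
xenobiotic-metabolism genes, 21 questionnaire variables) published only
group-level tables; the package therefore pairs the analysis code with a
synthetic cohort generator calibrated to those tables, and validates against
the published counts wherever they determine a quantity exactly.

## Models and procedures

### Logistic regression kernel

All association and interaction models are binary logistic regressions,
`logit P(case) = Xβ`, fitted by iteratively reweighted least squares with
step-halving (the per-iteration log-likelihood trace is kept and is
non-decreasing). Standard errors come from the inverse observed information;
confidence intervals are Wald intervals on the log-odds scale. Convergence:
relative log-likelihood change below 1e-10, at most 100 iterations.
Complete-case handling per model: rows with a missing value in any used
column are dropped, mirroring a study that reports per-variable missing
counts and no imputation procedure.

Quasi-complete separation — e.g. an exposure with zero exposed controls —
is detected when a coefficient magnitude exceeds 15 on the log-odds scale or
the information matrix is numerically singular. Separated terms report a
missing odds ratio with a (0, ∞) interval rather than a large finite
number; no penalized (Firth-type) fallback is attempted, because the target
output format prints `NA` for such rows. The threshold 15 corresponds to an
odds ratio above 3×10⁶, far outside anything estimable at n = 590.

### Quality control

* Hardy–Weinberg equilibrium: exact conditional test (enumeration of all
  heterozygote counts compatible with the observed allele totals, summing
  probabilities not exceeding the observed table's; no mid-p correction),
  computed on controls only. SNPs with p < 1e-4 are dropped.
* SNP missing rate: missing calls divided by all study samples; drop when
  strictly above 0.1. HWE is applied first, so a SNP failing both filters is
  reported with reason `hwe`; the kept set does not depend on the order.
* Variables: drop when missing rate strictly exceeds 0.05. The five
  covariates (age, gender, education, family history of cancer, BMI) are
  exempt — they are adjusters, retained by design — but their missing
  rates are reported.

### Association

Genotypes are coded additively as counts of the control-group minor allele
(ties at frequency 0.5 broken alphabetically; a SNP monomorphic in controls
is oriented by the pooled frequency with a warning). Exposures get one
univariate and one covariate-adjusted logistic model each; SNPs get the
Cochran–Armitage trend test (additive scores 0/1/2, hypergeometric variance,
chi-squared(1) reference) plus crude and adjusted additive logistic models.
Benjamini–Hochberg adjustment is applied within one result table's family
of tests, separately per p-value column.

### Environmental risk score (semi-supervised co-clustering)

The sample × exposure binary matrix is modelled as a Bernoulli latent block
model with two row clusters and two column groups. The column groups are
supervised: an exposure is labelled 1 (risk direction) when its univariate
odds ratio strictly exceeds 1 — equivalently, its log-odds coefficient is
positive, which extends the rule naturally to separated exposures with a
positively diverging coefficient — and 0 otherwise. These labels stay fixed;
only the row partition is estimated, by classification EM: hard row
assignments maximizing each row's classification log-likelihood alternate
with block-parameter updates. Block Bernoulli parameters use add-one
(Beta(2,2) MAP) smoothing and row proportions a Dirichlet(2) MAP, so the
traced objective — the smoothed complete-data log-likelihood — is exactly
coordinate-ascended; monotonicity is asserted on every run. Twenty
stratified-random restarts are fitted from a single seed; the best final
objective wins, ties to the lowest restart index. A restart that empties a
row cluster is re-seeded (counted and logged); if all restarts degenerate
(e.g. a constant matrix) the fit raises.

Missing exposure cells are imputed with the column mode before clustering
(rates in the motivating data are at most 4/590 per variable, so the choice
is immaterial there).

The per-sample ERS is this package's explicit convention (the published
text does not state one): the row cluster with the higher smoothed exposure
prevalence on the risk-labelled columns maps to ERS = 1; an exact tie sends
the smaller cluster to 1 (logged). Two row clusters and two column groups
are used because the ERS and the variable labels are binary; no model
selection over cluster counts is attempted.

### Genetic risk scores

Per QC-passed SNP, a univariate additive logistic model determines the risk
allele (minor if its log-OR is positive, otherwise major, flipping the dose
to 2−dose) and the weight |log-OR|. U_GRS sums risk-allele doses; W_GRS
sums weight × dose, so contributions are non-negative after orientation.
A SNP whose univariate fit separates is excluded from both scores with a
warning. Missing doses are imputed with the per-SNP mean risk-allele dose.
Both scores are dichotomized at the pooled cohort median with a strict
greater-than rule (even-length medians are the midpoint of the central
order statistics; ties at the median go to 0, so at most half the cohort is
assigned 1). Whether the weighted score is additionally divided by the sum
of weights is immaterial downstream: dichotomization at the median is
invariant to positive rescaling.

### Interaction models

Three families share one engine, `logit P(case) = β₀ + β_a·a + β_b·b +
β_int·a·b (+ covariates)`: ERS × SNP dose (one model per SNP), dichotomized
GRS × exposure (one per exposure; both weighted and unweighted variants are
emitted), and GRS × ERS (a family of one). The reported effect is the ratio
of odds ratios ROR = exp(β_int) with a Wald interval; for binary factors the
unadjusted ROR equals the ratio of stratum-specific cross-product ratios (a
saturated-model identity the tests exercise). Unadjusted and
covariate-adjusted variants are always both reported. SNP interactions use
the additive dose, consistent with the single-coefficient SNP term in the
association models. A degenerate cross-tabulation (no exposed samples in
one score stratum, making the product column collinear) is reported as a
flagged row with missing ROR and (0, ∞) interval, like separation.

## Synthetic cohort generator

The generator emulates the design of the motivating study so every stage is
testable without the non-public individual-level data. Genotypes are drawn
per SNP from (q²+Fpq, 2pq(1−F), p²+Fpq) — the inbreeding coefficient F
produces controlled Hardy–Weinberg violations for the QC tests — with the
22 retained markers at their published control minor-allele frequencies.
Exposures are Bernoulli at published control prevalences; covariates follow
the published control distributions (age ~ N(57.9, 13.7²), BMI ~ N(24.3,
6.8²), binary covariates at their control rates). Outcome status comes from
a population logistic model with configurable main-effect and product-term
coefficients; case-control sampling is emulated by rejection (draw, keep
until 169 cases and 421 controls accrue), so the intercept is a
baseline-risk calibration knob and all non-intercept log-odds ratios remain
consistently estimable. Missingness is injected completely at random after
status assignment. All randomness flows from a single seed; identical seed
and configuration reproduce the cohort byte for byte.

Default effect sizes in the paperlike configuration are the logs of the
published odds ratios (crude for exposures, reported for SNPs), with
planted QC failures: three markers at F = 0.6, four at 20% missingness,
five questionnaire variables at 12% missingness. Retained-marker missing
rates follow the published genotype-count totals but are capped at 0.06 so
the QC bookkeeping (29 → 22 markers, 16 retained variables) is stable
across seeds: the planted failure rates sit more than five binomial
standard deviations above their thresholds and the retained rates more than
three below.

What the generator does **not** emulate: linkage disequilibrium between
markers (genotypes are independent), exposure–genotype or
exposure–exposure correlation beyond what the outcome induces, the
frequency-matched recruitment of the original controls, and — importantly —
marginal effect sizes. Planted coefficients are conditional log-odds
ratios; because the logistic model is non-collapsible, the crude
(marginal) odds ratios observed in a simulated cohort are attenuated
relative to the planted values when many other effects are present.
Passing tests on this cohort therefore demonstrate pipeline correctness
and bookkeeping, not a reproduction of the study's marginal effect-size
landscape.

## Validation experiments and problem sizes

* Printed-count reproduction: the published per-variable 2×2 exposure
  counts determine every crude OR exactly; the package rebuilds a cohort
  with those margins and reproduces all ten finite ORs to two decimals,
  plus the benzene separation row. The published SNP ORs are presumed
  covariate-adjusted (the crude cross-product of the printed counts does
  not reproduce them), so they are treated as generative inputs, never as
  oracles.
* Interaction recovery: 500 replicates at the study size (169/421) with a
  planted score × exposure interaction of log(0.23) — the magnitude of the
  study's headline smoking × weighted-GRS finding — recover the mean
  coefficient within 3 Monte-Carlo standard errors (unadjusted variant,
  which is the one behind the published headline; residual deviation is the
  well-known small-sample magnitude inflation of the logistic MLE, about
  2% here).
* Test size: the empirical type-I error of the nominal-0.05 interaction
  test, 5000 null replicates at the study size (Monte-Carlo SE ≈ 0.003),
  lands near 0.05 (measured ≈ 0.048–0.051 across seeds).
* Co-clustering: the smoothed objective is monotone on every run; a
  noise-free planted 2×2 block matrix (200 × 10) is recovered exactly; at
  flip-noise 0.2 the benchmark uses a 200 × 20 block-diagonal planted
  matrix, where the adjusted Rand index is ≥ 0.9 in ≥ 95% of 100
  replicates. At 200 × 10 and noise 0.2 the Bayes-optimal row classifier
  already misassigns about 2% of rows, so the ARI distribution straddles
  0.9 for any algorithm; the wider matrix makes the partition genuinely
  recoverable and the benchmark informative about the implementation.
* Oracle equivalences: 2×2 logistic OR ≡ ad/bc on 1000 random tables; the
  exact HWE test matches a rational-arithmetic enumeration oracle for every
  genotype table with n ≤ 50; BH matches the reference step-up
  implementation; the trend statistic equals (N−1)·corr² in closed form and
  its chi-squared p lies inside the discrete permutation null's
  [P(T>t), P(T≥t)] bracket at 10⁵ permutations.

## Known limitations

* Wald intervals only; the published intervals are slightly asymmetric
  relative to the Wald closed form (their method is unstated), so interval
  endpoints are checked to a tolerance band while point estimates are exact.
* The ERS construction fixes the column labels; if the original analysis
  merely initialized them, row partitions could differ. The per-sample ERS
  rule is a convention of this package.
* No sample-level QC, relatedness checks, dominant/recessive codings,
  haplotype or NHL-subtype analyses.
* The reconstructed printed-count cohort reproduces per-variable margins
  only; joint distributions (and hence multivariable estimates on it) are
  not those of the real data.
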