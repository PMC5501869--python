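# Methods

## Model

`rvbayes` tests, per locus, whether rare variants are associated with a
binary phenotype in a case/control cohort of N unrelated individuals, and
if so which variants are responsible and under which mode of inheritance.

Let `G` be the N×k matrix of rare-variant allele counts (0/1/2), `s_i` the
ploidy of individual `i` at the locus (2, or 1 for males at X-linked loci
outside the pseudoautosomal regions), and `y` the binary phenotype.

* **Baseline model (γ = 0).** Every individual is a case with probability
  τ₀ ~ Beta(α₀, β₀). The marginal likelihood is available in closed form.
* **Association model (γ = 1).** A latent binary vector `z` flags which of
  the k variants are pathogenic. Individual `i` has a *pathogenic
  configuration* when `f(G_i, z, s_i, m) = 1`, where under the dominant
  mode `f = 1` iff `Σ_j G_ij z_j ≥ 1` and under the recessive mode iff
  `Σ_j G_ij z_j ≥ s_i`. The recessive rule with `s_i = 2` covers both
  homozygous and compound-heterozygous genotypes, and with `s_i = 1`
  X-linked hemizygotes. When phased haplotypes are supplied, the recessive
  rule can additionally require the pathogenic alleles to lie on distinct
  haplotypes (closed-form layer only; the sampler uses the unphased rule).
  Cases arise with probability π ~ Beta(απ, βπ) among configured
  individuals and τ ~ Beta(ατ, βτ) otherwise, so the likelihood given
  `z` is a product of two beta-binomial factors.

The pathogenicity indicators have a logistic prior
`z_j ~ Bernoulli(p_j)`, `logit p_j = ω + φ c_j`, where `c` carries
per-variant prior information ("co-data": consequence class, conservation,
…). ω has a logit-beta prior (expit(ω) ~ Beta(αω, βω)) and φ a log-normal
prior constrained positive so that co-data can only act in the direction of
its sign. User-supplied raw weights are centered to sum to zero — making ω
interpretable as the mean log-odds of pathogenicity — and then scaled to
unit variance before entering the regression. Standardization keeps φ
comparable across weighting schemes and is required to reproduce the
co-data simulation results; constant weights standardize to zero and are
inert. The log-normal is parameterized by the prior mean and variance of φ
itself: σ² = log(1 + Var/Mean²), μ = log(Mean) − σ²/2.

### Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| (α₀, β₀), (ατ, βτ) | (1, 1) | uniform priors on baseline/non-carrier risk |
| (απ, βπ) | (6, 1) | carrier risk concentrated near 6/7 (high penetrance) |
| (αω, βω) | (2, 8) | ~20% of variants pathogenic a priori; P(>0.54) ≈ 0.01 |
| E[φ], Var[φ] | 1, 0.35 | co-data shifts taken at face value, effect size flexible |
| P(m = dom &#124; γ=1) | 0.5 | equal prior odds on the two modes |
| P(γ = 1) | 0.01 | 1% prior probability of association |

For a high-impact variant class, (αω, βω) = (2, 1) is used instead, since
most such variants are expected pathogenic if the class is causal.

## Evidence estimation

The evidence under γ = 1 sums over all 2^k values of `z` and integrates
over (ω, φ); it is intractable beyond k ≈ 20. Two routes are implemented:

* **Exact (k ≤ 20).** Full enumeration of `z` with Gaussian quadrature
  over ω (Gauss–Legendre on the Beta scale) and φ (Gauss–Hermite on the
  log scale). Stable to ≤1e-6 under refinement at the default orders
  (48 × 24). This is the independent oracle for the sampler.
* **Power posteriors (any k).** A ladder of tempered distributions
  ∝ p(y|z,m)^t · prior, for temperatures 0 = t₁ < … < t_R = 1. Per rung,
  `z` is updated by component-wise Gibbs in random sweep order — a flip of
  `z_j` only touches the carriers of variant `j`, so sweep cost scales
  with the number of non-zero genotypes, not with N — while ω and log φ
  move by random-walk Metropolis with proposal scales tuned to 20–40%
  acceptance during burn-in. Rungs run sequentially, warm-started, in one
  seeded PRNG stream (runs are bit-reproducible). The log evidence is the
  thermodynamic integral of the per-rung posterior mean log-likelihood,
  evaluated by the trapezoidal rule; its Monte-Carlo standard error uses
  batch means (20 batches) to absorb autocorrelation.

**Ladder.** Default 11 rungs at t = (l/10)². We measured the trapezoidal
discretization bias against the exact oracle: quartic spacing leaves the
top of the ladder too sparse (bias ≈ −0.05 log units at 11 rungs), while
quadratic spacing brings it below the Monte-Carlo error (≲0.005), and also
tracks a 41-rung reference at k = 200. Default 1,000 retained sweeps per
rung after 200 burn-in; evidence SE is then ~0.03–0.2 log units depending
on k. `lgamma` values are precomputed in lookup tables over the integer
counts, which makes a default run on N = 1000, k = 25 take ~0.15 s.

Everything downstream is closed-form log-space arithmetic: evidence is
estimated conditionally on each mode and combined by log-sum-exp with the
mode prior; competing variant-class models (with their own variant
subsets, co-data and priors) are combined through
P(γ=u | y) ∝ P(y | γ=u) P(γ=u), and per-variant pathogenicity marginals,
expected explained cases and expected pathogenic-variant counts are
averaged over models with posterior-probability weights. The expected
pathogenic count is restricted to variants actually carried by someone:
uncarried variants can have z_j = 1 under the prior without any
observable consequence, and counting them would report prior noise.

## Synthetic cohorts

The generator emulates the cohort design used for evaluation: allele
counts i.i.d. Binomial(2, AF) with AF = 0.0017 (dominant scenarios) or
0.03 (recessive), k = 25 variants of which the first 5 are truly
pathogenic, N = 1000, and labels drawn with probability π for configured
individuals and τ otherwise. Null datasets are label permutations of
independently generated associated datasets. What this does *not* emulate:
linkage disequilibrium between variants, relatedness, population
stratification, variable allele frequencies within a locus, genotyping
error, or X-linked loci (ploidy is 2 throughout). Passing simulation tests
therefore demonstrates correctness of the inference machinery under the
model's own sampling assumptions, not robustness to those real-data
complications.

**Ranking experiments.** Performance is summarized as the mean positive
predictive value (PPV) at 80% power over mixtures of 10 associated and 990
permuted datasets ranked by posterior probability of association. The
simulation scorer conditions on the panel's inheritance mode (dominant and
recessive scenarios are evaluated as separate panels); integrating over
modes instead would let chance *recessive* configurations — at k = 200 and
AF 0.0017 about 15% of individuals carry two or more rare alleles — inflate
the null score tail and is not what a per-mode evaluation measures.
Real-data locus runs keep the default prior integration over modes. PPV at
80% power is: the PPV
at the smallest rank cutoff recovering ⌈0.8·10⌉ = 8 true datasets, i.e.
1 − FDR there. Scored datasets are pooled once and mixtures resampled from
the pools (drawing with replacement only when a pool is smaller than the
draw); ties are broken by a seeded random mixture order, so results are
reproducible. The comparator is CAST: a two-sided Fisher's exact test on
collapsed carrier status (≥1 rare allele under dominance, ≥ploidy under
recessiveness), ranked by negative log p.

Variant-level accuracy is summarized by a ROC over posterior pathogenicity
marginals pooled across replicate datasets (pooling, rather than averaging
per-replicate curves, weights every variant equally and is the variant
ranking a screening analyst actually faces). The co-data experiment varies
how many truly pathogenic (0–5) and truly non-pathogenic (0–20, step 4)
variants receive raw weight 1, and reports per cell the mixture PPV and
the mean posterior E[φ] over associated datasets.

## Problem sizes

The default experiment sizes in the acceptance script and test suite are
scaled-down versions of the full 10,000-repetition grids: score pools of
tens of associated and hundreds-to-thousands of permuted datasets, and a
few hundred mixture repetitions. These sizes were chosen so each headline
quantity is estimated with Monte-Carlo uncertainty small relative to the
effect being demonstrated; the full-scale grids are available by raising
the pool and repetition arguments (`n_assoc`, `n_null`, `n_repetitions`).

## Numerical and degenerate-input choices

* All likelihoods in log space via log-gamma; no factorials.
* Association fitting requires ≥1 case and ≥1 control; all-case or
  all-control phenotypes are rejected.
* Loci where nobody carries any variant yield Bayes factor 1 exactly
  (posterior = prior), by construction of the beta-binomial factors.
* Missing genotypes are imputed to homozygous reference with a warning
  (the model has no missingness mechanism); allele counts exceeding ploidy
  are rejected at construction.
* Degenerate CAST tables (no carriers, no non-carriers, or one-class
  phenotype) return p = 1.
* Fisher–Yates shuffling and all proposals run inside one seeded kernel
  stream; two runs with the same seed are bit-identical.
* Gibbs probabilities are clamped at |logit| > 35 to avoid overflow.

## Known limitations

* The sampler ignores phase; compound-heterozygous calls in cis are
  counted as configured under the recessive rule unless the closed-form
  layer with phase is used.
* No covariate adjustment beyond the variant-level co-data; confounding by
  ancestry or relatedness must be handled upstream (unrelated individuals
  are a documented precondition).
* Evidence SEs assume approximately stationary chains per rung; very short
  runs (<~100 sweeps) can understate the error.
* Multiallelic VCF records must be split upstream; large deletions are
  accepted only as pre-coded 0/1/2 columns.
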