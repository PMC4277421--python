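# Methods

`famada` implements a family-based region association test for sequence
data: per-site score tests that respect pedigree relatedness, an adaptive
truncated combination of the per-site P-values, and a permutation null that
randomises allelic transmission conditional on founder genotypes.  This
note records the model, the numerical choices, and what the built-in
simulator does and does not emulate.

## The per-site statistic

For `n` individuals across `N` independent families, let `Y` be the trait
(0/1 or continuous), `X` the covariates (with intercept), and
`r = Y − X(XᵀX)⁻¹XᵀY` the ordinary-least-squares residuals.  At site `l`
with genotype-score vector `g_l` (minor-allele counts 0/1/2 under an
additive coding) and founder minor-allele frequency `p̂_l`, the statistic is

    T_l = (rᵀ g_l)² / ( 2 p̂_l (1 − p̂_l) · rᵀ Φ r ),

where `Φ` is the genetic-correlation matrix with entries `2 φ_ij` (twice
the kinship coefficient), block-diagonal over families.  Phenotypes are
treated as fixed and genotypes as random — the retrospective view of the
Thornton–McPeek family of quasi-likelihood score tests — which makes the
test robust to ascertainment of pedigrees through affected members.  Under
the null, `T_l` is approximately χ² with 1 degree of freedom; the variance
term `2p(1−p)·rᵀΦr` is the null variance of `rᵀg_l` when founder alleles
are Hardy–Weinberg draws at frequency `p` and descend through the pedigree.

Choices worth stating:

* **Minor allele from founders only.**  Non-founder genotypes are
  deterministic functions of founder haplotypes plus meiosis noise, so
  founder counting gives the unconfounded frequency.  Ties at exactly 0.5
  keep the input's alt allele.
* **No genotype centring.**  Centring `g_l` by `2p̂_l` is a no-op because
  residuals from an intercept model sum to zero (asserted by test).
* **Linear residuals for both trait types.**  Dichotomous traits use the
  same OLS adjustment as continuous ones; the statistic needs only a
  residual vector, not a likelihood.
* **Monomorphic-in-founders sites** have a vanishing denominator; they are
  flagged invalid, assigned P = 1, and excluded from score combination.
* `rᵀΦr` is genotype-independent; it is computed once per analysis and
  reused across sites and permutation replicates.

## Kinship

Kinship coefficients are computed by the classical founders-first
recursion: `φ(i,i) = (1 + φ(f_i, m_i))/2` and
`φ(i,j) = (φ(f_i, j) + φ(m_i, j))/2` for any `j` processed before `i`.
Founders are assumed non-inbred and mutually unrelated, so `Φ` is exactly
block-diagonal across families; the implementation exploits that in the
quadratic form.  The recursion is validated against a Monte-Carlo
identity-by-descent gene-dropping oracle (10⁶ drops) and a
positive-semi-definiteness check (smallest eigenvalue ≥ −10⁻⁸ relative to
the largest).

## Adaptive combination of P-values

Given per-site P-values `P_1 … P_L` and a threshold grid
`θ_1 < … < θ_J` (default 0.05, 0.10, …, 0.50), the significance score at
threshold `j` is

    S_j = Σ_l (−ln P_l) · 1[P_l < θ_j],    valid sites only,

so sites with large P-values — the likely-neutral ones — are excluded, and
the effective threshold is chosen by the data.  The `−ln` transform is
configurable (`−log₁₀` available); the indicator uses strict inequality.

### Permutation null and the min-P adjustment

Because `J` thresholds are searched, significance comes from `B`
gene-dropping permutations (default 1000): haplotype transmission is
re-randomised conditional on founder genotypes, traits stay fixed, and
residuals, `rᵀΦr` and founder MAFs are reused unchanged (founder
invariance makes recomputation a no-op, asserted by test).

Every unit — the observed data and each replicate — receives per-threshold
P-values on one common scale: `p_x,j = #{y ≠ x : S_y,j ≥ S_x,j} / B`,
each unit compared against the other `B` units.  `MinP_x = min_j p_x,j`,
and the reported adjusted P-value is

    (1 + #{b : MinP_b ≤ MinP_observed}) / (B + 1).

Under the null the `B + 1` rank vectors are exchangeable, so this is a
valid (slightly conservative under ties) permutation test; the smoothed
`(1 + count)/(B + 1)` estimator keeps the P-value off zero.  A
scale-asymmetric variant (replicates self-included, observed not) was
rejected during development because putting the observed and replicate
scores on different denominators makes the min-over-thresholds step
anti-conservative at small levels, whereas the exchangeable construction
is provably valid.  The remaining discreteness of order `1/B` at B = 200
motivates the default B = 1000 for calibrated small-α inference.

Ties are broken exactly by the ≥ / ≤ comparisons written above — no
jitter, so results are bit-reproducible from the seed.

### Exhaustive mode and sequential stopping

For pedigrees with at most 12 non-founders the Monte-Carlo loop can be
replaced by exact enumeration of all `4^m` equally likely meiosis patterns
(`exhaustive=True`); the adjusted P-value is then the exact probability
`P(MinP_pattern ≤ MinP_observed)` with no smoothing.  An optional
sequential Monte-Carlo mode stops permuting once the exceedance count for
the observed MinP reaches a user cap — useful when screening many regions,
off by default because the stopped estimate is coarser.

## Gene-dropping engine

Haplotypes transmit as units (no within-region recombination), matching
the single-gene/short-window use case.  Because of that, a permutation
replicate is fully described by *descent indices*: for every individual,
two pointers into the founder-haplotype pool.  The engine therefore drops
indices rather than sequences and recovers per-replicate numerators
`rᵀg_l` with one scatter-add and a `(B × 2F)(2F × L)` matrix product,
which is what makes 10³-replicate permutation tests cheap.

Randomness comes from a counter-based Philox generator consumed in a fixed
deterministic order (replicate-major, individuals in topological order).
Per-(family, individual) key derivation was considered and dropped: it
only matters for out-of-order parallel execution, which the engine does
not do; the seed→result contract is tested instead.

Phased input is required.  Real-data pipelines that phase with external
tools (e.g. Beagle) can feed their most-likely haplotype pairs in; the
phase uncertainty this ignores is not propagated.

## The simulator

The simulator reproduces the study conditions the test was evaluated
under; it is first-class, tested code.

* **Haplotype pool.**  A single random coalescent genealogy (successive
  pairwise coalescences, exponential waiting times with rate `k(k−1)/2`)
  with a fixed number `L` of infinite-sites mutations placed on branches
  proportionally to length, root branch excluded — so every site
  segregates.  Default pool size 1000 haplotypes: large enough that 400
  founder haplotypes per 50-family study draw with little resampling, small
  enough to regenerate per replicate.  The site-frequency spectrum follows
  the neutral `1/i` expectation and is cross-checked against msprime in the
  test suite.  No recombination or mutation-rate realism is attempted; an
  external haplotype matrix can be substituted for the pool.
* **Families.**  Three-generation 12-member families: founders at template
  positions 1, 2, 5, 6 draw two pool haplotypes each; the couple (1, 2)
  has children 3 and 4, who marry founders 6 and 5; children 7–9 descend
  from (3, 6) and 10–12 from (4, 5).  Non-founders receive one full-length
  haplotype from each parent.
* **Dichotomous traits.**  Five causal sites (Nos. 10, 20, 30, 40, 50,
  1-based) by default, not restricted to be rare.  Each causal site gets a
  genotype relative risk from its population attributable risk and pool
  MAF, `GRR = PAR/(MAF(1−PAR)) + 1`, so rarer causal variants carry larger
  effects.  Penetrance is multiplicative per minor allele on the baseline
  `f₀ = 0.05`, clamped at 1; affection is Bernoulli(penetrance) for
  founders and offspring alike.  No ascertainment on affection status by
  default (an optional rejection-sampling hook exists for exploration).
* **Continuous traits.**  `Y = μ + Σ_l G_il + ε`, genotypic values with
  means `+a_l, 0, −a_l` for 2, 1, 0 minor alleles, `ε ~ N(0, σ²_e)`,
  defaults `μ = σ²_e = 100` (non-critical — effects are calibrated to the
  per-QTL variance fraction `h²_l`, default grid 0.001–0.006).  Under
  Hardy–Weinberg founder frequencies the additive variance at a locus is
  `2p(1−p)a²`, giving `a_l` in closed form.  The within-genotype spread of
  the genotypic value defaults to 0 and is configurable; the `h²`
  calibration accounts for whatever value is set.

What the simulator does *not* emulate — and hence what passing tests do
not certify about real data: linkage-disequilibrium structure beyond a
single genealogy, recombination, genotyping error, phase error, missing
data, population stratification among founders, and ascertained sampling.

## Experiment sizes and runtime choices

The packaged experiments size themselves for a single CPU:

* Null calibration: 50 families × 100 sites, dichotomous, B = 1000,
  1000 replicates in the test suite and 3000 in the acceptance script
  (binomial SE ≈ 0.004 at the 0.05 level, ≈ 0.002 at 0.01).
* Power trends: 500 replicates per effect point at B = 200, which
  resolves the monotone trend over total PAR {0.05, 0.15, 0.30} and total
  variance explained {0.005, 0.015, 0.03}.
* χ²₁ calibration: 2000 independent replicates, one randomly chosen valid
  site each (independence makes the Kolmogorov–Smirnov test clean); the
  continuous-trait null is used because a continuous trait gives the
  statistic a continuous distribution, so the KS check probes the χ²
  approximation itself rather than the discreteness of Bernoulli residuals
  at low-MAF sites.

## Degenerate inputs and edge cases

Constant traits, traits fully absorbed by covariates, rank-deficient
covariate matrices, all-monomorphic regions, unphased or multi-allelic
VCF records, missing members, and missing trait values all raise typed
errors; Mendelian inconsistencies in real input warn but do not fail (the
simulator cannot produce them).  Permutation requires `B ≥ 100`; the
enumeration guard caps exhaustive mode at 24 meioses.

## Known limitations

* Dichotomous traits use linear-model residuals; no logistic or mixed-model
  adjustment.
* Unrelated singleton controls contribute nothing to the permutation null
  (their genotypes never change), so the method is intended for full
  pedigrees with founder genotypes available.
* Analytic P-values do not exist for the adaptive statistic; runtime is
  dominated by `B` and the replicate count.
* Autosomal analysis only; multi-allelic sites and dosages unsupported.
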