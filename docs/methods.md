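# Methods

## Model and hypotheses

Independent random vectors X_ik = (X_i1k, …, X_idk)ᵀ, i = 1…a groups,
k = 1…n_i subjects, with marginal distributions
F_ij(x) = ½[F⁺_ij(x) + F⁻_ij(x)] — the *normalized* distribution function
(average of the right- and left-continuous versions), which handles ties and
therefore continuous, discrete and ordinal outcomes uniformly. Missingness
indicators λ_ijk ∈ {0, 1} mark observed measurements; the theory assumes the
missingness is completely at random and that every cell keeps enough observed
subjects (λ_ij·/n converging to positive constants). Null hypotheses are
CF = 0 for a contrast matrix C; only the row space of C matters, so the
package always reduces C to the projection T = Cᵀ(CCᵀ)⁺C internally and
normalizes the built-in group contrast to P_a ⊗ J_d/d (same row space as the
conventional P_a ⊗ 1_d1_dᵀ, better conditioned across d).

## Estimators

Mid-ranks over all N observed values are computed by sorting with
average-tie assignment (O(N log N)); the defining O(N²) counting-function
form, R_ijk = ½ + Σ c(X_ijk − X_lms), is retained in the test suite as an
independent oracle and the two must agree exactly. The relative effect
estimator is p̂_ij = (1/λ_ij·)Σ_k λ_ijk(R_ijk − ½)/N, i.e. the average of
Ĥ(X_ijk) = (R_ijk − ½)/N over the cell's observed subjects; this resolves an
ambiguity in how the estimator is sometimes typeset — the alternative
reading R_ijk/N − ½ would violate p̂ ∈ (0, 1) and the identity
Σ_ij (λ_ij·/N) p̂_ij = ½, both of which the test suite asserts.

The covariance estimator is V̂_n = ⊕_i (n/n_i)V̂_i with

    v̂_i(j,j)  = n_i Σ_k λ_ijk (R_ijk − R̄_ij·)² / [N² λ_ij·(λ_ij·−1)]
    v̂_i(j,j′) = n_i Σ_k λ_ijk λ_ij′k (R_ijk − R̄_ij·)(R_ij′k − R̄_ij′·)
                / [N² ((λ_ij·−1)(λ_ij′·−1) + Δ_i,jj′ − 1)]

where Δ_i,jj′ counts subjects observed at both times. The N² scale matches
Var(Ĥ) with Ĥ on the (R − ½)/N scale. Degenerate off-diagonal denominators
(possible only when Δ_i,jj′ ≤ 1 in tiny cells, and in sparse bootstrap
replicates) are zeroed with a logged warning rather than raised, so that
resampling never aborts mid-study; the diagonal requires λ_ij· ≥ 2, which is
validated before any test runs. Cells with λ_ij· ∈ {0, 1} cause a refusal
naming the cell. Subjects with no observation at all are kept (they
contribute nothing to any sum) with a warning.

## Test statistics and calibration

* **WTS** n(Cp̂)ᵀ[CV̂Cᵀ]⁺(Cp̂), asymptotically χ²_f, f = rank C. The
  pseudoinverse is spectral with a relative eigenvalue cutoff of 1e−10 ×
  the largest magnitude; Kronecker-contrast ranks are exact integers, so the
  cutoff can never truncate a genuine eigenvalue of a well-scaled V̂. The
  same tolerance computes rank C, keeping f consistent with the
  pseudoinverse.
* **ATS** np̂ᵀTp̂/tr(TV̂) with the Box-type f̂ = tr(TV̂)²/tr(TV̂TV̂) and
  reference F(f̂, ∞), evaluated as the law of χ²_{f̂}/f̂ with non-integer
  degrees of freedom (that is the definition of an F with infinite
  denominator df). Valid even when V is singular, but the approximation is
  not asymptotically exact.
* **MATS** n(Cp̂)ᵀ[CD̂Cᵀ]⁺(Cp̂), D̂ = diag V̂. Its limit is a χ²₁-mixture with
  unknown weights, so no asymptotic p-value is reported — deliberately; the
  bootstrap is the only calibration. It requires every cell variance
  v̂_i(j,j) > 0 and raises otherwise (e.g. an all-tied cell).

**Wild bootstrap.** Centered rank vectors Z_ik = R_ik − R̄_i· (missing
coordinates carried as 0 and multiplied by λ = 0 in every sum, so a
replicate never fills in a missing value) are multiplied by one weight per
*subject* — sharing the weight across time points is what reproduces the
within-subject covariance; per-coordinate weights would destroy it. Weight
laws: Rademacher (default and recommended — best type-I error control in
the underlying study), Mammen's golden-ratio two-point law, standard normal,
centered Poisson(1); all mean 0, variance 1. Each replicate recomputes
p̂*, V̂*, D̂* by the same formulas with R → Z* and cell means re-centered per
replicate, then the same statistic; the p-value uses ≥ and denominator B
(the printed six-step algorithm). A bootstrap replicate with tr(TV̂*) ≤ 0
gets T* = 0 and is counted — conservative, it can only raise the ATS
p-value; occurrences are tallied in the result object.

**Reproducibility.** A single root seed feeds a PCG64 generator that draws
the whole (B, n) weight matrix in one vectorized call; replicates are rows.
Within each group, weights are assigned to subjects in a canonical order
(lexicographic by observation mask, then rank vector), so the bootstrap
p-value is bit-identical under permutation of subject rows and under
strictly monotone transformation of the data. All B replicates for the
three statistics are evaluated in one batched numpy pass (batched eigh for
the pseudoinverses), which is what makes 10⁴ × 500 replicate evaluations
per scenario feasible on one core.

## Synthetic data

The generators emulate the small-sample conditions under which the tests
were validated:

* **Continuous**: Gaussian copula — multivariate normal with correlation
  matrix from one of the settings AR (0.6^|l−j|), CS (identity; the label
  follows the source study's nomenclature even though the matrix is exactly
  I), TP (Toeplitz d − |l−j|, divided by d since a copula consumes a
  correlation) — pushed through Φ and then the inverse CDF of the marginal
  (standard normal, standard Laplace, standard lognormal, χ²₁₅). Location
  alternatives add the shift μ₁ after the marginal transform (e.g.
  (0,0,ζ,ζ) or (0,0,0,ζ) on d = 4). Because the copula fixes the ranks
  given the seed, rank-based results are identical across marginals with
  the same seed — a property the tests assert.
* **Ordinal**: X = int(4(cZ + Y)/(c+1)) + 1 with Z uniform per subject and Y
  uniform per measurement; values in {1,2,3,4}, compound-symmetric
  dependence tuned by c (default c = 1, giving P(X=1) = 1/8 and positive
  within-subject correlation).
* **Missingness**: MCAR deletes coordinates i.i.d. with probability r.
  MAR1/MAR2 (defined for d ∈ {4, 8}) use determining/target coordinate
  pairs — (1,2),(3,4) for d = 4; (1,2),(1,3),(6,7),(6,8) for d = 8, leaving
  times 4 and 5 never missing — deleting the target with probability
  15%/30%/15% across the (−∞,−2σ̂), [−2σ̂,2σ̂], (2σ̂,∞) strata (MAR1) or
  10%/30% below/above the median (MAR2) of the determining coordinate.
  Masks leaving any cell with fewer than two observed subjects are redrawn
  wholesale (up to 1000 attempts, then an error that the design is too
  small for the rate); this conditions the simulated design on validity,
  which is what the estimators require. The redraw policy is this package's
  choice; the source study does not specify one.

What the generators do *not* emulate: informative (MNAR) dropout, serial
correlation beyond the three covariance settings, unequal covariances
across groups, or measurement-error structure. Passing tests therefore
demonstrate calibration under MCAR/MAR with exchangeable-ish dependence,
not robustness to non-ignorable missingness.

## Simulation studies and problem sizes

`run_type1_study` simulates nsim null datasets and reports, per method
(asymptotic WTS/ATS and bootstrapped WTS/ATS/MATS), the rejection fraction
× 100 with its binomial Monte Carlo SE; rejection is p ≤ α for the
asymptotic tests and bootstrap-p < α for the bootstrap tests (the two rules
cannot disagree at the grid values a B = 499 or 999 bootstrap can produce).
`run_power_study` sweeps a shift grid ζ·pattern. Per-dataset randomness is
spawned from a root SeedSequence, so studies are reproducible end to end.

The acceptance script uses nsim = 10 000 datasets per scenario with B = 499
bootstrap replicates — the replication count of the original study with a
reduced bootstrap size, whose effect on a rejection *rate* is only added
Monte Carlo noise, not bias. The in-suite calibration tests use nsim = 2000
(tolerance three binomial SEs ≈ ±1.5 percentage points around the published
cells) to keep the default test run short.

## Known limitations

* Hypotheses are about distribution functions, not the unweighted relative
  effects p*; the two coincide under the null tested here but target
  different alternatives.
* No confidence intervals for p̂ and no multiple-contrast (max-type) tests.
* The asymptotic MATS p-value is intentionally absent (see above).
* Factorial structures beyond one group factor × one time factor must be
  encoded by flattening indices or supplying a custom contrast matrix.
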