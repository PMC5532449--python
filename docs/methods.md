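# Methods

This note documents the models, algorithms, numerical choices and the
synthetic-data calibration behind `robustsem`, in the spirit of a software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and implied moments

The linear SEM is Y = ν + Λη + e, η = α + Bη + ξ, with (e, ξ) mean-zero,
uncorrelated, cov(ξ) = Ψ, cov(e) = Θ. With A = (I − B)⁻¹ the implied
moments are μ = ν + ΛAα and Σ = ΛAΨAᵀΛᵀ + Θ. `ModelSpec` stores a
free/fixed pattern per matrix; identification defaults to marker variables
(first loading per factor fixed at 1), with unit factor variances as the
alternative. Exogenous covariates, categorical indicators, multi-group
models and cross-parameter equality constraints are out of scope.

Free parameters are optimized on an unconstrained scale: log for free
variances (Θ and elementwise-Ψ diagonals), a Cholesky factor with log
diagonal for a fully free Ψ, identity for everything else. This keeps Σ
positive definite by construction for CFA-type models (Θ diagonal > 0,
Ψ = LLᵀ), at the cost of making true boundary solutions (Heywood cases)
appear as variances collapsing toward zero; a free variance below 1e-7 at
the solution is reported as nonconvergence, mirroring the common practice
of treating negative/zero residual variances as failed replications. The
public `ParameterSet` always holds natural-scale values.

## ML-Normal

The structured fit minimizes F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p +
(ȳ−μ)ᵀΣ⁻¹(ȳ−μ) with S the divisor-n sample covariance, by L-BFGS-B with
analytic gradients (chain rule through Λ, B, Ψ, Θ, ν, α and the
unconstrained transforms; verified against finite differences in the
tests). The likelihood-ratio statistic against the closed-form saturated
model is then exactly T = n·F̂, matching the convention of mainstream SEM
software. Moment input (mean, covariance, n) is accepted and gives
estimates identical to raw-data input; this is also how TSR's second stage
is realized. Convergence requires optimizer success (or an infinity-norm
gradient below 1e-4 after one restart from the pattern's start values)
plus an admissible solution (positive-definite Σ, Ψ and Θ eigenvalues
above −1e-8, no collapsed free variance). Standard errors, when requested,
come from the observed information on the unconstrained scale (central
finite differences of the analytic gradient), delta-method transformed to
the natural scale.

SRMR is the correlation-metric variant over the p(p+1)/2 unique covariance
residuals, diagonal included, covariance structure only. Software
implementations differ in whether the diagonal and mean residuals enter;
this variant is fixed, documented, and tested for internal consistency
(zero at a perfect fit, monotone in any single residual).

## ML-t

The t family models Y ~ t_p(μ, Σ, df) with one common df; for df > 2 the
implied data covariance is df/(df−2)·Σ. The structured fit maximizes the
exact t log-likelihood over (θ, log df) jointly by L-BFGS-B with analytic
gradients (the df derivative uses digamma terms). df is bounded to
[2.01, 500]: the lower bound keeps the covariance interpretable, the upper
bound stops flat-likelihood wandering, and estimates above 200 are flagged
"effectively normal". Each fitted model — target, saturated, baseline —
estimates its own df; nothing is profiled across fits, so the LRT degrees
of freedom equal the normal-family difference (the df parameter cancels).

Two starting points are tried and the better optimum kept: the
normal-theory solution (ideal for clean data) and a Huber-robust start
(structured fit to φ = 0.10 TSR moments), which matters under heavy
contamination where the normal solution is badly biased and can sit in the
wrong basin of attraction.

Saturated and baseline (diagonal-scale) t models are fitted by ECME:
weighted mean/scatter M-steps with weights wᵢ = (df + p)/(df + δᵢ),
alternated with a bounded univariate maximization of the observed
likelihood over log df. Every sweep is monotone in the observed
log-likelihood (asserted in the tests); convergence is a relative
log-likelihood change below 1e-8 or 500 sweeps.

The Wald confidence interval for df is symmetric on the natural scale
(df̂ ± z·SE from the observed information), with a log-scale option. Near
the effectively-normal regime the df likelihood is flat and the interval
is honest but uninformative.

## Two-stage robust (TSR)

Stage 1 iterates μ ← Σw₁(dᵢ)yᵢ/Σw₁(dᵢ) and Σ ← n⁻¹Σw₂(dᵢ)(yᵢ−μ)(yᵢ−μ)ᵀ
with w₁(d) = min(1, u/d), w₂ = w₁²/τ, u² the (1−φ) quantile of χ²_p, from
median/MAD starts until the maximum elementwise change falls below 1e-9
(cap 200 iterations). The consistency constant τ = E[w₁(d)²d²]/p under
d² ~ χ²_p has the closed form [p·F_{p+2}(u²) + u²(1 − F_p(u²))]/p via the
chi-square identity E[X·1(X≤c)] = p·F_{p+2}(c), so no quadrature is
needed; τ(φ=0) = 1 and the weighted scatter is unbiased for Σ under clean
normality (checked by simulation in the tests). Stage 2 feeds (μ̂, Σ̂, n)
into the normal-theory structured fit. The resulting chi-square and fit
indices are the *uncorrected* stage-2 quantities — the residual-based
corrected statistic and sandwich standard errors for two-stage estimators
are deliberately out of scope — so TSR fit statistics here are indicative
rather than formally calibrated, and are labeled as such.

## Fit indices and information criteria

All indices are functions of (T, df, n) and therefore family-agnostic:
RMSEA = √(max(T−df, 0)/(df·n)) (denominator n, not n−1; both round to the
same third decimal at the package's reference sizes, and the alternative
is a flag), CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, 0) clipped to
[0, 1], p-values from the central χ²_df upper tail. AIC = −2ℓ + 2k,
BIC = −2ℓ + k·ln n, SABIC = −2ℓ + k·ln((n+2)/24), with k counting df for
the t family — so on clean data the t family must buy its extra parameter,
and family preference flags (t-criterion smaller) are a contamination
diagnostic. Population misfit fits a wrong structure to exact population
moments: F₀ is the minimized discrepancy, population RMSEA = √(F₀/df), and
population CFI = 1 − F₀/F₀ᵇ against the diagonal (independence) baseline,
whose population misfit has the closed form Σln σⱼⱼ − ln|Σ|.

## Satorra-Bentler scaled statistic

The mean-scaled statistic is T/c with c = tr(UΓ̂)/df, Γ̂ the empirical
covariance of vech((yᵢ−ȳ)(yᵢ−ȳ)ᵀ), and U = V − VΔ(ΔᵀVΔ)⁻¹ΔᵀV the
normal-theory residual weight, Δ the Jacobian of vech(Σ(θ)) in the
covariance-relevant parameters (with saturated means the mean block
contributes nothing and is dropped). V = ½Dᵀ(Σ_w⁻¹⊗Σ_w⁻¹)D is evaluated at
the sample covariance by default — the classical ADF-style convention that
keeps the scaling a pure function of the sample moments — with the
model-implied Σ̂ available as an option; the two agree asymptotically
under a correct model and c → 1 on clean normal data (tested). Only the
mean-scaled (not mean-and-variance-adjusted) version is provided.

## Synthetic data and contamination

Clean data are y = ν + Λη + e with ξ ~ N(0, Ψ), e ~ N(0, Θ); factor scores
are retained. The built-in study model has 3 factors and 9 indicators,
marker loadings 1, off-marker loadings 0.9/1.1, 0.7/0.55, 1.3/1.25, a 0.5
cross-loading of item 9 on factor 1, Ψ with unit variances and 0.25
covariances, Θ = I, zero means. Omitting the cross-loading yields
population RMSEA ≈ 0.061 and population CFI ≈ 0.960 (recomputed by the
acceptance script).

Two mechanisms modify exactly round(ε·n) rows (the first positions of a
seeded shuffle; bookkeeping records indices and multipliers):

- **Outliers**: y ← y + h·Λᵒξ with h = exp(z), z ~ N(0,1) per row, and Λᵒ
  a seeded orthonormal basis of the null space of Λᵀ (requires p > 2q),
  columns rescaled to a common norm. The shift is exactly orthogonal to
  the loading space, emulating gross measurement error that leaves
  factor-level information intact.
- **Bad influential observations**: y ← h·y elementwise, inflating factor
  and error components jointly. This mechanism has no free constant.

The Λᵒ column norm is the one genuinely free constant of the outlier
mechanism; it directly sets contamination severity. The default 0.75 is a
calibrated choice: it places the per-replication maximum squared
Mahalanobis distances and the downstream damage to normal-theory fit
statistics in the severity regime of the published study designs this
generator emulates, and the influential mechanism (which has no such knob)
lands in the same regime, which is the consistency check behind the
calibration. The norm is an explicit argument (`scale=`), with
`"mean_norm"` (mean Euclidean column norm of Λ) as a named alternative.

What the generator does *not* emulate: real data are rarely exactly
normal-within-the-bulk, contamination is rarely exactly orthogonal to the
loading space or exactly log-normal in magnitude, and missingness,
categorical measurement and dependence across rows are absent. Passing
Monte Carlo checks therefore demonstrate correctness of the estimators
under the stated mechanisms, not performance guarantees for arbitrary
field data.

## Monte Carlo harness

A `Condition` is one design cell (mechanism × ε × model × n × methods).
The seed of replication r is SeedSequence([base_seed, crc32(fingerprint),
r]), making results reproducible and independent of worker count (joblib
is used only to parallelize, never to split randomness). Summaries
condition on convergence: rejection rate of the LRT at α = .05, median and
adjusted MAD (1.4826 × median absolute deviation, the normal-consistent
robust SD analogue) of T, RMSEA and CFI, and per-criterion proportions of
replications in which the t family has the smaller criterion, computed
over replications where both families converged. Default n_reps is 2,000;
the shipped tests and the acceptance script use 200–500 replications per
cell, which keeps each cell's binomial Monte Carlo error around 0.01–0.03
on a rate — the problem sizes were chosen so that every check has
tolerance at least three such standard errors.

## Diagnostics

`distance_report` returns unsquared Mahalanobis distances under sample,
robust (Huber), or user-supplied moments, QQ pairs against √(χ²_p)
quantiles (distance scale on both axes), and flags cases whose squared
distance exceeds the (1 − φ) χ²_p quantile. `mardia_kurtosis` returns
b₂ₚ = mean(d⁴) with its normalized excess against the normal-theory value
p(p+2); contamination of either kind drives the excess positive.

## Known limitations

- TSR inference is uncorrected (see above); its rejection rates run
  slightly above nominal even on clean data.
- ML-t convergence degrades below n ≈ 100 and the df estimate is weakly
  identified on clean data (flat likelihood above df ≈ 50); treat large
  df̂ as "normal is adequate", not as a meaningful point estimate.
- The observed-information standard errors assume an interior optimum;
  they are unreliable when df̂ sits at its bounds or a variance is near
  zero.
- Multivariate-t likelihood surfaces under severe contamination are
  multimodal; the two-start strategy is a mitigation, not a guarantee.
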