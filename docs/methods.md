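# Methods

## The measure

For an absolutely continuous X with density f, cdf F, survival
F̄ = 1 − F and quantile function Q = F⁻¹:

    J(X)  = −(1/2) E[f(X)]                      (extropy)
    VJ(X) = Var(−1/(2 f(X))) = (1/4)E[f²] − J²  (varextropy)
    VH(X) = Var(−log f(X))                      (varentropy)

VJ is a variance, hence nonnegative, and vanishes iff f is constant on
its support (uniform).  It is translation-invariant and obeys
VJ(aX + b) = VJ(X)/a².  Existence requires ∫f³ < ∞; a density that
blows up faster than x^(−1/3) at a support endpoint has infinite VJ
(e.g. Weibull with shape α ≤ 2/3), and the engines raise rather than
return a silently wrong number when the computed "variance" comes out
clearly negative.

Note on the displayed quantile form: the definition-consistent quantile
expression is VJ = (1/4)∫₀¹ f²(Q(u))du − (1/4)(∫₀¹ f(Q(u))du)², i.e.
the squared term also carries the 1/4 (it is J² with
J = −(1/2)∫f(Q)du).  A variant missing that factor circulates; we use
the definition-consistent form, which reproduces every catalog closed
form.

## Quadrature

All continuous measures are evaluated in the quantile domain
(u = F(x)), where the density-power integrals become integrals over
(0, 1): ∫f^(k+1)dx = ∫₀¹ f^k(Q(u))du.  We use adaptive Gauss–Kronrod
quadrature (scipy `quad`) on u ∈ (1e−12, 1 − 1e−12) with absolute
tolerance 1e−10 and generous subdivision (limit 500); endpoint
singularities of f(Q(u)) (beta with shape < 1, Weibull with α < 1) are
handled by the adaptive subdivision.  Achieved accuracy is audited by
the closed-form cross-check suite: every catalog family agrees with its
closed form to 1e−6 relative (with an absolute floor of 1e−9 for the
zero-varextropy uniform members).

Ad-hoc densities (size-biased, order-statistic and record densities
used as oracles) are integrated directly in the x-domain by the same
routine.

## Monte Carlo

`varextropy_mc` draws n variates (seed mandatory — there is no silent
global RNG), evaluates y = f(X), and returns the sample variance of y
over 4 (ddof = 1).  The standard error uses the delta-method
asymptotics of a sample variance, Var(s²) ≈ (m₄ − m₂²)/n with mₖ the
central sample moments of y, divided by 4.  Default n = 10⁶ gives
standard errors around 10⁻⁵ for the catalog families; tests compare
engines at 3 standard errors.

## Taylor approximation

Expanding f around μ = E X to second order gives

    VJ(X) ≈ (1/16) f″(μ)² (μ₄ − μ₂²) + (1/4) f′(μ)² μ₂
            + (1/4) f′(μ) f″(μ) μ₃,

with μᵣ the central moments.  Derivatives are analytic for the smooth
catalog families; otherwise central differences with step
h = 1e−5·max(1, |μ|) are used (disable with
`numeric_fallback=False`).  This is an approximation, not an estimator:
for Exp(1) it gives e⁻²/4 ≈ 0.0338 against the exact 1/48 ≈ 0.0208 —
useful for qualitative comparisons only, and exact when f″ and f′
vanish at μ (uniform).

## Lifetime variants

Residual (f(x+t)/F̄(t) on x > 0) and past (f/F(t) on x < t) laws are
materialized as first-class models, so their measures are the plain
engines applied to the truncated densities.  Sanity anchors: the
exponential's residual varextropy is constant in t (memorylessness);
the past varextropy of the power-α law is the parent value times 1/t²
(the past law is the same power law rescaled to (0, t)).

The PHRM relative (survival F̄^θ) admits the one-dimensional form

    VJ(X_θ) = (θ³/4)∫₀¹ f²(Q(1−u)) u^{3(θ−1)} du
            − (θ⁴/4)(∫₀¹ f(Q(1−u)) u^{2(θ−1)} du)²,

which equals the definition applied to θ f F̄^{θ−1} (change of variable
u = F̄^{1/θ}); both routes are computed and tested against each other.
For θ < 1 the first integrand carries u^{3(θ−1)} → ∞ at 0; the value is
finite only when f(Q(1−u)) decays fast enough (it does for the
exponential, not for the uniform), and the divergence guard applies.

## Order statistics: two conventions

With B = B(k, n−k+1), U₁ ~ Beta(3k−2, 3(n−k)+1),
U₂ ~ Beta(2k−1, 2(n−k)+1):

    VJ(X_{k:n}) = B(3k−2, 3(n−k)+1)/(4B³) · E[f²(Q(U₁))]
                − B²(2k−1, 2(n−k)+1)/(4B⁴) · E²[f(Q(U₂))]

is Var(−1/(2 f_{k:n})) exactly (mode `definition`, the default).  A
closed-form convention in circulation divides the squared term by 4B²
instead of 4B⁴; published reference tables for the standard uniform
parent (n = 10) follow it, so it is provided as mode `as_printed` and
flagged in the result notes.  The two coincide at k = n = 1 and differ
otherwise; an iid-sampling oracle (k-th smallest of n draws) sides with
the definition, and a dedicated test records that asymmetry.  Family
closed forms (uniform with a 1/(b−a)² prefactor, exponential, Pareto)
follow the printed convention and are validated against the
`as_printed` quadrature.

Pareto convention: survival (β/x)^{1/λ} for x > β, so
f(Q(u)) = (1−u)^{1+λ}/(λβ) and the closed form has prefactor
1/(λ²β²) with beta arguments (3k−2, 3(n−k)+2λ+3) and
(2k−1, 2(n−k)+λ+2) — the parameterization that makes the closed form
polynomial in λ and numerically consistent with the generic formula.

Beta-function coefficients are evaluated via log-gamma differences
(`betaln`, `gammaln`), keeping the expressions finite beyond n ≈ 50.

## Record values

The n-th upper record has density [−log F̄]^{n−1} f/(n−1)! and the
representation X_{U_n} = Q(1 − e^{−G}), G ~ Gamma(n, 1), used both for
sampling and for the two-expectation formula (V ~ Gamma(3n−2),
W ~ Gamma(2n−1)).  The gamma-weighted integrals are computed on the
v = −log F̄(x) scale, where the integrands are smooth.

## Discrete case

VJ(p) = (1/4)[Σpᵢ³ − (Σpᵢ²)²] ≥ 0 by Jensen, zero iff p is uniform on
its support.  The discrete extropy is J = −Σ(1−pᵢ)log(1−pᵢ), the
definition from the extropy literature that coincides with Shannon
entropy for two-point laws — the convention under which the Bernoulli
(θ = 0.337009) and symmetric three-point (p = q ≈ 0.1508) worked
examples share the value 0.639032.  The Bernoulli quartic simplifies to
s(1−4s)/4, s = θ(1−θ), giving the maximum 1/64 at
θ = (1 ∓ 1/√2)/2 analytically; a 10⁻⁴-step grid search cross-checks it.
The three-point solver brackets the extropy root on the increasing
branch of p ↦ J(p) and returns the smallest root (Brent, xtol 1e−12).
The support spacing h affects no information measure and is stored as
metadata.  Printed-precision comparisons round half away from zero.

## Stochastic orders

Order relations quantify over continua, so the checkers evaluate the
defining inequality on a grid (default 10⁴ points, quantile clipping
1e−6, tolerance 1e−9) and return evidence, not proof: `holds=False`
carries a witness point whose violation exceeds the tolerance;
non-finite evaluations yield `undetermined`.  The superadditive order
uses a two-dimensional (t, u) grid of about √grid_size per axis.

The implication table towards the varextropy order returns
"X ≥VJ Y" for: dispersive (unconditional); hazard-rate plus a DFR
side condition; superadditive/star/convex-transform plus
f(0) ≥ g(0) > 0; and the stated st/lr entry.  The st/lr entry as
stated fails for shifted copies of one distribution (VJ is
translation-invariant while the shift is strictly st-ordered), so the
harness verifies it only on pairs sharing a left support endpoint and
keeps a shifted-copy counterexample as a regression test documenting
the implicit support condition.

Bounds: the Gaussian Poincaré (Chernoff) inequality
Var(h(X)) ≤ E[h′(X)²] for X ~ N(0,1) specializes at h = φ to
VJ(N(0,1)) ≤ 1/(24√3 π) ≈ 0.0076573 (E[φ′²] = 1/(6√3π), divided
by 4); and Chebyshev applied to f(X)/2 (mean −J, variance VJ) gives
the lower bound VJ(X) ≥ P(|f(X) + 2J(X)| ≥ 2), checked by seeded
Monte Carlo with a binomial standard error.

## Conditional decomposition

For the σ-field generated by a finite partition of the support,

    VJ(X) = E[VJ(X | F)] + (1/4) Var[E[f(X) | F]],

estimated by Monte Carlo with quantile cells by default (explicit
boundaries accepted; empty cells are merged and noted).  With ddof = 0
the two estimated terms sum to the total sample variance over 4
exactly, and the report asserts VJ(X) ≥ E[VJ(X|F)] within 3 standard
errors.  Only finite partitions are supported; general σ-fields are out
of scope.

## Problem sizes and defaults

Quadrature dominates nothing (hundreds of integrand evaluations per
measure); Monte-Carlo checks use 10⁶ draws in the engine-agreement
suite and 10⁵–2·10⁵ where a sampling oracle backs a formula, sizes at
which the standard errors are one to two orders below the effects being
tested.  The full test suite runs in well under a minute on one core.

## Known limitations

- No estimation from data: the package computes measures of *specified*
  models; it offers no nonparametric VJ estimator, censoring support,
  or fitting.
- Divergence detection is heuristic (a clearly negative variance);
  a divergent integral that happens to evaluate positive on the
  quadrature mesh would pass undetected.
- Order-relation verdicts are grid-based evidence; a violation confined
  to a region thinner than the grid spacing can be missed.
- Lower records, k-records and dependent samples are not covered; the
  bivariate formula assumes independence.
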