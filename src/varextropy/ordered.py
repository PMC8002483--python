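"""Varextropy of order statistics and upper record values.

Order statistics.  The k-th order statistic of an iid sample of size n
has density f_{k:n} = f F^{k-1} (1-F)^{n-k} / B(k, n-k+1).  Two
evaluations of VJ(X_{k:n}) are provided:

* ``mode="definition"`` — Var(-1/(2 f_{k:n}(X_{k:n}))), i.e.

      B(3k-2, 3(n-k)+1)/(4 B^3(k, n-k+1)) E[f^2(Q(U1))]
    - B^2(2k-1, 2(n-k)+1)/(4 B^4(k, n-k+1)) E^2[f(Q(U2))],

  with U1 ~ Beta(3k-2, 3(n-k)+1) and U2 ~ Beta(2k-1, 2(n-k)+1);

* ``mode="as_printed"`` — the same expression with the squared term
  divided by 4 B^2(k, n-k+1) instead of 4 B^4.  This variant circulates
  in the literature and is what published reference tables for the
  standard uniform parent (n = 10) tabulate, so it is kept available
  and flagged in the result notes; for k = n = 1 the two coincide.

Series/parallel systems (k = 1 or k = n) admit one-dimensional
u-integral forms; the series system is the PHRM relative with
theta = n.

Records.  The n-th upper record value has density
f_n = [-log(1-F)]^{n-1} f / (n-1)!  and can be sampled as
Q(1 - e^{-G}) with G ~ Gamma(n, 1).  Its varextropy follows from two
gamma-weighted expectations (V ~ Gamma(3n-2, 1), W ~ Gamma(2n-1, 1)):

    VJ(X_{U_n}) = (3n-3)!/(4 ((n-1)!)^3) E[f^2(Q(1 - e^{-V}))]
                - ((2n-2)!)^2/(4 ((n-1)!)^4) E^2[f(Q(1 - e^{-W}))].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .measures import MeasureResult, U_EPS, _clamp_vj, quad_interval
from .models import ContinuousModel

__all__ = [
    "OrderStatSpec",
    "RecordSpec",
    "order_stat_model",
    "order_stat_varextropy",
    "series_system_varextropy",
    "parallel_system_varextropy",
    "order_stat_closed_form",
    "record_model",
    "record_varextropy",
    "record_sample",
]


@dataclass(frozen=True)
class OrderStatSpec:
    """Parent law plus the rank k within a sample of size n."""

    parent: ContinuousModel
    k: int
    n: int

    def __post_init__(self):
        if self.n < 1 or not (1 <= self.k <= self.n):
            raise ValueError("order statistic requires 1 <= k <= n")


@dataclass(frozen=True)
class RecordSpec:
    """Parent law plus the upper-record index n >= 2."""

    parent: ContinuousModel
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("record value requires index n >= 2")


def _quad01(fn):
    return quad_interval(fn, U_EPS, 1.0 - U_EPS)


def order_stat_model(parent: ContinuousModel, k: int, n: int) -> ContinuousModel:
    """The k-th order statistic of n iid draws as a ContinuousModel."""
    OrderStatSpec(parent, k, n)
    lo, hi = parent.support
    logB = special.betaln(k, n - k + 1)

    def pdf(x):
        u = np.clip(parent.cdf(x), 0.0, 1.0)
        w = stats.beta.pdf(u, k, n - k + 1)
        return parent.pdf(x) * w

    cdf = lambda x: special.betainc(k, n - k + 1, np.clip(parent.cdf(x), 0.0, 1.0))
    quantile = lambda u: parent.quantile(special.betaincinv(k, n - k + 1, np.asarray(u)))

    def sampler(m, rng):
        return parent.quantile(rng.beta(k, n - k + 1, size=m))

    return ContinuousModel(
        name=f"{parent.name}_{k}of{n}",
        params={**parent.params, "k": k, "n": n, "logB": logB},
        pdf=pdf,
        cdf=cdf,
        sf=lambda x: 1.0 - cdf(x),
        quantile=quantile,
        support=(lo, hi),
        _sampler=sampler,
    )


def order_stat_varextropy(
    spec: OrderStatSpec, mode: str = "definition"
) -> MeasureResult:
    """VJ(X_{k:n}) via beta-weighted quadrature, in either mode."""
    if mode not in ("definition", "as_printed"):
        raise ValueError("mode must be 'definition' or 'as_printed'")
    parent, k, n = spec.parent, spec.k, spec.n
    fQ = lambda u: parent.pdf(parent.quantile(u))
    b1 = stats.beta(3 * k - 2, 3 * (n - k) + 1)
    b2 = stats.beta(2 * k - 1, 2 * (n - k) + 1)
    e_f2 = _quad01(lambda u: fQ(u) ** 2 * b1.pdf(u))
    e_f1 = _quad01(lambda u: fQ(u) * b2.pdf(u))
    logB = special.betaln(k, n - k + 1)
    c1 = math.exp(special.betaln(3 * k - 2, 3 * (n - k) + 1) - 3.0 * logB)
    sq_pow = 4.0 if mode == "definition" else 2.0
    c2 = math.exp(2.0 * special.betaln(2 * k - 1, 2 * (n - k) + 1) - sq_pow * logB)
    val = c1 * e_f2 / 4.0 - c2 * e_f1 ** 2 / 4.0
    if mode == "definition":
        val = _clamp_vj(val)
    return MeasureResult(
        value=val,
        method=mode,
        notes=(
            "Var(-1/(2 f_{k:n})) of the order-statistic density"
            if mode == "definition"
            else "printed closed-form convention (squared term over 4 B^2)"
        ),
    )


def series_system_varextropy(parent: ContinuousModel, n: int) -> MeasureResult:
    """VJ of the series-system lifetime X_{1:n} via its u-integral form

    (n^3/4) \\int f^2(Q(1-u)) u^{3(n-1)} du
    - (n^4/4) (\\int f(Q(1-u)) u^{2(n-1)} du)^2,

    the PHRM representation with theta = n.
    """
    if n < 1:
        raise ValueError("series system requires n >= 1")
    fQ = lambda u: parent.pdf(parent.quantile(1.0 - u))
    a = _quad01(lambda u: fQ(u) ** 2 * u ** (3.0 * (n - 1)))
    b = _quad01(lambda u: fQ(u) * u ** (2.0 * (n - 1)))
    return MeasureResult(
        value=_clamp_vj(n ** 3 * a / 4.0 - n ** 4 * b ** 2 / 4.0),
        method="quantile_quadrature",
        notes=f"series system (minimum of {n})",
    )


def parallel_system_varextropy(parent: ContinuousModel, n: int) -> MeasureResult:
    """VJ of the parallel-system lifetime X_{n:n} (u in place of 1-u)."""
    if n < 1:
        raise ValueError("parallel system requires n >= 1")
    fQ = lambda u: parent.pdf(parent.quantile(u))
    a = _quad01(lambda u: fQ(u) ** 2 * u ** (3.0 * (n - 1)))
    b = _quad01(lambda u: fQ(u) * u ** (2.0 * (n - 1)))
    return MeasureResult(
        value=_clamp_vj(n ** 3 * a / 4.0 - n ** 4 * b ** 2 / 4.0),
        method="quantile_quadrature",
        notes=f"parallel system (maximum of {n})",
    )


def order_stat_closed_form(family: str, params: dict, k: int, n: int) -> MeasureResult:
    """Closed-form VJ(X_{k:n}) (printed convention) for the three
    families that admit one.

    * uniform(a, b):  [B(3k-2,3(n-k)+1)/(4B^3) - B^2(2k-1,2(n-k)+1)/(4B^2)]
      / (b-a)^2
    * exponential(lam):  lam^2 [B(3k-2,3(n-k)+3)/(4B^3)
      - B^2(2k-1,2(n-k)+2)/(4B^2)]
    * pareto(lam, beta): [B(3k-2,3(n-k)+2 lam+3)/(4B^3)
      - B^2(2k-1,2(n-k)+lam+2)/(4B^2)] / (lam^2 beta^2)

    with B = B(k, n-k+1) throughout.
    """
    if not (1 <= k <= n):
        raise ValueError("order statistic requires 1 <= k <= n")
    logB = special.betaln(k, n - k + 1)

    def term(a1, b1, a2, b2, scale):
        first = math.exp(special.betaln(a1, b1) - 3.0 * logB) / 4.0
        second = math.exp(2.0 * special.betaln(a2, b2) - 2.0 * logB) / 4.0
        return scale * (first - second)

    if family == "uniform":
        a, b = params.get("a", 0.0), params.get("b", 1.0)
        val = term(3 * k - 2, 3 * (n - k) + 1, 2 * k - 1, 2 * (n - k) + 1,
                   1.0 / (b - a) ** 2)
    elif family == "exponential":
        lam = params["lam"]
        val = term(3 * k - 2, 3 * (n - k) + 3, 2 * k - 1, 2 * (n - k) + 2,
                   lam ** 2)
    elif family == "pareto":
        lam, beta = params["lam"], params.get("beta", 1.0)
        val = term(3 * k - 2, 3 * (n - k) + 2 * lam + 3,
                   2 * k - 1, 2 * (n - k) + lam + 2,
                   1.0 / (lam ** 2 * beta ** 2))
    else:
        raise ValueError(
            f"no order-statistic closed form for family {family!r}; "
            "supported: uniform, exponential, pareto"
        )
    return MeasureResult(value=val, method="closed_form",
                         notes="printed convention (squared term over 4 B^2)")


# ---------------------------------------------------------------------------
# records


def record_model(parent: ContinuousModel, n: int) -> ContinuousModel:
    """The n-th upper record value as a ContinuousModel."""
    RecordSpec(parent, n)
    lo, hi = parent.support
    lognf = special.gammaln(n)

    def pdf(x):
        sbar = np.clip(parent.sf(x), 1e-300, 1.0)
        g = -np.log(sbar)
        with np.errstate(divide="ignore"):
            logw = (n - 1) * np.log(g) - lognf
        return parent.pdf(x) * np.where(g > 0, np.exp(logw), 0.0)

    cdf = lambda x: special.gammainc(n, -np.log(np.clip(parent.sf(x), 1e-300, 1.0)))
    quantile = lambda u: parent.quantile(
        -np.expm1(-special.gammaincinv(n, np.asarray(u)))
    )

    def sampler(m, rng):
        g = rng.gamma(shape=n, scale=1.0, size=m)
        return parent.quantile(-np.expm1(-g))

    return ContinuousModel(
        name=f"{parent.name}_record{n}",
        params={**parent.params, "n": n},
        pdf=pdf,
        cdf=cdf,
        sf=lambda x: 1.0 - cdf(x),
        quantile=quantile,
        support=(lo, hi),
        _sampler=sampler,
    )


def record_sample(parent: ContinuousModel, n: int, size: int, seed=None) -> np.ndarray:
    """Sample the n-th upper record via Q(1 - e^{-G}), G ~ Gamma(n, 1)."""
    RecordSpec(parent, n)
    rng = np.random.default_rng(seed)
    g = rng.gamma(shape=n, scale=1.0, size=size)
    return np.asarray(parent.quantile(-np.expm1(-g)), dtype=float)


def record_varextropy(spec: RecordSpec) -> MeasureResult:
    """VJ of the n-th upper record value via its gamma representation.

    The two expectations are evaluated on the gamma scale
    v = -log(1 - F(x)), where the integrands are smooth.
    """
    parent, n = spec.parent, spec.n
    fQ = lambda v: parent.pdf(parent.quantile(-np.expm1(-v)))
    g1 = stats.gamma(3 * n - 2)
    g2 = stats.gamma(2 * n - 1)
    e_f2 = quad_interval(lambda v: fQ(v) ** 2 * g1.pdf(v), 0, np.inf)
    e_f1 = quad_interval(lambda v: fQ(v) * g2.pdf(v), 0, np.inf)
    lognf = special.gammaln(n)
    c1 = math.exp(special.gammaln(3 * n - 2) - 3.0 * lognf)
    c2 = math.exp(2.0 * special.gammaln(2 * n - 1) - 4.0 * lognf)
    return MeasureResult(
        value=_clamp_vj(c1 * e_f2 / 4.0 - c2 * e_f1 ** 2 / 4.0),
        method="quadrature",
        notes=f"upper record n={n}, gamma representation",
    )
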