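"""Continuous distribution models and the closed-form catalog.

A :class:`ContinuousModel` bundles the density, distribution function,
quantile function and sampler of an absolutely continuous law together
with optional analytic density derivatives and central moments.  It is
the single currency passed to every continuous-measure engine in this
package.

The catalog covers the standard lifetime families for which the
varextropy ``VJ(X) = Var(-1/(2 f(X)))`` and/or the varentropy
``VH(X) = Var(-log f(X))`` admit closed forms:

==================  =============================================
family              closed VJ
==================  =============================================
uniform(a, b)       0
exponential(lam)    lam^2 / 48
two-param. exp.     lam^2 / 48  (free of the location mu)
weibull(alpha,lam)  (alpha^2 lam^(2/alpha)/4) *
                    [Gamma(2r+1)/3^(2r+1) - Gamma(r+1)^2/2^(2r+2)],
                    r = (alpha-1)/alpha
power(alpha)        alpha^3 (alpha-1)^2 / (4 (3 alpha-2)(2 alpha-1)^2)
pareto(lam, beta)   [B(1,2 lam+3) - B(1,lam+2)^2] / (4 lam^2 beta^2)
laplace(beta)       1 / (192 beta^2)
beta(a, b)          B(3a-2,3b-2)/(4 B(a,b)^3) - B(2a-1,2b-1)^2/(4 B(a,b)^4)
normal(mu, sigma)   (2 - sqrt(3)) / (16 sqrt(3) pi sigma^2)
half_normal(sigma)  4x the normal value (folding a zero-symmetric law
                    quadruples VJ)
==================  =============================================

Parameterizations: the Weibull cdf is ``1 - exp(-lam x^alpha)``; the
power density is ``alpha x^(alpha-1)`` on (0, 1); the Pareto survival
function is ``(beta/x)^(1/lam)`` for ``x > beta`` (shape expressed
through 1/lam so that the order-statistic closed form of
:mod:`varextropy.ordered` is polynomial in lam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Tuple

import numpy as np
from scipy import special, stats

__all__ = [
    "ContinuousModel",
    "CatalogEntry",
    "CATALOG",
    "FAMILIES",
    "make_model",
    "model_from_scipy",
    "model_from_config",
    "model_to_config",
    "closed_form_vj",
    "closed_form_vh",
    "closed_form_j",
    "equilibrium_varextropy",
]


@dataclass(frozen=True)
class ContinuousModel:
    """An absolutely continuous distribution.

    ``pdf``/``cdf``/``sf``/``quantile`` are vectorized callables;
    ``support`` is the open interval carrying the density (endpoints
    may be infinite).  ``d1``/``d2`` are the first and second density
    derivatives when known analytically, ``central_moments`` holds
    ``(mu2, mu3, mu4)`` and ``mean`` the expectation; all are optional
    and only required by the Taylor approximation.
    """

    name: str
    params: Mapping[str, float]
    pdf: Callable[[np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray], np.ndarray]
    sf: Callable[[np.ndarray], np.ndarray]
    quantile: Callable[[np.ndarray], np.ndarray]
    support: Tuple[float, float]
    d1: Optional[Callable[[float], float]] = None
    d2: Optional[Callable[[float], float]] = None
    mean: Optional[float] = None
    central_moments: Optional[Tuple[float, float, float]] = None
    symmetry_center: Optional[float] = None
    _sampler: Optional[Callable[[int, np.random.Generator], np.ndarray]] = field(
        default=None, repr=False
    )

    def rvs(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` variates; ``seed`` may be an int or a Generator."""
        rng = np.random.default_rng(seed)
        if self._sampler is not None:
            return np.asarray(self._sampler(n, rng), dtype=float)
        # inverse-transform fallback
        return np.asarray(self.quantile(rng.uniform(size=n)), dtype=float)

    def with_name(self, name: str) -> "ContinuousModel":
        return replace(self, name=name)


def _masked_pdf(raw_pdf, lo, hi):
    """Wrap a pdf so that evaluations outside the open support return 0."""

    def pdf(x):
        x = np.asarray(x, dtype=float)
        inside = (x > lo) & (x < hi)
        out = np.zeros_like(x, dtype=float)
        if np.any(inside):
            out[inside] = raw_pdf(x[inside])
        return out if out.ndim else float(out)

    return pdf


def model_from_scipy(
    frozen,
    name: str,
    params: Mapping[str, float],
    *,
    d1=None,
    d2=None,
    symmetry_center=None,
) -> ContinuousModel:
    """Build a ContinuousModel around a frozen scipy.stats distribution."""
    lo, hi = frozen.support()
    m, v, s, k = (float(x) for x in frozen.stats(moments="mvsk"))
    mu2 = v
    mu3 = s * v ** 1.5
    mu4 = (k + 3.0) * v * v

    def sampler(n, rng):
        return frozen.rvs(size=n, random_state=rng)

    return ContinuousModel(
        name=name,
        params=dict(params),
        pdf=_masked_pdf(frozen.pdf, lo, hi),
        cdf=frozen.cdf,
        sf=frozen.sf,
        quantile=frozen.ppf,
        support=(float(lo), float(hi)),
        d1=d1,
        d2=d2,
        mean=m,
        central_moments=(mu2, mu3, mu4),
        symmetry_center=symmetry_center,
        _sampler=sampler,
    )


# ---------------------------------------------------------------------------
# family constructors


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


def _uniform(a: float = 0.0, b: float = 1.0) -> ContinuousModel:
    _require(b > a, "uniform requires b > a")
    frozen = stats.uniform(loc=a, scale=b - a)
    m = model_from_scipy(frozen, "uniform", {"a": a, "b": b},
                         symmetry_center=(a + b) / 2.0)
    return replace(m, d1=lambda x: 0.0, d2=lambda x: 0.0)


def _exponential(lam: float = 1.0) -> ContinuousModel:
    _require(lam > 0, "exponential requires lam > 0")
    frozen = stats.expon(scale=1.0 / lam)
    return model_from_scipy(
        frozen, "exponential", {"lam": lam},
        d1=lambda x: -lam ** 2 * math.exp(-lam * x),
        d2=lambda x: lam ** 3 * math.exp(-lam * x),
    )


def _two_param_exponential(lam: float = 1.0, mu: float = 0.0) -> ContinuousModel:
    _require(lam > 0, "two_param_exponential requires lam > 0")
    frozen = stats.expon(loc=mu, scale=1.0 / lam)
    return model_from_scipy(
        frozen, "two_param_exponential", {"lam": lam, "mu": mu},
        d1=lambda x: -lam ** 2 * math.exp(-lam * (x - mu)),
        d2=lambda x: lam ** 3 * math.exp(-lam * (x - mu)),
    )


def _weibull(alpha: float, lam: float = 1.0) -> ContinuousModel:
    _require(alpha > 0, "weibull requires alpha > 0")
    _require(lam > 0, "weibull requires lam > 0")
    # cdf 1 - exp(-lam x^alpha)  <=>  weibull_min(c=alpha, scale=lam^(-1/alpha))
    frozen = stats.weibull_min(alpha, scale=lam ** (-1.0 / alpha))

    def pdf_d1(x):
        a, l = alpha, lam
        return a * l * math.exp(-l * x ** a) * x ** (a - 2) * (
            (a - 1) - a * l * x ** a
        )

    return model_from_scipy(
        frozen, "weibull", {"alpha": alpha, "lam": lam},
        d1=(pdf_d1 if alpha >= 2 or alpha == 1 else None),
    )


def _power(alpha: float) -> ContinuousModel:
    _require(alpha > 1, "power requires alpha > 1")
    frozen = stats.powerlaw(alpha)
    return model_from_scipy(
        frozen, "power", {"alpha": alpha},
        d1=lambda x: alpha * (alpha - 1) * x ** (alpha - 2),
        d2=lambda x: alpha * (alpha - 1) * (alpha - 2) * x ** (alpha - 3),
    )


def _pareto(lam: float, beta: float = 1.0) -> ContinuousModel:
    _require(lam > 0, "pareto requires lam > 0")
    _require(beta > 0, "pareto requires beta > 0")
    # survival (beta/x)^(1/lam), x > beta
    frozen = stats.pareto(1.0 / lam, scale=beta)
    c = 1.0 / lam
    return model_from_scipy(
        frozen, "pareto", {"lam": lam, "beta": beta},
        d1=lambda x: -c * (c + 1) * beta ** c * x ** (-c - 2),
        d2=lambda x: c * (c + 1) * (c + 2) * beta ** c * x ** (-c - 3),
    )


def _laplace(beta: float = 1.0, mu: float = 0.0) -> ContinuousModel:
    _require(beta > 0, "laplace requires beta > 0")
    frozen = stats.laplace(loc=mu, scale=beta)
    # density has a kink at mu, so no analytic derivatives at the mean
    return model_from_scipy(frozen, "laplace", {"beta": beta, "mu": mu},
                            symmetry_center=mu)


def _beta(a: float, b: float) -> ContinuousModel:
    _require(a > 0 and b > 0, "beta requires a > 0 and b > 0")
    frozen = stats.beta(a, b)
    logB = special.betaln(a, b)

    def pdf_d1(x):
        return math.exp(-logB) * x ** (a - 2) * (1 - x) ** (b - 2) * (
            (a - 1) * (1 - x) - (b - 1) * x
        )

    return model_from_scipy(
        frozen, "beta", {"a": a, "b": b},
        d1=(pdf_d1 if min(a, b) > 1 else None),
        symmetry_center=(0.5 if a == b else None),
    )


def _normal(mu: float = 0.0, sigma: float = 1.0) -> ContinuousModel:
    _require(sigma > 0, "normal requires sigma > 0")
    frozen = stats.norm(mu, sigma)

    def pdf_d1(x):
        z = (x - mu) / sigma
        return -z / sigma * frozen.pdf(x)

    def pdf_d2(x):
        z = (x - mu) / sigma
        return (z * z - 1.0) / sigma ** 2 * frozen.pdf(x)

    return model_from_scipy(frozen, "normal", {"mu": mu, "sigma": sigma},
                            d1=pdf_d1, d2=pdf_d2, symmetry_center=mu)


def _half_normal(sigma: float = 1.0) -> ContinuousModel:
    _require(sigma > 0, "half_normal requires sigma > 0")
    frozen = stats.halfnorm(scale=sigma)
    return model_from_scipy(frozen, "half_normal", {"sigma": sigma})


_CONSTRUCTORS: dict[str, Callable[..., ContinuousModel]] = {
    "uniform": _uniform,
    "exponential": _exponential,
    "two_param_exponential": _two_param_exponential,
    "weibull": _weibull,
    "power": _power,
    "pareto": _pareto,
    "laplace": _laplace,
    "beta": _beta,
    "normal": _normal,
    "half_normal": _half_normal,
}

FAMILIES = tuple(sorted(_CONSTRUCTORS))


def make_model(family: str, **params: float) -> ContinuousModel:
    """Construct a catalog model.

    Raises ``ValueError`` naming the violated constraint for invalid
    parameters and ``KeyError`` for an unknown family.
    """
    try:
        ctor = _CONSTRUCTORS[family]
    except KeyError:
        raise KeyError(
            f"unknown family {family!r}; known families: {', '.join(FAMILIES)}"
        ) from None
    return ctor(**params)


# ---------------------------------------------------------------------------
# closed forms


@dataclass(frozen=True)
class CatalogEntry:
    """Closed-form evaluators for one family (any may be absent)."""

    family: str
    closed_vj: Optional[Callable[[Mapping[str, float]], float]] = None
    closed_vh: Optional[Callable[[Mapping[str, float]], float]] = None
    closed_j: Optional[Callable[[Mapping[str, float]], float]] = None


def _vj_weibull(p):
    a, lam = p["alpha"], p["lam"]
    r = (a - 1.0) / a
    return (a ** 2 * lam ** (2.0 / a) / 4.0) * (
        special.gamma(2 * r + 1) / 3.0 ** (2 * r + 1)
        - special.gamma(r + 1) ** 2 / 2.0 ** (2 * r + 2)
    )


def _vj_beta(p):
    a, b = p["a"], p["b"]
    if 3 * a - 2 <= 0 or 3 * b - 2 <= 0:
        raise ValueError("beta closed VJ requires a > 2/3 and b > 2/3")
    B = special.beta(a, b)
    return (
        special.beta(3 * a - 2, 3 * b - 2) / (4 * B ** 3)
        - special.beta(2 * a - 1, 2 * b - 1) ** 2 / (4 * B ** 4)
    )


def _vj_pareto(p):
    lam, beta = p["lam"], p["beta"]
    return (
        special.beta(1, 2 * lam + 3) / 4.0
        - special.beta(1, lam + 2) ** 2 / 4.0
    ) / (lam ** 2 * beta ** 2)


def _vh_weibull(p):
    a = p["alpha"]
    return math.pi ** 2 / 6.0 * (1 - 1.0 / a) ** 2 + 2.0 / a - 1.0


def _vh_power(p):
    a = p["alpha"]
    return (a - 1) ** 2 * (special.polygamma(1, a) - special.polygamma(1, a + 1))


def _vh_beta(p):
    a, b = p["a"], p["b"]
    psi1 = lambda z: special.polygamma(1, z)
    return (
        (a - 1) ** 2 * psi1(a)
        + (b - 1) ** 2 * psi1(b)
        - (a + b - 2) ** 2 * psi1(a + b)
    )


def _j_weibull(p):
    a, lam = p["alpha"], p["lam"]
    r = (a - 1.0) / a
    return -0.5 * a * lam ** (1.0 / a) * special.gamma(r + 1) / 2.0 ** (r + 1)


CATALOG: dict[str, CatalogEntry] = {
    "uniform": CatalogEntry(
        "uniform",
        closed_vj=lambda p: 0.0,
        closed_vh=lambda p: 0.0,
        closed_j=lambda p: -0.5 / (p["b"] - p["a"]),
    ),
    "exponential": CatalogEntry(
        "exponential",
        closed_vj=lambda p: p["lam"] ** 2 / 48.0,
        closed_vh=lambda p: 1.0,
        closed_j=lambda p: -p["lam"] / 4.0,
    ),
    "two_param_exponential": CatalogEntry(
        "two_param_exponential",
        closed_vj=lambda p: p["lam"] ** 2 / 48.0,
        closed_vh=lambda p: 1.0,
        closed_j=lambda p: -p["lam"] / 4.0,
    ),
    "weibull": CatalogEntry(
        "weibull", closed_vj=_vj_weibull, closed_vh=_vh_weibull, closed_j=_j_weibull
    ),
    "power": CatalogEntry(
        "power",
        closed_vj=lambda p: p["alpha"] ** 3
        * (p["alpha"] - 1) ** 2
        / (4 * (3 * p["alpha"] - 2) * (2 * p["alpha"] - 1) ** 2),
        closed_vh=_vh_power,
        closed_j=lambda p: -p["alpha"] ** 2 / (2 * (2 * p["alpha"] - 1)),
    ),
    "pareto": CatalogEntry(
        "pareto",
        closed_vj=_vj_pareto,
        closed_j=lambda p: -1.0 / (2 * p["lam"] * p["beta"] * (p["lam"] + 2)),
    ),
    "laplace": CatalogEntry(
        "laplace",
        closed_vj=lambda p: 1.0 / (192.0 * p["beta"] ** 2),
        closed_vh=lambda p: 1.0,
        closed_j=lambda p: -1.0 / (8.0 * p["beta"]),
    ),
    "beta": CatalogEntry(
        "beta",
        closed_vj=_vj_beta,
        closed_vh=_vh_beta,
        closed_j=lambda p: -special.beta(2 * p["a"] - 1, 2 * p["b"] - 1)
        / (2 * special.beta(p["a"], p["b"]) ** 2),
    ),
    "normal": CatalogEntry(
        "normal",
        closed_vj=lambda p: (2 - math.sqrt(3))
        / (16 * math.sqrt(3) * math.pi * p["sigma"] ** 2),
        closed_vh=lambda p: 0.5,
        closed_j=lambda p: -1.0 / (4 * p["sigma"] * math.sqrt(math.pi)),
    ),
    "half_normal": CatalogEntry(
        "half_normal",
        # folding a zero-symmetric X quadruples VJ: VJ(|X|) = 4 VJ(X)
        closed_vj=lambda p: (2 - math.sqrt(3))
        / (4 * math.sqrt(3) * math.pi * p["sigma"] ** 2),
        closed_j=lambda p: -1.0 / (2 * p["sigma"] * math.sqrt(math.pi)),
    ),
}


def _lookup(model: ContinuousModel, attr: str):
    entry = CATALOG.get(model.name)
    fn = getattr(entry, attr, None) if entry is not None else None
    if fn is None:
        raise ValueError(f"no {attr} registered for family {model.name!r}")
    return fn(model.params)


def closed_form_vj(model: ContinuousModel):
    """Closed-form varextropy of a catalog model."""
    from .measures import MeasureResult

    return MeasureResult(value=float(_lookup(model, "closed_vj")),
                         method="closed_form")


def closed_form_vh(model: ContinuousModel):
    """Closed-form varentropy of a catalog model."""
    from .measures import MeasureResult

    return MeasureResult(value=float(_lookup(model, "closed_vh")),
                         method="closed_form")


def closed_form_j(model: ContinuousModel):
    """Closed-form extropy of a catalog model."""
    from .measures import MeasureResult

    return MeasureResult(value=float(_lookup(model, "closed_j")),
                         method="closed_form")


def equilibrium_varextropy(mu: float):
    """Varextropy of the equilibrium law f = sf/mu built from its own
    survival function.

    Self-referentiality forces exponentiality with rate 1/mu, so the
    value is the exponential closed form 1/(48 mu^2).
    """
    from .measures import MeasureResult

    if mu <= 0:
        raise ValueError("equilibrium_varextropy requires mu > 0")
    return MeasureResult(
        value=1.0 / (48.0 * mu ** 2),
        method="closed_form",
        notes="equilibrium density f = sf/mu is exponential(1/mu)",
    )


# ---------------------------------------------------------------------------
# config (de)serialization


def model_from_config(spec: Mapping) -> ContinuousModel:
    """Build a model from a ``{"family": ..., "params": {...}}`` mapping."""
    family = spec["family"]
    params = dict(spec.get("params", {}))
    return make_model(family, **params)


def model_to_config(model: ContinuousModel) -> dict:
    return {"family": model.name, "params": dict(model.params)}
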