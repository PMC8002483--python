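"""Residual and past lifetimes, hazard rates, and the proportional
hazard rate model (PHRM).

For a lifetime X with density f, cdf F and survival sf = 1 - F:

* the residual lifetime at t is X_t = [X - t | X >= t], with density
  f(x + t)/sf(t) on x > 0;
* the past lifetime is X_[t] = [X | X <= t], with density f(x)/F(t) on
  lo < x < t;
* the hazard rate is lambda(t) = f(t)/sf(t);
* a PHRM relative of a baseline with survival sf is the law with
  survival sf(x)^theta, theta > 0 (theta = n gives the minimum of n
  iid copies).

Residual and past varextropies are the plain varextropy of the
truncated densities; the PHRM varextropy is also available through its
u-integral representation

    VJ(X_theta) = (theta^3/4) \\int_0^1 f^2(Q(1-u)) u^{3(theta-1)} du
                - (theta^4/4) (\\int_0^1 f(Q(1-u)) u^{2(theta-1)} du)^2,

which this module evaluates and which agrees with the direct definition
applied to the density theta f sf^{theta-1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import (
    MeasureResult,
    U_EPS,
    _clamp_vj,
    extropy,
    quad_interval,
    varextropy,
)
from .models import ContinuousModel

__all__ = [
    "PHRMSpec",
    "residual_model",
    "past_model",
    "residual_extropy",
    "residual_varextropy",
    "past_extropy",
    "past_varextropy",
    "hazard_rate",
    "phrm_model",
    "phrm_varextropy",
]


def residual_model(parent: ContinuousModel, t: float) -> ContinuousModel:
    """The residual lifetime [X - t | X >= t] as a ContinuousModel."""
    lo, hi = parent.support
    if t >= hi:
        raise ValueError("truncation time t is at or beyond the right support endpoint")
    t = max(t, lo)
    sbar = float(parent.sf(t))
    if sbar <= 0.0:
        raise ValueError("survival at t is zero; residual lifetime undefined")
    Ft = float(parent.cdf(t))
    pdf = lambda x: parent.pdf(np.asarray(x) + t) / sbar
    cdf = lambda x: np.clip((parent.cdf(np.asarray(x) + t) - Ft) / sbar, 0.0, 1.0)
    sf = lambda x: np.clip(parent.sf(np.asarray(x) + t) / sbar, 0.0, 1.0)
    quantile = lambda u: parent.quantile(Ft + np.asarray(u) * sbar) - t
    return ContinuousModel(
        name=f"{parent.name}_residual",
        params={**parent.params, "t": t},
        pdf=pdf,
        cdf=cdf,
        sf=sf,
        quantile=quantile,
        support=(0.0, hi - t),
    )


def past_model(parent: ContinuousModel, t: float) -> ContinuousModel:
    """The past lifetime [X | X <= t] as a ContinuousModel."""
    lo, hi = parent.support
    if t <= lo:
        raise ValueError("truncation time t is at or below the left support endpoint")
    Ft = float(parent.cdf(t))
    if Ft <= 0.0:
        raise ValueError("F(t) is zero; past lifetime undefined")
    pdf = lambda x: np.where(np.asarray(x) < t, parent.pdf(x), 0.0) / Ft
    cdf = lambda x: np.clip(parent.cdf(x) / Ft, 0.0, 1.0)
    quantile = lambda u: parent.quantile(np.asarray(u) * Ft)
    return ContinuousModel(
        name=f"{parent.name}_past",
        params={**parent.params, "t": t},
        pdf=pdf,
        cdf=cdf,
        sf=lambda x: 1.0 - np.clip(parent.cdf(x) / Ft, 0.0, 1.0),
        quantile=quantile,
        support=(lo, min(t, hi)),
    )


def residual_extropy(parent: ContinuousModel, t: float) -> MeasureResult:
    """J(X_t) = -(1/(2 sf(t)^2)) \\int_t^inf f^2."""
    res = extropy(residual_model(parent, t))
    res.notes = f"residual lifetime at t={t}"
    return res


def residual_varextropy(parent: ContinuousModel, t: float) -> MeasureResult:
    """VJ of the residual lifetime, equal to Var[f(X+t)]/(4 sf(t)^2)."""
    res = varextropy(residual_model(parent, t))
    res.notes = f"residual lifetime at t={t}"
    return res


def past_extropy(parent: ContinuousModel, t: float) -> MeasureResult:
    """J(X_[t]) = -(1/(2 F(t)^2)) \\int_lo^t f^2."""
    res = extropy(past_model(parent, t))
    res.notes = f"past lifetime at t={t}"
    return res


def past_varextropy(parent: ContinuousModel, t: float) -> MeasureResult:
    """VJ of the past lifetime [X | X <= t]."""
    res = varextropy(past_model(parent, t))
    res.notes = f"past lifetime at t={t}"
    return res


def hazard_rate(parent: ContinuousModel, t: float) -> float:
    """lambda(t) = f(t)/sf(t)."""
    sbar = float(parent.sf(t))
    if sbar <= 0.0:
        raise ValueError("survival at t is zero; hazard rate undefined")
    return float(parent.pdf(t)) / sbar


# ---------------------------------------------------------------------------
# proportional hazard rate model


@dataclass(frozen=True)
class PHRMSpec:
    """A baseline lifetime and the hazard-proportionality constant."""

    baseline: ContinuousModel
    theta: float

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("PHRM requires theta > 0")


def phrm_model(baseline: ContinuousModel, theta: float) -> ContinuousModel:
    """The law with survival sf(x)^theta and density theta f sf^(theta-1)."""
    spec = PHRMSpec(baseline, theta)
    lo, hi = baseline.support
    pdf = lambda x: spec.theta * baseline.pdf(x) * baseline.sf(x) ** (spec.theta - 1.0)
    sf = lambda x: baseline.sf(x) ** spec.theta
    cdf = lambda x: 1.0 - baseline.sf(x) ** spec.theta
    quantile = lambda u: baseline.quantile(1.0 - (1.0 - np.asarray(u)) ** (1.0 / spec.theta))
    return ContinuousModel(
        name=f"{baseline.name}_phrm",
        params={**baseline.params, "theta": theta},
        pdf=pdf,
        cdf=cdf,
        sf=sf,
        quantile=quantile,
        support=(lo, hi),
    )


def phrm_varextropy(spec: PHRMSpec) -> MeasureResult:
    """VJ of the PHRM relative via the u-integral representation.

    With U ~ U(0,1) and Q the baseline quantile function,

        VJ(X_theta) = (theta^3/4) E[f^2(Q(1-U)) U^{3(theta-1)}]
                    - (theta^4/4) E^2[f(Q(1-U)) U^{2(theta-1)}],

    expectations being integrals over u in (0, 1).
    """
    th = spec.theta
    fQ = lambda u: spec.baseline.pdf(spec.baseline.quantile(1.0 - u))
    a = quad_interval(lambda u: fQ(u) ** 2 * u ** (3.0 * (th - 1.0)),
                      U_EPS, 1.0 - U_EPS)
    b = quad_interval(lambda u: fQ(u) * u ** (2.0 * (th - 1.0)),
                      U_EPS, 1.0 - U_EPS)
    val = _clamp_vj(th ** 3 * a / 4.0 - th ** 4 * b ** 2 / 4.0)
    return MeasureResult(
        value=val,
        method="quantile_quadrature",
        notes=f"PHRM u-integral representation, theta={th}",
    )
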