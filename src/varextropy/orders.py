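"""Stochastic orders, the varextropy order, and variance bounds.

The varextropy order compares information volatility: X <=_VJ Y iff
VJ(X) <= VJ(Y).  The uniform law, having VJ = 0, is a global minimum.

The classical orders (usual stochastic, likelihood ratio, hazard rate,
dispersive, superadditive, star, convex-transform) are checked
numerically on grids, so a verdict is evidence rather than proof.  The
known implication table towards the varextropy order is exposed by
:func:`implied_vj_relation`; its headline entry is the dispersive one:
X <=_disp Y implies VJ(X) >= VJ(Y), because the dispersive order says
f(F^{-1}(u)) >= g(G^{-1}(u)) everywhere on (0, 1).

Two variance bounds round the module out: the Gaussian Poincare
(Chernoff) inequality Var(h(X)) <= E[h'(X)^2] for X ~ N(0,1), which for
h = phi gives VJ(N(0,1)) <= 1/(24 sqrt(3) pi); and the Chebyshev lower
bound VJ(X) >= P(|f(X) + 2 J(X)| >= 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, stats

from .lifetime import hazard_rate
from .measures import MeasureResult, extropy, varextropy
from .models import ContinuousModel

__all__ = [
    "OrderingVerdict",
    "RELATIONS",
    "varextropy_order",
    "check_order",
    "dfr_check",
    "chernoff_bound_check",
    "ChernoffReport",
    "chebyshev_lower_bound",
    "ChebyshevReport",
    "implied_vj_relation",
]

RELATIONS = ("st", "lr", "hr", "disp", "su", "star", "convex", "VJ")

_GRID_EPS = 1e-6
_TOL = 1e-9


@dataclass
class OrderingVerdict:
    """Outcome of a stochastic-order check on a grid."""

    relation: str
    holds: Optional[bool]  # True / False / None (undetermined)
    witness: Optional[Tuple[float, ...]] = None
    grid: str = ""
    tolerance: float = _TOL
    margin: Optional[float] = None  # smallest slack observed

    def __bool__(self) -> bool:
        return self.holds is True


def varextropy_order(
    mx: ContinuousModel, my: ContinuousModel, tolerance: float = _TOL
) -> OrderingVerdict:
    """Check X <=_VJ Y, i.e. VJ(X) <= VJ(Y)."""
    vjx = varextropy(mx).value
    vjy = varextropy(my).value
    margin = vjy - vjx
    return OrderingVerdict(
        relation="VJ",
        holds=bool(margin >= -tolerance),
        witness=None if margin >= -tolerance else (vjx, vjy),
        grid="quadrature comparison",
        tolerance=tolerance,
        margin=margin,
    )


def _verdict(relation, margins, points, grid_desc, tolerance):
    margins = np.asarray(margins, dtype=float)
    finite = np.isfinite(margins)
    if not np.all(finite):
        return OrderingVerdict(relation, None, None, grid_desc, tolerance,
                               margin=float(np.nanmin(margins)))
    i = int(np.argmin(margins))
    worst = float(margins[i])
    if worst < -tolerance:
        return OrderingVerdict(relation, False, tuple(np.atleast_1d(points[i])),
                               grid_desc, tolerance, margin=worst)
    return OrderingVerdict(relation, True, None, grid_desc, tolerance, margin=worst)


def check_order(
    relation: str,
    mx: ContinuousModel,
    my: ContinuousModel,
    grid_size: int = 10_000,
    tolerance: float = _TOL,
) -> OrderingVerdict:
    """Numerically check one of the classical orders X <=_rel Y.

    Defining inequalities evaluated on the grid:

    * st:     sf_X(t) <= sf_Y(t) for all t
    * lr:     g(t)/f(t) increasing on the common support
    * hr:     lambda_X(x) >= lambda_Y(x)
    * disp:   f(F^{-1}(u)) >= g(G^{-1}(u)), u in (0, 1)
    * su:     G^{-1}(F(t+u)) >= G^{-1}(F(t)) + G^{-1}(F(u)), t, u >= 0
    * star:   G^{-1}(F(x))/x increasing in x > 0
    * convex: G^{-1}(F(x)) convex (nonnegative second differences)
    """
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    if relation == "VJ":
        return varextropy_order(mx, my, tolerance)
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")

    u = np.linspace(_GRID_EPS, 1.0 - _GRID_EPS, grid_size)
    desc = f"{grid_size}-point grid, quantile clipping {_GRID_EPS}"

    if relation == "disp":
        mgn = mx.pdf(mx.quantile(u)) - my.pdf(my.quantile(u))
        return _verdict("disp", mgn, u, desc, tolerance)

    if relation == "st":
        # pooled quantile grid spans both supports
        x = np.unique(np.concatenate([mx.quantile(u), my.quantile(u)]))
        mgn = np.asarray(my.sf(x), dtype=float) - np.asarray(mx.sf(x), dtype=float)
        return _verdict("st", mgn, x, desc, tolerance)

    lo = max(mx.support[0], my.support[0])
    hi = min(mx.support[1], my.support[1])
    if relation in ("lr", "hr"):
        x = np.unique(np.clip(
            np.concatenate([mx.quantile(u), my.quantile(u)]), lo, hi))
        x = x[(x > lo) & (x < hi)]
        if relation == "hr":
            fx, sx = np.asarray(mx.pdf(x)), np.asarray(mx.sf(x), dtype=float)
            fy, sy = np.asarray(my.pdf(x)), np.asarray(my.sf(x), dtype=float)
            ok = (sx > 0) & (sy > 0)
            mgn = fx[ok] / sx[ok] - fy[ok] / sy[ok]
            return _verdict("hr", mgn, x[ok], desc, tolerance)
        fx = np.asarray(mx.pdf(x), dtype=float)
        fy = np.asarray(my.pdf(x), dtype=float)
        ok = fx > 0
        ratio = fy[ok] / fx[ok]
        mgn = np.diff(ratio)
        return _verdict("lr", mgn, x[ok][1:], desc, tolerance)

    # transform orders need x >= 0 reference points of X
    gs = min(grid_size, 2000)
    u = np.linspace(_GRID_EPS, 1.0 - _GRID_EPS, gs)
    x = np.asarray(mx.quantile(u), dtype=float)
    gfx = np.asarray(my.quantile(mx.cdf(x)), dtype=float)
    if relation == "convex":
        mgn = np.diff(gfx, 2)
        return _verdict("convex", mgn, x[1:-1], desc, tolerance)
    if relation == "star":
        pos = x > max(0.0, lo)
        ratio = gfx[pos] / x[pos]
        mgn = np.diff(ratio)
        return _verdict("star", mgn, x[pos][1:], desc, tolerance)
    # su: two-dimensional grid in (t, u)
    gs2 = max(int(math.sqrt(grid_size)), 30)
    q = np.linspace(0.01, 0.99, gs2)
    t = np.asarray(mx.quantile(q), dtype=float)
    t = t[t >= 0]
    T, U = np.meshgrid(t, t)
    lhs = np.asarray(my.quantile(np.clip(mx.cdf(T + U), 0, 1)), dtype=float)
    rhs = np.asarray(my.quantile(mx.cdf(T)), dtype=float) + np.asarray(
        my.quantile(mx.cdf(U)), dtype=float)
    mgn = (lhs - rhs).ravel()
    pts = np.stack([T.ravel(), U.ravel()], axis=1)
    return _verdict("su", mgn, pts, f"{gs2}x{gs2} grid in (t, u)", tolerance)


def dfr_check(model: ContinuousModel, grid_size: int = 2000,
              tolerance: float = 1e-9) -> bool:
    """True if the hazard rate is non-increasing on a quantile grid."""
    u = np.linspace(0.001, 0.999, grid_size)
    x = np.asarray(model.quantile(u), dtype=float)
    sf = np.asarray(model.sf(x), dtype=float)
    ok = sf > 0
    lam = np.asarray(model.pdf(x[ok]), dtype=float) / sf[ok]
    return bool(np.all(np.diff(lam) <= tolerance * np.maximum(lam[:-1], 1.0)))


# ---------------------------------------------------------------------------
# bounds


@dataclass
class ChernoffReport:
    variance: float          # Var(h(X)), X ~ N(0,1)
    bound: float             # E[h'(X)^2]
    holds: bool
    vj: Optional[float] = None        # VJ(N(0,1)) when h = phi
    vj_bound: Optional[float] = None  # bound/4 = 1/(24 sqrt(3) pi)


def chernoff_bound_check(
    h: Optional[Callable[[float], float]] = None,
    dh: Optional[Callable[[float], float]] = None,
) -> ChernoffReport:
    """Gaussian Poincare inequality Var(h(X)) <= E[h'(X)^2], X ~ N(0,1).

    With the default h = phi (the standard normal density itself,
    h' = -x phi(x)) the inequality divides by 4 into the varextropy
    bound VJ(N(0,1)) <= 1/(24 sqrt(3) pi).
    """
    is_phi = h is None
    if is_phi:
        h = stats.norm.pdf
        dh = lambda x: -x * stats.norm.pdf(x)
    elif dh is None:
        raise ValueError("a user-supplied h requires its derivative dh")
    phi = stats.norm.pdf
    eh, _ = integrate.quad(lambda x: h(x) * phi(x), -np.inf, np.inf, limit=300)
    eh2, _ = integrate.quad(lambda x: h(x) ** 2 * phi(x), -np.inf, np.inf, limit=300)
    edh2, _ = integrate.quad(lambda x: dh(x) ** 2 * phi(x), -np.inf, np.inf, limit=300)
    var = eh2 - eh ** 2
    rep = ChernoffReport(variance=var, bound=edh2,
                         holds=bool(var <= edh2 + 1e-12))
    if is_phi:
        rep.vj = var / 4.0
        rep.vj_bound = 1.0 / (24.0 * math.sqrt(3.0) * math.pi)
    return rep


@dataclass
class ChebyshevReport:
    vj: float
    probability: float   # Monte-Carlo estimate of P(|f(X) + 2 J(X)| >= 2)
    stderr: float
    holds: bool          # VJ >= probability - 3 stderr
    n: int


def chebyshev_lower_bound(model: ContinuousModel, n: int = 10 ** 5,
                          seed=None) -> ChebyshevReport:
    """Chebyshev lower bound VJ(X) >= P(|f(X) + 2 J(X)| >= 2).

    (Chebyshev applied to f(X)/2, whose mean is -J and whose variance
    is VJ.)  The probability is estimated by Monte Carlo with a
    binomial standard error.
    """
    if n < 1:
        raise ValueError("chebyshev_lower_bound requires n >= 1")
    j = extropy(model).value
    vj = varextropy(model).value
    x = model.rvs(n, seed=seed)
    hit = np.abs(np.asarray(model.pdf(x), dtype=float) + 2.0 * j) >= 2.0
    p = float(np.mean(hit))
    se = math.sqrt(max(p * (1 - p), 0.0) / n)
    return ChebyshevReport(vj=vj, probability=p, stderr=se,
                           holds=bool(vj >= p - 3.0 * se), n=n)


# ---------------------------------------------------------------------------
# implication table


def implied_vj_relation(
    premise: OrderingVerdict,
    dfr_x: Optional[bool] = None,
    dfr_y: Optional[bool] = None,
    f0: Optional[float] = None,
    g0: Optional[float] = None,
) -> str:
    """The varextropy relation implied by an established premise order.

    Returns ``"X >=VJ Y"`` (i.e. VJ(X) >= VJ(Y)) for:

    * disp — unconditionally;
    * hr — when X or Y is DFR (pass ``dfr_x``/``dfr_y``);
    * su/star/convex — when f(0) >= g(0) > 0 (pass ``f0``/``g0``);
    * st/lr — as stated in the source implication table (interpreted
      with the implicit common-left-endpoint support condition).

    Raises ``ValueError`` if the premise does not hold or a required
    side condition is missing/violated.
    """
    if premise.holds is not True:
        raise ValueError("premise order relation is not established")
    rel = premise.relation
    if rel == "disp":
        return "X >=VJ Y"
    if rel == "hr":
        if not (dfr_x or dfr_y):
            raise ValueError("hr premise implies >=VJ only when X or Y is DFR")
        return "X >=VJ Y"
    if rel in ("su", "star", "convex"):
        if f0 is None or g0 is None:
            raise ValueError(f"{rel} premise requires boundary densities f0, g0")
        if not (f0 >= g0 > 0):
            raise ValueError(f"{rel} premise implies >=VJ only when f(0) >= g(0) > 0")
        return "X >=VJ Y"
    if rel in ("st", "lr"):
        return "X >=VJ Y"
    raise ValueError(f"no varextropy implication registered for relation {rel!r}")
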