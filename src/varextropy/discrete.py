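"""Discrete varextropy, entropy and extropy for finite supports.

For a probability vector p_1..p_m the discrete varextropy is

    VJ(X) = (1/4) [ sum_i p_i^3 - (sum_i p_i^2)^2 ],

which is nonnegative and vanishes exactly when the vector is uniform on
its support.  The discrete extropy is taken as

    J(X) = - sum_i (1 - p_i) log(1 - p_i),

which coincides with the Shannon entropy for two-point laws.  The
Bernoulli varextropy reduces to the quartic

    VJ(Bern(theta)) = s (1 - 4 s) / 4,   s = theta (1 - theta),

maximized at s = 1/8 (theta = (1 -+ 1/sqrt(2))/2) with maximum 1/64.
A symmetric three-point family P(X = h) = P(X = -h) = p,
P(X = 0) = 1 - 2p is provided together with a solver that matches its
extropy to a target value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "DiscreteModel",
    "discrete_varextropy",
    "discrete_entropy",
    "discrete_extropy",
    "bernoulli_model",
    "bernoulli_varextropy",
    "bernoulli_varextropy_max",
    "three_point_model",
    "solve_three_point",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteModel:
    """A finite discrete law: outcomes (optional labels) and probabilities."""

    probs: Tuple[float, ...]
    outcomes: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.size < 1:
            raise ValueError("probability vector must be nonempty")
        if np.any(p < -_PROB_TOL) or np.any(p > 1 + _PROB_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum():.12g})")
        if self.outcomes is not None and len(self.outcomes) != p.size:
            raise ValueError("outcomes and probs must have equal length")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))


def _pvec(model) -> np.ndarray:
    if isinstance(model, DiscreteModel):
        return np.asarray(model.probs, dtype=float)
    return np.asarray(DiscreteModel(tuple(model)).probs, dtype=float)


def discrete_varextropy(model) -> float:
    """(1/4)[sum p_i^3 - (sum p_i^2)^2]; zero iff uniform on its support."""
    p = _pvec(model)
    v = 0.25 * (float(np.sum(p ** 3)) - float(np.sum(p ** 2)) ** 2)
    return max(v, 0.0)


def discrete_entropy(model) -> float:
    """Shannon entropy -sum p_i log p_i (natural log, 0 log 0 = 0)."""
    p = _pvec(model)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def discrete_extropy(model) -> float:
    """Extropy -sum (1 - p_i) log(1 - p_i); equals the entropy when m = 2."""
    p = _pvec(model)
    q = 1.0 - p
    q = q[q > 0]
    return float(-np.sum(q * np.log(q)))


# ---------------------------------------------------------------------------
# Bernoulli


def bernoulli_model(theta: float) -> DiscreteModel:
    if not 0.0 <= theta <= 1.0:
        raise ValueError("Bernoulli parameter must lie in [0, 1]")
    return DiscreteModel(probs=(1.0 - theta, theta), outcomes=(0.0, 1.0))


def bernoulli_varextropy(theta: float) -> float:
    """VJ of Bern(theta) via the quartic
    0.25[(1-t)^3 + t^3 - (1-t)^4 - t^4 - 2 t^2 (1-t)^2],
    algebraically equal to s(1-4s)/4 with s = t(1-t)."""
    t = float(theta)
    if not 0.0 <= t <= 1.0:
        raise ValueError("Bernoulli parameter must lie in [0, 1]")
    return 0.25 * (
        (1 - t) ** 3 + t ** 3 - (1 - t) ** 4 - t ** 4 - 2 * t ** 2 * (1 - t) ** 2
    )


def bernoulli_varextropy_max(grid_step: float = 1e-4) -> Tuple[float, float]:
    """(theta_at_max, max VJ) over theta in [0, 1].

    Analytically the maximum of s(1-4s)/4 over s = theta(1-theta) in
    [0, 1/4] is 1/64, attained at s = 1/8, i.e. theta = (1 - 1/sqrt 2)/2
    (the smaller root); a grid search cross-checks the closed form.
    """
    theta_star = (1.0 - 1.0 / math.sqrt(2.0)) / 2.0
    vmax = 1.0 / 64.0
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    vg = np.array([bernoulli_varextropy(t) for t in grid])
    if vg.max() > vmax + 1e-9:
        raise AssertionError("grid search exceeds the analytic maximum")
    return theta_star, vmax


# ---------------------------------------------------------------------------
# symmetric three-point family


def three_point_model(p: float, q: Optional[float] = None, h: float = 1.0) -> DiscreteModel:
    """P(X = h) = p, P(X = 0) = 1 - p - q, P(X = -h) = q (q defaults to p).

    The spacing h fixes the support but enters none of the information
    measures; it is stored as an outcome label only.
    """
    q = p if q is None else q
    if h <= 0:
        raise ValueError("three-point spacing h must be positive")
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError("three-point family requires p, q >= 0 and p + q <= 1")
    return DiscreteModel(probs=(p, 1.0 - p - q, q), outcomes=(h, 0.0, -h))


def _three_point_extropy(p: float) -> float:
    return discrete_extropy(three_point_model(p))


def solve_three_point(target_extropy: float, h: float = 1.0) -> DiscreteModel:
    """Find the symmetric three-point law (q = p) whose extropy equals
    ``target_extropy``, returning the smallest-p solution.

    The extropy rises from 0 at p = 0 to its maximum and the solver
    brackets the root on the increasing branch.
    """
    lo, hi = 1e-12, 0.5 - 1e-12
    grid = np.linspace(lo, hi, 2001)
    vals = np.array([_three_point_extropy(p) for p in grid])
    if not (0.0 <= target_extropy <= vals.max() + 1e-12):
        raise ValueError(
            f"target extropy {target_extropy} outside attainable range "
            f"[0, {vals.max():.6f}]"
        )
    if target_extropy < 1e-12:
        raise ValueError("target extropy 0 is attained only in the degenerate limit p -> 0")
    sign = vals - target_extropy
    idx = int(np.argmax(sign > 0))
    if idx == 0:
        raise ValueError("failed to bracket the extropy root")
    root = optimize.brentq(
        lambda p: _three_point_extropy(p) - target_extropy,
        grid[idx - 1], grid[idx], xtol=1e-12, rtol=1e-12,
    )
    return three_point_model(float(root), h=h)
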