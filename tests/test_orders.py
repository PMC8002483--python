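"""Stochastic orders, the varextropy order, implication harness and the
Chernoff/Chebyshev bounds."""

import math

import numpy as np
import pytest

from varextropy import (
    OrderStatSpec,
    chebyshev_lower_bound,
    check_order,
    chernoff_bound_check,
    dfr_check,
    implied_vj_relation,
    make_model,
    order_stat_varextropy,
    order_stat_closed_form,
    varextropy,
    varextropy_order,
)
from conftest import affine_model


class TestVarextropyOrder:
    def test_laplace_below_exponential(self):
        # VJ = 1/192 vs 1/48
        v = varextropy_order(make_model("laplace", beta=1.0),
                             make_model("exponential", lam=1.0))
        assert v.holds is True

    def test_weibull_shape2_below_exponential(self):
        # 0.0129 vs 0.0208 (prints as 0.02)
        v = varextropy_order(make_model("weibull", alpha=2.0, lam=1.0),
                             make_model("weibull", alpha=1.0, lam=1.0))
        assert v.holds is True

    def test_uniform_is_global_minimum(self, catalog_model):
        u = make_model("uniform", a=0.0, b=1.0)
        assert varextropy_order(u, catalog_model).holds is True

    def test_failure_carries_witness(self):
        v = varextropy_order(make_model("exponential", lam=2.0),
                             make_model("exponential", lam=1.0))
        assert v.holds is False
        assert v.witness is not None

    def test_symmetric_consistency_at_equality(self):
        a = make_model("exponential", lam=1.0)
        b = make_model("two_param_exponential", lam=1.0, mu=5.0)
        assert varextropy_order(a, b).holds is True
        assert varextropy_order(b, a).holds is True

    def test_exponential_vj_increasing_in_rate(self):
        vals = [varextropy(make_model("exponential", lam=l)).value
                for l in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_normal_vj_decreasing_in_sigma_location_free(self):
        vals = [varextropy(make_model("normal", mu=0.0, sigma=s)).value
                for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        shifted = varextropy(make_model("normal", mu=10.0, sigma=2.0)).value
        assert shifted == pytest.approx(vals[2], rel=1e-8)


class TestCheckOrder:
    def test_dispersive_exponential_pair(self):
        # f(F^{-1}(u)) = lam (1-u): the faster rate is less dispersed
        v = check_order("disp", make_model("exponential", lam=2.0),
                        make_model("exponential", lam=1.0), grid_size=1000)
        assert v.holds is True

    def test_dispersive_reversed_fails_with_witness(self):
        v = check_order("disp", make_model("exponential", lam=1.0),
                        make_model("exponential", lam=2.0), grid_size=1000)
        assert v.holds is False
        assert v.witness is not None
        u = v.witness[0]
        fx = 1.0 * (1 - u)
        gy = 2.0 * (1 - u)
        assert fx - gy < -v.tolerance

    def test_st_reflexive_equality(self):
        m = make_model("exponential", lam=1.0)
        assert check_order("st", m, m, grid_size=500).holds is True

    def test_st_exponential_rates(self):
        assert check_order("st", make_model("exponential", lam=2.0),
                           make_model("exponential", lam=1.0),
                           grid_size=500).holds is True

    def test_lr_exponential_rates(self):
        # g/f = (1/2) e^{x} is increasing
        assert check_order("lr", make_model("exponential", lam=2.0),
                           make_model("exponential", lam=1.0),
                           grid_size=500).holds is True

    def test_hr_exponential_rates(self):
        assert check_order("hr", make_model("exponential", lam=2.0),
                           make_model("exponential", lam=1.0),
                           grid_size=500).holds is True

    @pytest.mark.parametrize("relation", ["su", "star", "convex"])
    def test_transform_orders_linear_map(self, relation):
        # G^{-1}(F(x)) = 2x is superadditive, star-shaped and convex
        assert check_order(relation, make_model("exponential", lam=2.0),
                           make_model("exponential", lam=1.0),
                           grid_size=400).holds is True

    def test_convex_transform_weibull_to_exponential(self):
        # G^{-1}(F(x)) = x^2 is convex: Weibull(2) below Exp in convex order
        assert check_order("convex", make_model("weibull", alpha=2.0, lam=1.0),
                           make_model("exponential", lam=1.0),
                           grid_size=400).holds is True

    def test_unknown_relation(self):
        m = make_model("exponential", lam=1.0)
        with pytest.raises(ValueError, match="unknown relation"):
            check_order("foo", m, m)

    def test_small_grid_rejected(self):
        m = make_model("exponential", lam=1.0)
        with pytest.raises(ValueError, match="grid_size"):
            check_order("st", m, m, grid_size=10)


class TestDFR:
    @pytest.mark.parametrize("family,params,expected", [
        ("exponential", {"lam": 2.0}, True),
        ("weibull", {"alpha": 0.5, "lam": 1.0}, True),
        ("weibull", {"alpha": 2.0, "lam": 1.0}, False),
        ("pareto", {"lam": 1.0, "beta": 1.0}, True),
    ])
    def test_catalog_hazard_shapes(self, family, params, expected):
        assert dfr_check(make_model(family, **params)) is expected


class TestChernoffBound:
    def test_default_is_normal_density(self):
        rep = chernoff_bound_check()
        assert rep.holds
        target = (2 - math.sqrt(3)) / (16 * math.sqrt(3) * math.pi)
        assert rep.vj == pytest.approx(target, rel=1e-8)
        assert rep.vj_bound == pytest.approx(1.0 / (24 * math.sqrt(3) * math.pi),
                                             rel=1e-12)
        assert rep.vj <= rep.vj_bound
        # E[phi'(X)^2] = 1/(6 sqrt(3) pi); the VJ bound is a quarter of it
        assert rep.bound == pytest.approx(1.0 / (6 * math.sqrt(3) * math.pi),
                                          rel=1e-8)

    def test_constant_h_equality_at_zero(self):
        rep = chernoff_bound_check(h=lambda x: 1.0, dh=lambda x: 0.0)
        assert rep.holds
        assert rep.variance == pytest.approx(0.0, abs=1e-10)
        assert rep.bound == pytest.approx(0.0, abs=1e-10)

    def test_identity_h_equality_at_one(self):
        rep = chernoff_bound_check(h=lambda x: x, dh=lambda x: 1.0)
        assert rep.holds
        assert rep.variance == pytest.approx(1.0, abs=1e-8)
        assert rep.bound == pytest.approx(1.0, abs=1e-10)

    def test_missing_derivative(self):
        with pytest.raises(ValueError, match="derivative"):
            chernoff_bound_check(h=lambda x: x ** 2)


class TestChebyshevBound:
    def test_uniform_equality_at_zero(self):
        rep = chebyshev_lower_bound(make_model("uniform"), n=10 ** 4, seed=5)
        assert rep.probability == 0.0
        assert rep.vj == pytest.approx(0.0, abs=1e-10)
        assert rep.holds

    def test_exponential_unit_rate(self):
        # |f + 2J| = |e^{-x} - 1/2| < 2 always, so the bound is 0 <= 1/48
        rep = chebyshev_lower_bound(make_model("exponential", lam=1.0),
                                    n=10 ** 5, seed=5)
        assert rep.probability == 0.0
        assert rep.holds

    def test_exponential_high_rate_nontrivial(self):
        # f(0+) = 20 makes |f + 2J| >= 2 a positive-probability event
        rep = chebyshev_lower_bound(make_model("exponential", lam=20.0),
                                    n=10 ** 5, seed=5)
        assert rep.probability > 0.5
        assert rep.holds  # VJ = 400/48 ~ 8.33 comfortably dominates


class TestImplicationHarness:
    def exp_pair(self):
        # X = Exp(2), Y = Exp(1): X <= Y in disp/st/lr/hr
        return make_model("exponential", lam=2.0), make_model("exponential", lam=1.0)

    def test_disp_implies_vj_reversed(self):
        mx, my = self.exp_pair()
        premise = check_order("disp", mx, my, grid_size=500)
        assert implied_vj_relation(premise) == "X >=VJ Y"
        assert varextropy(mx).value >= varextropy(my).value  # 1/12 >= 1/48

    def test_hr_with_dfr(self):
        mx, my = self.exp_pair()
        premise = check_order("hr", mx, my, grid_size=500)
        rel = implied_vj_relation(premise, dfr_x=dfr_check(mx), dfr_y=dfr_check(my))
        assert rel == "X >=VJ Y"
        assert varextropy(mx).value >= varextropy(my).value

    def test_hr_without_dfr_needs_side_condition(self):
        mx, my = self.exp_pair()
        premise = check_order("hr", mx, my, grid_size=500)
        with pytest.raises(ValueError, match="DFR"):
            implied_vj_relation(premise)

    @pytest.mark.parametrize("relation", ["su", "star", "convex"])
    def test_transform_orders_with_boundary_densities(self, relation):
        mx, my = self.exp_pair()
        premise = check_order(relation, mx, my, grid_size=400)
        f0, g0 = float(mx.pdf(1e-9)), float(my.pdf(1e-9))
        assert f0 >= g0 > 0
        assert implied_vj_relation(premise, f0=f0, g0=g0) == "X >=VJ Y"
        with pytest.raises(ValueError, match="boundary"):
            implied_vj_relation(premise)

    def test_unestablished_premise_rejected(self):
        mx, my = self.exp_pair()
        premise = check_order("disp", my, mx, grid_size=500)  # reversed: fails
        assert premise.holds is False
        with pytest.raises(ValueError, match="not established"):
            implied_vj_relation(premise)

    def test_st_lr_implication_on_concrete_pairs(self):
        # pairs share a left support endpoint; verified numerically
        pairs = [
            (make_model("exponential", lam=2.0), make_model("exponential", lam=1.0)),
            (make_model("exponential", lam=3.0), make_model("exponential", lam=1.5)),
            (make_model("weibull", alpha=1.0, lam=2.0),
             make_model("weibull", alpha=1.0, lam=1.0)),
        ]
        for mx, my in pairs:
            for relation in ("st", "lr"):
                premise = check_order(relation, mx, my, grid_size=500)
                assert premise.holds is True
                assert implied_vj_relation(premise) == "X >=VJ Y"
                assert varextropy(mx).value >= varextropy(my).value

    def test_shifted_copy_counterexample_recorded(self):
        # X <= X + b in st order, yet VJ(X) = VJ(X + b): the st entry of
        # the implication table needs the implicit support condition
        mx = make_model("exponential", lam=1.0)
        my = affine_model(mx, 1.0, 2.0)
        premise = check_order("st", mx, my, grid_size=500)
        assert premise.holds is True
        assert varextropy(mx).value == pytest.approx(varextropy(my).value,
                                                     rel=1e-7)

    def test_counterexample_flips_with_premise(self):
        # reversing the dispersive pair reverses the VJ comparison
        mx, my = self.exp_pair()
        assert check_order("disp", mx, my, grid_size=500).holds is True
        assert check_order("disp", my, mx, grid_size=500).holds is False
        assert varextropy_order(my, mx).holds is True   # VJ(Y) <= VJ(X)
        assert varextropy_order(mx, my).holds is False


class TestOrderStatOrderings:
    @pytest.mark.parametrize("n", [5, 10])
    def test_uniform_extremes_maximal_median_minimal(self, n):
        vals = [order_stat_closed_form("uniform", {}, k, n).value
                for k in range(1, n + 1)]
        median_rank = (n + 1) // 2 if n % 2 else n // 2
        assert np.argmin(vals) + 1 in (median_rank, n + 1 - median_rank)
        assert max(vals) == pytest.approx(vals[0], rel=1e-12)
        assert max(vals) == pytest.approx(vals[-1], rel=1e-12)

    # the DFR Weibull shape is kept above 2/3 so every density-power
    # integral involved stays finite
    @pytest.mark.parametrize("family,params", [
        ("exponential", {"lam": 1.0}),
        ("weibull", {"alpha": 0.75, "lam": 1.0}),
    ])
    @pytest.mark.parametrize("n", [2, 5])
    def test_dfr_parent_extreme_order_stats(self, family, params, n):
        # for DFR parents: VJ(min) >= VJ(X) and VJ(max) <= VJ(X)
        parent = make_model(family, **params)
        assert dfr_check(parent)
        vj = varextropy(parent).value
        vmin = order_stat_varextropy(OrderStatSpec(parent, 1, n)).value
        vmax = order_stat_varextropy(OrderStatSpec(parent, n, n)).value
        assert vmin >= vj - 1e-10, (family, n)
        assert vmax <= vj + 1e-10, (family, n)
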