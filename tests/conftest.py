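import numpy as np
import pytest

from varextropy import ContinuousModel, make_model

# one representative per catalog family, used by cross-check suites
CATALOG_CASES = [
    ("uniform", {"a": 0.0, "b": 1.0}),
    ("exponential", {"lam": 1.7}),
    ("two_param_exponential", {"lam": 1.3, "mu": 2.0}),
    ("weibull", {"alpha": 2.0, "lam": 1.0}),
    ("power", {"alpha": 2.5}),
    ("pareto", {"lam": 1.0, "beta": 1.0}),
    ("laplace", {"beta": 0.8, "mu": 0.0}),
    ("beta", {"a": 2.0, "b": 3.0}),
    ("normal", {"mu": 0.0, "sigma": 1.5}),
    ("half_normal", {"sigma": 1.2}),
]


@pytest.fixture(params=CATALOG_CASES, ids=[c[0] for c in CATALOG_CASES])
def catalog_model(request):
    family, params = request.param
    return make_model(family, **params)


def affine_model(model: ContinuousModel, a: float, b: float) -> ContinuousModel:
    """The law of Y = aX + b (a > 0), built from first principles so that
    scale/location laws are tested against an independently constructed
    model rather than against family parameter arithmetic."""
    assert a > 0
    lo, hi = model.support
    return ContinuousModel(
        name=f"{model.name}_affine",
        params={**model.params, "a": a, "b": b},
        pdf=lambda y: model.pdf((np.asarray(y) - b) / a) / a,
        cdf=lambda y: model.cdf((np.asarray(y) - b) / a),
        sf=lambda y: model.sf((np.asarray(y) - b) / a),
        quantile=lambda u: a * np.asarray(model.quantile(u)) + b,
        support=(a * lo + b, a * hi + b),
    )
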