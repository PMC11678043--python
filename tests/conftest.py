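import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from aqbd.design import FactorDefinition, make_ccd
from aqbd.fixtures import SyntheticSpec, generate_responses, load_fixture
from aqbd.model import ModelSpec, fit_model


@pytest.fixture(scope="session")
def fx():
    return load_fixture("curcuminoid")


@pytest.fixture(scope="session")
def design19(fx):
    """The study's 19-run face-centered CCD (3 factors, 5 centers)."""
    return make_ccd(fx.factors, alpha="face_centered", n_center=5, seed=7)


@pytest.fixture(scope="session")
def kbmc_truth(fx):
    return fx.models["k BMC"]


def simulate_kbmc(design, truth, sd=0.104, seed=0):
    tab = generate_responses(SyntheticSpec(design, {"k BMC": truth}, sd, seed=seed))
    return tab["k BMC"].to_numpy()


@pytest.fixture(scope="session")
def kbmc_fit(design19, kbmc_truth):
    """A reduced-quadratic retention-factor fit at the study's noise scale."""
    y = simulate_kbmc(design19, kbmc_truth, sd=0.104, seed=42)
    return fit_model(design19, y, kbmc_truth.spec, response_name="k BMC")


@pytest.fixture(scope="session")
def random_fit():
    """A generic full-rank OLS fit on random (seeded) data, n=19, p=5."""
    rng = np.random.default_rng(1234)
    X = np.column_stack([np.ones(19), rng.normal(size=(19, 4))])
    beta = np.array([1.0, 0.5, -0.3, 0.0, 0.8])
    y = X @ beta + rng.normal(0, 0.3, 19)
    spec = ModelSpec.from_strings(("x1", "x2", "x3", "x4"),
                                  ["1", "x1", "x2", "x3", "x4"])
    from aqbd.model import fit_ols

    return fit_ols(X, y, spec=spec)


@pytest.fixture(scope="session")
def two_factor_linear():
    """A fitted purely linear 2-factor model (for propagation checks)."""
    factors = [FactorDefinition("X", "u", 0.0, 2.0), FactorDefinition("Y", "u", 10.0, 30.0)]
    d = make_ccd(factors, n_center=3, seed=3)
    spec = ModelSpec.from_strings(("X", "Y"), ["1", "X", "Y"])
    truth_b = np.array([5.0, 1.5, -0.8])
    rng = np.random.default_rng(5)
    from aqbd.model import build_model_matrix, fit_ols

    X = build_model_matrix(d, spec)
    y = X @ truth_b + rng.normal(0, 0.05, X.shape[0])
    fit = fit_ols(X, y, spec=spec, factors=factors)
    return d, fit, truth_b

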