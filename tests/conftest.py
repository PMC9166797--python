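import numpy as np
import pandas as pd
import pytest

from bpbench.cohort import (
    CohortConfig,
    CorrelationSpec,
    VariableSpec,
    calibrate_outcome_model,
    generate_outcome,
    load_cohort_config,
    simulate_covariates,
)


@pytest.fixture(scope="session")
def ami_config():
    return load_cohort_config("ami")


@pytest.fixture(scope="session")
def chf_config():
    return load_cohort_config("chf")


def make_toy_config(rho: float = 0.2, n_derivation: int = 1000, n_validation: int = 1000):
    """A small five-predictor cohort for fast unit tests."""
    variables = (
        VariableSpec("age", "continuous", 70.0, 72.0, 10.0, 11.0),
        VariableSpec("sbp", "continuous", 150.0, 148.0, 30.0, 31.0),
        VariableSpec("creatinine", "continuous", 100.0, 105.0, 50.0, 55.0),
        VariableSpec("female", "binary", 0.40, 0.45),
        VariableSpec("diabetes", "binary", 0.30, 0.32),
    )
    outcome = VariableSpec("discharge_sbp", "continuous", 120.0, 122.0, 20.0, 21.0)
    return CohortConfig(
        cohort_id="toy",
        variables=variables,
        outcome_spec=outcome,
        n_derivation=n_derivation,
        n_validation=n_validation,
        correlation=CorrelationSpec(mode="exchangeable", rho=rho),
    )


@pytest.fixture(scope="session")
def toy_config():
    return make_toy_config()


@pytest.fixture(scope="session")
def toy_samples(toy_config):
    """Derivation/validation tables with a calibrated linear truth (sf=0.5)."""
    deriv = simulate_covariates(toy_config, "derivation", 1000, seed=11)
    valid = simulate_covariates(toy_config, "validation", 1000, seed=11)
    model = calibrate_outcome_model(toy_config, deriv, signal_fraction=0.5, seed=11)
    y_d = generate_outcome(model, deriv, seed=12)
    y_v = generate_outcome(model, valid, seed=13)
    return deriv.with_outcome(y_d), valid.with_outcome(y_v), model


@pytest.fixture()
def linear_toy():
    """A noiseless y = 2 + 3*x truth on one continuous predictor."""
    rng = np.random.default_rng(5)
    x = rng.normal(0.0, 1.0, 200)
    X = pd.DataFrame({"x": x})
    y = 2.0 + 3.0 * x
    return X, y
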