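"""Cohort synthesis: config loading, copula marginals, outcome calibration."""

import numpy as np
import pandas as pd
import pytest

from bpbench.cohort import (
    CohortConfig,
    ConfigError,
    CorrelationSpec,
    VariableSpec,
    baseline_table,
    bootstrap_expand,
    calibrate_outcome_model,
    generate_outcome,
    load_cohort_config,
    simulate_covariates,
)

from conftest import make_toy_config


class TestConfigLoading:
    def test_packaged_ami(self, ami_config):
        assert ami_config.n_predictors == 33
        assert ami_config.n_derivation == 8145
        assert ami_config.n_validation == 4444
        assert ami_config.outcome_spec.deriv_mean == pytest.approx(120.40)
        assert ami_config.outcome_spec.deriv_sd == pytest.approx(19.69)

    def test_packaged_chf(self, chf_config):
        assert chf_config.n_predictors == 28
        assert chf_config.n_derivation == 7156
        assert chf_config.n_validation == 6818

    def test_suppressed_cell_imputed_and_flagged(self, ami_config):
        shock = next(v for v in ami_config.variables if v.name == "cardiogenic_shock")
        assert shock.valid_mean == pytest.approx(0.005)
        assert shock.imputed

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigError, match="unknown cohort"):
            load_cohort_config("nonexistent_cohort")

    def test_out_of_range_prevalence_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            """
cohort_id: bad
n_derivation: 10
n_validation: 10
outcome:
  name: y
  kind: continuous
  derivation: {mean: 0, sd: 1}
  validation: {mean: 0, sd: 1}
variables:
  - name: b
    kind: binary
    derivation: {prevalence: 1.2}
    validation: {prevalence: 0.5}
"""
        )
        with pytest.raises(ConfigError, match="prevalence"):
            load_cohort_config(bad)

    def test_duplicate_variable_names_rejected(self):
        v = VariableSpec("x", "continuous", 0.0, 0.0, 1.0, 1.0)
        with pytest.raises(ConfigError, match="duplicate"):
            CohortConfig(
                cohort_id="dup",
                variables=(v, v),
                outcome_spec=VariableSpec("y", "continuous", 0.0, 0.0, 1.0, 1.0),
                n_derivation=10,
                n_validation=10,
            )

    def test_file_round_trip_matches_packaged(self, tmp_path, ami_config):
        # the packaged yaml read through the file path gives the same config
        import importlib.resources as res

        text = res.files("bpbench").joinpath("data/ami.yaml").read_text()
        path = tmp_path / "ami_copy.yaml"
        path.write_text(text)
        assert load_cohort_config(path).config_hash() == ami_config.config_hash()


class TestSimulateCovariates:
    def test_shape_and_column_order(self, ami_config):
        t = simulate_covariates(ami_config, "derivation", 500, seed=1)
        assert t.data.shape == (500, 33)
        assert t.columns == ami_config.variable_names

    def test_marginal_recovery_at_large_n(self, toy_config):
        # every column within 4 Monte Carlo SEs of its spec at n = 50,000
        n = 50_000
        t = simulate_covariates(toy_config, "derivation", n, seed=2)
        for var in toy_config.variables:
            col = t.data[var.name].to_numpy()
            if var.kind == "continuous":
                se_mean = var.deriv_sd / np.sqrt(n)
                assert abs(col.mean() - var.deriv_mean) < 4 * se_mean
                se_sd = var.deriv_sd / np.sqrt(2 * (n - 1))
                assert abs(col.std(ddof=1) - var.deriv_sd) < 4 * se_sd
            else:
                p = var.deriv_mean
                se = np.sqrt(p * (1 - p) / n)
                assert abs(col.mean() - p) < 4 * se

    def test_role_selects_marginals(self, toy_config):
        t = simulate_covariates(toy_config, "validation", 50_000, seed=2)
        age = toy_config.variables[0]
        assert abs(t.data["age"].mean() - age.valid_mean) < 4 * age.valid_sd / np.sqrt(50_000)

    def test_copula_correlation_monotone_in_rho(self):
        n = 50_000

        def mean_corr(rho):
            cfg = make_toy_config(rho=rho)
            t = simulate_covariates(cfg, "derivation", n, seed=3)
            cont = t.data[["age", "sbp", "creatinine"]].to_numpy()
            c = np.corrcoef(cont, rowvar=False)
            return c[np.triu_indices(3, 1)].mean()

        assert mean_corr(0.5) > mean_corr(0.1)

    def test_determinism_and_seed_sensitivity(self, toy_config):
        a = simulate_covariates(toy_config, "derivation", 100, seed=4)
        b = simulate_covariates(toy_config, "derivation", 100, seed=4)
        c = simulate_covariates(toy_config, "derivation", 100, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert (a.data.to_numpy() != c.data.to_numpy()).any()

    def test_degenerate_marginals(self):
        cfg = CohortConfig(
            cohort_id="degen",
            variables=(
                VariableSpec("never", "binary", 0.0, 0.0),
                VariableSpec("const", "continuous", 7.0, 7.0, 0.0, 0.0),
            ),
            outcome_spec=VariableSpec("y", "continuous", 0.0, 0.0, 1.0, 1.0),
            n_derivation=10,
            n_validation=10,
        )
        t = simulate_covariates(cfg, "derivation", 200, seed=1)
        assert (t.data["never"] == 0.0).all()
        assert (t.data["const"] == 7.0).all()

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        spec = CorrelationSpec(mode="matrix", matrix=bad)
        with pytest.raises(ConfigError, match="not PSD"):
            spec.latent_matrix(3)


class TestOutcomeCalibration:
    def test_pure_noise_limit(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 500, seed=6)
        m = calibrate_outcome_model(toy_config, t, signal_fraction=0.0, seed=6)
        assert (m.coefficients == 0).all()
        assert m.intercept == pytest.approx(120.0)
        assert m.noise_sd == pytest.approx(20.0)

    @pytest.mark.parametrize("sf", [0.2, 0.5])
    def test_signal_fraction_realized(self, toy_config, sf):
        t = simulate_covariates(toy_config, "derivation", 50_000, seed=7)
        m = calibrate_outcome_model(toy_config, t, signal_fraction=sf, seed=7)
        y = generate_outcome(m, t, seed=8).to_numpy()
        lp = m.linear_predictor(t)
        assert np.var(lp) / np.var(y) == pytest.approx(sf, abs=0.01)
        # calibration identity: outcome variance within 5% of target_sd^2
        assert np.var(y) == pytest.approx(m.target_sd**2, rel=0.05)

    def test_variance_decomposition_identity(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 2000, seed=9)
        m = calibrate_outcome_model(toy_config, t, signal_fraction=0.3, seed=9)
        implied = np.var(m.linear_predictor(t)) + m.noise_sd**2
        assert implied == pytest.approx(m.target_sd**2, rel=1e-6)

    def test_invalid_signal_fraction(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 100, seed=1)
        with pytest.raises(ValueError, match="signal_fraction"):
            calibrate_outcome_model(toy_config, t, signal_fraction=1.0)

    def test_noiseless_outcome_equals_linear_predictor(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 300, seed=10)
        m = calibrate_outcome_model(toy_config, t, signal_fraction=0.5, seed=10)
        m0 = type(m)(
            coefficients=m.coefficients,
            intercept=m.intercept,
            noise_sd=0.0,
            target_mean=m.target_mean,
            target_sd=m.target_sd,
            signal_fraction=m.signal_fraction,
        )
        y = generate_outcome(m0, t, seed=11).to_numpy()
        np.testing.assert_allclose(y, m.linear_predictor(t), rtol=0, atol=1e-10)

    def test_linearity_in_coefficients(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 300, seed=10)
        m = calibrate_outcome_model(toy_config, t, signal_fraction=0.5, seed=10)
        doubled = type(m)(
            coefficients=2 * m.coefficients,
            intercept=m.intercept,
            noise_sd=0.0,
            target_mean=m.target_mean,
            target_sd=m.target_sd,
            signal_fraction=m.signal_fraction,
        )
        base = m.linear_predictor(t) - m.intercept
        np.testing.assert_allclose(
            doubled.linear_predictor(t) - m.intercept, 2 * base, atol=1e-8
        )


class TestBootstrapExpand:
    def test_expansion_rows_come_from_source(self, toy_config):
        t = simulate_covariates(toy_config, "validation", 50, seed=1)
        big = bootstrap_expand(t, 5000, seed=2)
        assert big.n == 5000
        source = {tuple(r) for r in t.data.to_numpy()}
        sample = {tuple(r) for r in big.data.to_numpy()[:200]}
        assert sample <= source

    def test_outcome_carried_along(self, toy_config):
        t = simulate_covariates(toy_config, "validation", 30, seed=1)
        y = pd.Series(np.arange(30.0))
        big = bootstrap_expand(t.with_outcome(y), 100, seed=3)
        # each row's outcome equals the source row's outcome
        assert big.outcome is not None
        src = {tuple(r): v for r, v in zip(t.data.to_numpy(), y)}
        for row, v in zip(big.data.to_numpy(), big.outcome):
            assert src[tuple(row)] == v

    def test_m_zero_and_single_row(self, toy_config):
        t = simulate_covariates(toy_config, "validation", 10, seed=1)
        empty = bootstrap_expand(t, 0, seed=1)
        assert empty.n == 0 and empty.columns == t.columns
        one = simulate_covariates(toy_config, "validation", 1, seed=1)
        rep = bootstrap_expand(one, 50, seed=1)
        assert (rep.data.to_numpy() == one.data.to_numpy()[0]).all()

    def test_determinism(self, toy_config):
        t = simulate_covariates(toy_config, "validation", 40, seed=1)
        a = bootstrap_expand(t, 500, seed=9)
        b = bootstrap_expand(t, 500, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestBaselineTable:
    def test_identical_samples_give_p_near_one(self, toy_config):
        t = simulate_covariates(toy_config, "derivation", 400, seed=1)
        y = pd.Series(np.random.default_rng(1).normal(120, 20, 400))
        table = baseline_table(t.with_outcome(y), t.with_outcome(y))
        assert (table["p_value"] > 0.99).all()

    def test_shifted_continuous_column_detected(self, toy_config):
        # shift one column by 5 standard errors: p < 0.01 from the t-test
        n = 400
        a = simulate_covariates(toy_config, "derivation", n, seed=2)
        b_data = a.data.copy()
        sd = b_data["age"].std(ddof=1)
        b_data["age"] = b_data["age"] + 5 * sd * np.sqrt(2.0 / n)
        b = type(a)(b_data, a.cohort_id, a.role, a.seed, a.kinds)
        table = baseline_table(a, b)
        row = table[table["variable"] == "age"].iloc[0]
        assert row["p_value"] < 0.01

    def test_schema_mismatch_rejected(self, toy_config):
        a = simulate_covariates(toy_config, "derivation", 50, seed=1)
        b = type(a)(a.data[a.columns[:-1]], a.cohort_id, a.role, a.seed, a.kinds)
        with pytest.raises(ValueError, match="schema"):
            baseline_table(a, b)


def test_csv_round_trip_with_sidecar(toy_config, tmp_path):
    t = simulate_covariates(toy_config, "derivation", 60, seed=4)
    y = pd.Series(np.arange(60.0), name="discharge_sbp")
    path = tmp_path / "cohort.csv"
    t.with_outcome(y).write_csv(path)
    back = pd.read_csv(path)
    assert back.shape == (60, 6)
    assert (path.parent / "cohort.csv.json").exists()
    np.testing.assert_allclose(
        back[t.columns].to_numpy(), t.data.to_numpy(), atol=1e-12
    )
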