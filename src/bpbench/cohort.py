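"""Synthetic cohort generation for the AMI and CHF blood-pressure samples.

The original derivation/validation samples (hospitalizations for acute
myocardial infarction and congestive heart failure, with discharge systolic
blood pressure as the outcome) are access-restricted, but their per-variable
marginals — mean +/- SD for continuous covariates, prevalence for binary
ones — and sample sizes are published. This module turns those marginals
into synthetic stand-in cohorts:

* ``simulate_covariates`` draws a mixed continuous/binary covariate table
  from a Gaussian copula, so the marginals match the printed summaries while
  an exchangeable (or user-supplied) latent correlation provides realistic
  dependence between predictors.
* ``calibrate_outcome_model`` builds a known linear ground truth whose
  marginal mean/SD match the printed discharge blood pressure and whose
  explained-variance fraction (the theoretical R-squared ceiling) is chosen
  by the caller — the real study observes this relationship in data; the
  synthetic study needs it as an explicit, testable truth.
* ``bootstrap_expand`` resamples a validation table with replacement, used
  to blow validation samples up to 100,000 subjects so external-performance
  estimates carry negligible evaluation noise.

The packaged ``ami`` and ``chf`` configurations carry every published
baseline row (33 and 28 predictors). The one suppressed cell — cardiogenic
shock in the AMI validation sample, censored at source for small counts —
is imputed at 0.5% prevalence and flagged ``imputed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._rng import substream

__all__ = [
    "VariableSpec",
    "CorrelationSpec",
    "CohortConfig",
    "CovariateTable",
    "CalibratedOutcomeModel",
    "load_cohort_config",
    "simulate_covariates",
    "calibrate_outcome_model",
    "generate_outcome",
    "bootstrap_expand",
    "baseline_table",
]

PACKAGED_COHORTS = ("ami", "chf")

Role = Literal["derivation", "validation"]


class ConfigError(ValueError):
    """A cohort configuration violates the documented schema."""


@dataclass(frozen=True)
class VariableSpec:
    """Marginal description of one variable in one cohort.

    For continuous variables ``*_mean``/``*_sd`` are the sample mean and SD
    in the variable's own units; for binary variables ``*_mean`` holds the
    prevalence proportion in [0, 1] and the SD fields are None.
    """

    name: str
    kind: Literal["continuous", "binary"]
    deriv_mean: float
    valid_mean: float
    deriv_sd: float | None = None
    valid_sd: float | None = None
    lognormal: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"{self.name}: kind must be continuous or binary")
        if self.kind == "binary":
            for role, p in (("derivation", self.deriv_mean), ("validation", self.valid_mean)):
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"{self.name}: {role} prevalence {p} outside [0, 1]"
                    )
            if self.deriv_sd is not None or self.valid_sd is not None:
                raise ConfigError(f"{self.name}: binary variables carry prevalence only")
        else:
            for role, sd in (("derivation", self.deriv_sd), ("validation", self.valid_sd)):
                if sd is None:
                    raise ConfigError(f"{self.name}: continuous variable missing {role} sd")
                if sd < 0:
                    raise ConfigError(f"{self.name}: {role} sd {sd} is negative")

    def mean(self, role: Role) -> float:
        return self.deriv_mean if role == "derivation" else self.valid_mean

    def sd(self, role: Role) -> float | None:
        return self.deriv_sd if role == "derivation" else self.valid_sd


@dataclass(frozen=True)
class CorrelationSpec:
    """Latent (copula-scale) correlation between predictors.

    ``independent`` is the identity; ``exchangeable`` uses a common rho in
    (-1/(p-1), 1); ``matrix`` takes an explicit positive-semidefinite p x p
    correlation matrix. Only marginals are published for the real cohorts,
    so any choice here is a documented stand-in, not an estimate.
    """

    mode: Literal["independent", "exchangeable", "matrix"] = "exchangeable"
    rho: float = 0.2
    matrix: np.ndarray | None = None

    def latent_matrix(self, p: int) -> np.ndarray:
        if self.mode == "independent":
            return np.eye(p)
        if self.mode == "exchangeable":
            if p > 1 and not (-1.0 / (p - 1) < self.rho < 1.0):
                raise ConfigError(
                    f"exchangeable rho {self.rho} outside (-1/(p-1), 1) for p={p}"
                )
            return np.full((p, p), self.rho) + (1.0 - self.rho) * np.eye(p)
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (p, p):
            raise ConfigError(f"correlation matrix shape {mat.shape} != ({p}, {p})")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ConfigError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
            raise ConfigError("correlation matrix diagonal must be 1")
        eigmin = float(np.linalg.eigvalsh(mat).min())
        if eigmin < -1e-8:
            raise ConfigError(f"correlation matrix not PSD (min eigenvalue {eigmin:.3g})")
        return mat


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one disease cohort: marginals, sizes, correlation."""

    cohort_id: str
    variables: tuple[VariableSpec, ...]
    outcome_spec: VariableSpec
    n_derivation: int
    n_validation: int
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)

    def __post_init__(self) -> None:
        if self.n_derivation < 1 or self.n_validation < 1:
            raise ConfigError("sample sizes must be positive")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate variable names: {dupes}")
        if self.outcome_spec.kind != "continuous":
            raise ConfigError("outcome must be continuous")

    @property
    def n_predictors(self) -> int:
        return len(self.variables)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def kinds(self) -> dict[str, str]:
        return {v.name: v.kind for v in self.variables}

    def n_for(self, role: Role) -> int:
        return self.n_derivation if role == "derivation" else self.n_validation

    def config_hash(self) -> str:
        payload = {
            "cohort_id": self.cohort_id,
            "n_derivation": self.n_derivation,
            "n_validation": self.n_validation,
            "correlation": {
                "mode": self.correlation.mode,
                "rho": self.correlation.rho,
                "matrix": None
                if self.correlation.matrix is None
                else np.asarray(self.correlation.matrix).tolist(),
            },
            "outcome": _spec_to_dict(self.outcome_spec),
            "variables": [_spec_to_dict(v) for v in self.variables],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class CovariateTable:
    """An n x p covariate table plus provenance (cohort, role, seed).

    ``data`` columns follow the config's variable order; binary columns hold
    {0, 1} floats, continuous columns real values. ``outcome`` is attached
    by :func:`generate_outcome` / carried through :func:`bootstrap_expand`.
    """

    data: pd.DataFrame
    cohort_id: str
    role: str
    seed: int
    kinds: dict[str, str]
    outcome: pd.Series | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def with_outcome(self, y: pd.Series) -> "CovariateTable":
        if len(y) != self.n:
            raise ValueError("outcome length does not match table")
        return CovariateTable(
            self.data, self.cohort_id, self.role, self.seed, self.kinds, y
        )

    def to_frame(self, outcome_name: str = "discharge_sbp") -> pd.DataFrame:
        out = self.data.copy()
        if self.outcome is not None:
            out[outcome_name] = np.asarray(self.outcome)
        return out

    def write_csv(self, path: str | Path) -> None:
        """Write the table as headered CSV plus a provenance sidecar JSON."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "cohort_id": self.cohort_id,
            "role": self.role,
            "seed": self.seed,
            "n": self.n,
            "kinds": self.kinds,
            "has_outcome": self.outcome is not None,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


@dataclass(frozen=True)
class CalibratedOutcomeModel:
    """Linear ground truth calibrated to a printed outcome marginal.

    Outcome_i = intercept + sum_j beta_j x_ij + Normal(0, noise_sd^2), with
    the coefficients scaled so that on the calibration covariates the
    outcome mean equals ``target_mean`` and the linear predictor explains
    ``signal_fraction`` of the target variance; noise_sd supplies the rest,
    so the implied outcome SD equals ``target_sd``.
    """

    coefficients: pd.Series
    intercept: float
    noise_sd: float
    target_mean: float
    target_sd: float
    signal_fraction: float

    def linear_predictor(self, covariates: CovariateTable) -> np.ndarray:
        X = covariates.data
        missing = [c for c in self.coefficients.index if c not in X.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        return self.intercept + X[list(self.coefficients.index)].to_numpy() @ (
            self.coefficients.to_numpy()
        )


# ---------------------------------------------------------------------------
# config I/O


def _spec_to_dict(v: VariableSpec) -> dict:
    d: dict = {"name": v.name, "kind": v.kind}
    if v.kind == "continuous":
        d["derivation"] = {"mean": v.deriv_mean, "sd": v.deriv_sd}
        d["validation"] = {"mean": v.valid_mean, "sd": v.valid_sd}
    else:
        d["derivation"] = {"prevalence": v.deriv_mean}
        d["validation"] = {"prevalence": v.valid_mean}
        if v.imputed:
            d["validation"]["imputed"] = True
    return d


def _spec_from_dict(d: dict) -> VariableSpec:
    try:
        name = d["name"]
        kind = d["kind"]
        deriv = d["derivation"]
        valid = d["validation"]
    except KeyError as exc:
        raise ConfigError(f"variable entry missing field {exc}") from None
    if kind == "continuous":
        for role, block in (("derivation", deriv), ("validation", valid)):
            if "mean" not in block or "sd" not in block:
                raise ConfigError(f"{name}: {role} needs mean and sd")
        return VariableSpec(
            name=name,
            kind="continuous",
            deriv_mean=float(deriv["mean"]),
            deriv_sd=float(deriv["sd"]),
            valid_mean=float(valid["mean"]),
            valid_sd=float(valid["sd"]),
            lognormal=bool(d.get("lognormal", False)),
        )
    for role, block in (("derivation", deriv), ("validation", valid)):
        if "prevalence" not in block:
            raise ConfigError(f"{name}: {role} needs prevalence")
    return VariableSpec(
        name=name,
        kind="binary",
        deriv_mean=float(deriv["prevalence"]),
        valid_mean=float(valid["prevalence"]),
        imputed=bool(valid.get("imputed", False)),
    )


def load_cohort_config(source: str | Path) -> CohortConfig:
    """Load a cohort config by packaged name ("ami", "chf") or file path.

    The file schema is documented YAML: cohort_id, n_derivation,
    n_validation, correlation {mode, rho | matrix}, outcome, and a
    variables list with per-role mean/sd (continuous) or prevalence
    (binary). Violations raise :class:`ConfigError` naming the field.
    """
    if isinstance(source, str) and source in PACKAGED_COHORTS:
        text = (
            resources.files("bpbench").joinpath(f"data/{source}.yaml").read_text()
        )
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(
                f"unknown cohort {source!r}: not a packaged name "
                f"{PACKAGED_COHORTS} and no such file"
            )
        text = path.read_text()
    raw = yaml.safe_load(text)
    for key in ("cohort_id", "n_derivation", "n_validation", "outcome", "variables"):
        if key not in raw:
            raise ConfigError(f"config missing field {key!r}")
    corr_raw = raw.get("correlation", {"mode": "exchangeable", "rho": 0.2})
    mode = corr_raw.get("mode", "exchangeable")
    if mode not in ("independent", "exchangeable", "matrix"):
        raise ConfigError(f"correlation mode {mode!r} unknown")
    correlation = CorrelationSpec(
        mode=mode,
        rho=float(corr_raw.get("rho", 0.2)),
        matrix=None
        if corr_raw.get("matrix") is None
        else np.asarray(corr_raw["matrix"], dtype=float),
    )
    return CohortConfig(
        cohort_id=str(raw["cohort_id"]),
        variables=tuple(_spec_from_dict(d) for d in raw["variables"]),
        outcome_spec=_spec_from_dict(raw["outcome"]),
        n_derivation=int(raw["n_derivation"]),
        n_validation=int(raw["n_validation"]),
        correlation=correlation,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_covariates(
    config: CohortConfig,
    role: Role,
    n: int | None = None,
    seed: int = 0,
) -> CovariateTable:
    """Draw an n x p covariate table from the Gaussian copula.

    A latent multivariate normal z with the configured correlation is drawn;
    continuous column j is mean_j + sd_j * z_j (or a matched-moment
    lognormal when the variable is flagged), binary column j is
    1{z_j > Phi^-1(1 - prevalence_j)}. Identical (config, role, n, seed)
    reproduce the identical table.
    """
    if role not in ("derivation", "validation"):
        raise ValueError(f"role must be derivation or validation, got {role!r}")
    if n is None:
        n = config.n_for(role)
    if n < 1:
        raise ValueError("n must be >= 1")
    p = config.n_predictors
    corr = config.correlation.latent_matrix(p)
    rng = substream(seed, "covariates", config.cohort_id, role, n)
    # eigh-based square root tolerates the PSD-but-singular edge Cholesky rejects
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, p)) @ root.T

    cols: dict[str, np.ndarray] = {}
    for j, var in enumerate(config.variables):
        zj = z[:, j]
        if var.kind == "continuous":
            m, s = var.mean(role), var.sd(role)
            if var.lognormal and s > 0 and m > 0:
                # lognormal with matching first two moments
                sigma2 = np.log1p((s / m) ** 2)
                mu = np.log(m) - sigma2 / 2.0
                cols[var.name] = np.exp(mu + np.sqrt(sigma2) * zj)
            else:
                cols[var.name] = m + s * zj
        else:
            prev = var.mean(role)
            if prev <= 0.0:
                cols[var.name] = np.zeros(n)
            elif prev >= 1.0:
                cols[var.name] = np.ones(n)
            else:
                thresh = stats.norm.ppf(1.0 - prev)
                cols[var.name] = (zj > thresh).astype(float)
    data = pd.DataFrame(cols, columns=config.variable_names)
    return CovariateTable(
        data=data, cohort_id=config.cohort_id, role=role, seed=seed, kinds=config.kinds
    )


def calibrate_outcome_model(
    config: CohortConfig,
    covariates: CovariateTable,
    signal_fraction: float,
    raw_coefficients: Sequence[float] | None = None,
    seed: int = 0,
) -> CalibratedOutcomeModel:
    """Scale a raw coefficient vector into a calibrated linear truth.

    Raw coefficients (drawn reproducibly from ``seed`` when not supplied —
    standard normal per predictor, divided by the predictor's marginal SD so
    every variable contributes comparably) are multiplied by one common
    factor c and paired with an intercept so that, on ``covariates``,
    mean(outcome) = target_mean and var(linear predictor) =
    signal_fraction * target_sd^2. noise_sd = target_sd * sqrt(1 - sf).
    """
    if not 0.0 <= signal_fraction < 1.0:
        raise ValueError(f"signal_fraction must be in [0, 1), got {signal_fraction}")
    role: Role = covariates.role  # type: ignore[assignment]
    target_mean = config.outcome_spec.mean(role)
    target_sd = config.outcome_spec.sd(role)
    assert target_sd is not None
    names = config.variable_names
    X = covariates.data[names].to_numpy()

    if raw_coefficients is None:
        rng = substream(seed, "outcome-coefficients", config.cohort_id)
        raw = rng.standard_normal(len(names))
        # scale-free contributions: unit effect per marginal SD (binary: per
        # Bernoulli SD at the configured prevalence)
        for j, var in enumerate(config.variables):
            if var.kind == "continuous":
                s = var.sd(role) or 0.0
            else:
                prev = var.mean(role)
                s = float(np.sqrt(prev * (1.0 - prev)))
            raw[j] = raw[j] / s if s > 0 else 0.0
    else:
        raw = np.asarray(raw_coefficients, dtype=float)
        if raw.shape != (len(names),):
            raise ValueError(
                f"raw_coefficients length {raw.shape} != number of predictors {len(names)}"
            )

    if signal_fraction == 0.0:
        coefficients = pd.Series(np.zeros(len(names)), index=names)
        return CalibratedOutcomeModel(
            coefficients=coefficients,
            intercept=float(target_mean),
            noise_sd=float(target_sd),
            target_mean=float(target_mean),
            target_sd=float(target_sd),
            signal_fraction=0.0,
        )

    lp_raw = X @ raw
    v_raw = float(np.var(lp_raw))
    if v_raw <= 0.0:
        raise ValueError(
            "linear predictor is constant on the supplied covariates; "
            "cannot calibrate a positive signal_fraction"
        )
    c = float(np.sqrt(signal_fraction * target_sd**2 / v_raw))
    beta = c * raw
    intercept = float(target_mean - np.mean(X @ beta))
    noise_sd = float(target_sd * np.sqrt(1.0 - signal_fraction))
    return CalibratedOutcomeModel(
        coefficients=pd.Series(beta, index=names),
        intercept=intercept,
        noise_sd=noise_sd,
        target_mean=float(target_mean),
        target_sd=float(target_sd),
        signal_fraction=float(signal_fraction),
    )


def generate_outcome(
    model: CalibratedOutcomeModel,
    covariates: CovariateTable,
    seed: int = 0,
) -> pd.Series:
    """Draw outcome_i = intercept + x_i . beta + Normal(0, noise_sd^2)."""
    lp = model.linear_predictor(covariates)
    rng = substream(seed, "outcome-noise", covariates.cohort_id, covariates.role)
    y = lp + rng.normal(0.0, model.noise_sd, size=len(lp))
    return pd.Series(y, index=covariates.data.index, name="discharge_sbp")


def bootstrap_expand(
    table: CovariateTable,
    m: int,
    seed: int = 0,
) -> CovariateTable:
    """Resample ``table`` with replacement to ``m`` rows (outcome carried).

    Used to expand validation samples (e.g. 4444 -> 100,000 subjects) so
    external-performance estimates have negligible evaluation noise.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    if m > 0 and table.n == 0:
        raise ValueError("cannot expand an empty table")
    rng = substream(seed, "bootstrap", table.cohort_id, table.role, m)
    idx = rng.integers(0, table.n, size=m) if m > 0 else np.array([], dtype=int)
    data = table.data.iloc[idx].reset_index(drop=True)
    outcome = None
    if table.outcome is not None:
        outcome = pd.Series(
            np.asarray(table.outcome)[idx], name=table.outcome.name
        )
    return CovariateTable(
        data=data,
        cohort_id=table.cohort_id,
        role=table.role,
        seed=seed,
        kinds=table.kinds,
        outcome=outcome,
    )


def baseline_table(
    derivation: CovariateTable,
    validation: CovariateTable,
    outcome_name: str = "discharge_sbp",
) -> pd.DataFrame:
    """Baseline-characteristics comparison of two samples.

    Continuous rows report mean +/- SD per sample with a two-sample t-test
    p-value; binary rows report N (%) with a chi-squared p-value — the
    conventional presentation for a derivation-vs-validation table.
    """
    if derivation.columns != validation.columns:
        raise ValueError("derivation and validation tables have different schemas")
    rows = []

    def _row(name: str, kind: str, a: np.ndarray, b: np.ndarray) -> dict:
        if kind == "continuous":
            if np.var(a) == 0.0 and np.var(b) == 0.0:
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            return {
                "variable": name,
                "kind": kind,
                "derivation": f"{np.mean(a):.2f} ± {np.std(a, ddof=1):.2f}",
                "validation": f"{np.mean(b):.2f} ± {np.std(b, ddof=1):.2f}",
                "p_value": p,
            }
        ka, kb = int(np.sum(a)), int(np.sum(b))
        table = np.array(
            [[ka, len(a) - ka], [kb, len(b) - kb]], dtype=float
        )
        if np.any(table.sum(axis=0) == 0):
            p = 1.0
        else:
            p = float(stats.chi2_contingency(table, correction=True)[1])
        return {
            "variable": name,
            "kind": kind,
            "derivation": f"{ka} ({100.0 * ka / len(a):.1f}%)",
            "validation": f"{kb} ({100.0 * kb / len(b):.1f}%)",
            "p_value": p,
        }

    if derivation.outcome is not None and validation.outcome is not None:
        rows.append(
            _row(
                outcome_name,
                "continuous",
                np.asarray(derivation.outcome, dtype=float),
                np.asarray(validation.outcome, dtype=float),
            )
        )
    for name in derivation.columns:
        kind = derivation.kinds.get(name, "continuous")
        rows.append(
            _row(
                name,
                kind,
                derivation.data[name].to_numpy(dtype=float),
                validation.data[name].to_numpy(dtype=float),
            )
        )
    return pd.DataFrame(rows)
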