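"""The six prediction methods behind one fit/predict contract.

Methods: OLS linear regression with restricted cubic splines for continuous
predictors (``ols_rcs``), the lasso and ridge regression on standardized
predictors (``lasso``, ``ridge``), stochastic gradient boosting with
regression-tree base learners (``boosted_trees``), random forests
(``random_forest``), and a single-hidden-layer feed-forward neural network
with weight decay (``nnet1``). An ``intercept_only`` baseline is available
as a diagnostic; it is not one of the compared methods.

Penalty convention for the penalized linear models: with all predictors
standardized to unit variance and the intercept unpenalized, lasso
minimizes (1/2n)·RSS + lam·||b||_1 and ridge minimizes
(1/2n)·RSS + (lam/2)·||b||_2^2 — the usual coordinate-descent-path
parameterization, so packaged lam values are on that scale. Coefficients
are reported back on the original predictor scale.

The neural network is fit by quasi-Newton (L-BFGS) minimization of the
penalized least-squares criterion sum_i (y_i - f(x_i))^2 + decay * ||w||^2
over all weights and biases, with logistic hidden units, a linear output
unit, standardized inputs, and initial weights drawn Uniform(-0.5, 0.5)
from the seed (output bias started at mean(y)).
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge

from .cohort import CovariateTable
from .splines import KnotSet, place_knots, rcs_basis

__all__ = [
    "METHODS",
    "LearnerSpec",
    "FittedLearner",
    "fit_learner",
    "predict",
    "save_learner",
    "load_learner",
]

METHODS = ("ols_rcs", "lasso", "ridge", "boosted_trees", "random_forest", "nnet1")

_FORMAT_VERSION = "bpbench-learner/1"


def _validate_hyperparameters(method: str, hp: dict) -> dict:
    """Fill method defaults and range-check; returns a normalized dict."""
    hp = dict(hp)
    if method == "ols_rcs":
        hp.setdefault("knots", 3)
        if hp["knots"] not in (3, 4, 5, 6, 7):
            raise ValueError(f"ols_rcs knots must be in 3..7, got {hp['knots']}")
    elif method in ("lasso", "ridge"):
        hp.setdefault("lam", 0.0)
        if hp["lam"] < 0:
            raise ValueError(f"{method} penalty lam must be >= 0, got {hp['lam']}")
    elif method == "boosted_trees":
        hp.setdefault("n_trees", 100)
        hp.setdefault("interaction_depth", 1)
        hp.setdefault("learning_rate", 0.1)
        hp.setdefault("subsample", 1.0)
        if hp["interaction_depth"] < 1:
            raise ValueError("interaction_depth must be >= 1")
        if hp["learning_rate"] < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 < hp["subsample"] <= 1:
            raise ValueError("subsample must be in (0, 1]")
        if hp["n_trees"] < 1:
            raise ValueError("n_trees must be >= 1")
    elif method == "random_forest":
        hp.setdefault("n_trees", 500)
        hp.setdefault("mtry", None)  # None -> floor(p/3) at fit time
        hp.setdefault("min_node_size", 5)
        if hp["n_trees"] < 1:
            raise ValueError("n_trees must be >= 1")
        if hp["mtry"] is not None and hp["mtry"] < 1:
            raise ValueError("mtry must be >= 1")
        if hp["min_node_size"] < 1:
            raise ValueError("min_node_size must be >= 1")
    elif method == "nnet1":
        hp.setdefault("hidden_units", 5)
        hp.setdefault("weight_decay", 0.0)
        hp.setdefault("linear_hidden", False)
        hp.setdefault("max_iter", 500)
        if hp["hidden_units"] < 1:
            raise ValueError("hidden_units must be >= 1")
        if hp["weight_decay"] < 0:
            raise ValueError("weight_decay must be >= 0")
    elif method == "intercept_only":
        pass
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return hp


@dataclass(frozen=True)
class LearnerSpec:
    """A method identity plus its (complete, validated) hyperparameters."""

    method: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "hyperparameters",
            _validate_hyperparameters(self.method, dict(self.hyperparameters)),
        )

    def hp(self, key: str):
        return self.hyperparameters[key]


@dataclass
class FittedLearner:
    """An opaque fitted predictor honoring the training column schema.

    ``state`` is method-specific: for ``ols_rcs`` it holds per-predictor
    knot sets, the named coefficient vector and the residual SD sigma-hat
    (RSS/(n-p) variant); for the penalized linear models the original-scale
    coefficients plus the standardization used in fitting; for the tree
    ensembles the fitted scikit-learn estimator; for ``nnet1`` the weight
    matrices and input standardization.
    """

    spec: LearnerSpec
    schema: tuple[str, ...]
    kinds: dict[str, str]
    state: dict

    @property
    def residual_sd(self) -> float:
        if "residual_sd" not in self.state:
            raise AttributeError(
                f"{self.spec.method} does not expose a residual SD"
            )
        return float(self.state["residual_sd"])


def _as_frame(X) -> tuple[pd.DataFrame, dict[str, str]]:
    if isinstance(X, CovariateTable):
        return X.data, dict(X.kinds)
    df = pd.DataFrame(X)
    kinds = {}
    for c in df.columns:
        vals = np.unique(df[c].to_numpy(dtype=float))
        kinds[c] = "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"
    return df, kinds


def _check_inputs(Xdf: pd.DataFrame, y: np.ndarray) -> None:
    if Xdf.isna().to_numpy().any() or np.isnan(y).any():
        raise ValueError("inputs contain missing values")
    if len(Xdf) != len(y):
        raise ValueError(f"X has {len(Xdf)} rows but y has {len(y)}")


# ---------------------------------------------------------------------------
# ols_rcs


def _ols_design(
    Xdf: pd.DataFrame,
    schema: Sequence[str],
    kinds: Mapping[str, str],
    knots_map: Mapping[str, KnotSet],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(Xdf))]
    names = ["(intercept)"]
    for name in schema:
        x = Xdf[name].to_numpy(dtype=float)
        if kinds[name] == "continuous":
            basis = rcs_basis(x, knots_map[name])
            cols.extend(basis.T)
            names.append(name)
            names.extend(name + "'" * j for j in range(1, basis.shape[1]))
        else:
            cols.append(x)
            names.append(name)
    return np.column_stack(cols), names


def _fit_ols_rcs(spec, Xdf, kinds, y):
    k = int(spec.hp("knots"))
    schema = tuple(Xdf.columns)
    knots_map = {
        name: place_knots(Xdf[name].to_numpy(dtype=float), k)
        for name in schema
        if kinds[name] == "continuous"
    }
    D, names = _ols_design(Xdf, schema, kinds, knots_map)
    n, p = D.shape
    if n <= p:
        raise ValueError(f"ols_rcs needs n > p; got n={n}, design columns p={p}")
    coef, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    if rank < p:
        raise ValueError(
            f"ols_rcs design is rank deficient (rank {rank} < {p} columns)"
        )
    resid = y - D @ coef
    sigma2 = float(resid @ resid) / (n - p)
    return {
        "knots": {name: ks.knots for name, ks in knots_map.items()},
        "coefficients": dict(zip(names, coef.tolist())),
        "coef_vector": coef,
        "design_names": names,
        "residual_sd": float(np.sqrt(max(sigma2, 0.0))),
    }


def _predict_ols_rcs(fitted: FittedLearner, Xdf: pd.DataFrame) -> np.ndarray:
    knots_map = {
        name: KnotSet(tuple(k)) for name, k in fitted.state["knots"].items()
    }
    D, _ = _ols_design(Xdf, fitted.schema, fitted.kinds, knots_map)
    return D @ np.asarray(fitted.state["coef_vector"], dtype=float)


# ---------------------------------------------------------------------------
# penalized linear models


def _fit_penalized(spec, Xdf, y):
    lam = float(spec.hp("lam"))
    X = Xdf.to_numpy(dtype=float)
    n = len(X)
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD, the path-algorithm convention
    scale_safe = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale_safe
    ybar = float(np.mean(y))
    yc = y - ybar
    if lam == 0.0:
        beta_std, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    elif spec.method == "lasso":
        est = Lasso(alpha=lam, fit_intercept=False, max_iter=100_000, tol=1e-10)
        est.fit(Z, yc)
        beta_std = est.coef_
    else:
        # (1/2n) RSS + (lam/2)||b||^2  ==  RSS + n*lam*||b||^2 up to a factor
        est = Ridge(alpha=n * lam, fit_intercept=False, solver="cholesky")
        est.fit(Z, yc)
        beta_std = est.coef_
    beta = np.where(scale > 0, beta_std / scale_safe, 0.0)
    intercept = ybar - float(center @ beta)
    return {
        "coefficients": dict(zip(Xdf.columns, beta.tolist())),
        "coef_vector": beta,
        "intercept": intercept,
        "center": center,
        "scale": scale,
    }


def _predict_linear(fitted: FittedLearner, Xdf: pd.DataFrame) -> np.ndarray:
    beta = np.asarray(fitted.state["coef_vector"], dtype=float)
    return fitted.state["intercept"] + Xdf.to_numpy(dtype=float) @ beta


# ---------------------------------------------------------------------------
# tree ensembles


def _fit_boosted(spec, Xdf, y, seed):
    lr = float(spec.hp("learning_rate"))
    if lr == 0.0:
        # zero step size: the stagewise recursion never leaves the initial
        # constant, so the fit is the training mean
        return {"constant": float(np.mean(y))}
    est = GradientBoostingRegressor(
        n_estimators=int(spec.hp("n_trees")),
        learning_rate=lr,
        max_depth=int(spec.hp("interaction_depth")),
        subsample=float(spec.hp("subsample")),
        random_state=int(seed) & 0x7FFFFFFF,
    )
    est.fit(Xdf.to_numpy(dtype=float), y)
    return {"estimator": est}


def _fit_forest(spec, Xdf, y, seed):
    p = Xdf.shape[1]
    mtry = spec.hp("mtry")
    mtry = max(1, p // 3) if mtry is None else min(int(mtry), p)
    est = RandomForestRegressor(
        n_estimators=int(spec.hp("n_trees")),
        max_features=mtry,
        min_samples_leaf=int(spec.hp("min_node_size")),
        bootstrap=True,
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    est.fit(Xdf.to_numpy(dtype=float), y)
    return {"estimator": est}


def _predict_sklearn(fitted: FittedLearner, Xdf: pd.DataFrame) -> np.ndarray:
    if "constant" in fitted.state:
        return np.full(len(Xdf), fitted.state["constant"])
    return fitted.state["estimator"].predict(Xdf.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# single-hidden-layer neural network


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _fit_nnet(spec, Xdf, y, seed):
    H = int(spec.hp("hidden_units"))
    decay = float(spec.hp("weight_decay"))
    linear_hidden = bool(spec.hp("linear_hidden"))
    max_iter = int(spec.hp("max_iter"))
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale

    n_w1 = (p + 1) * H  # input->hidden weights and biases
    n_w2 = H + 1  # hidden->output weights and bias
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6E6E6574])
    )
    w0 = rng.uniform(-0.5, 0.5, n_w1 + n_w2)
    w0[-1] = float(np.mean(y))  # start the output bias at the outcome mean

    def unpack(w):
        W1 = w[: p * H].reshape(p, H)
        b1 = w[p * H : n_w1]
        w2 = w[n_w1 : n_w1 + H]
        b2 = w[-1]
        return W1, b1, w2, b2

    def objective(w):
        W1, b1, w2, b2 = unpack(w)
        A = Z @ W1 + b1
        Hout = A if linear_hidden else _sigmoid(A)
        f = Hout @ w2 + b2
        r = f - y
        loss = float(r @ r) + decay * float(w @ w)
        g_f = 2.0 * r
        g_w2 = Hout.T @ g_f + 2.0 * decay * w2
        g_b2 = float(np.sum(g_f)) + 2.0 * decay * b2
        g_H = np.outer(g_f, w2)
        g_A = g_H if linear_hidden else g_H * Hout * (1.0 - Hout)
        g_W1 = Z.T @ g_A + 2.0 * decay * W1
        g_b1 = g_A.sum(axis=0) + 2.0 * decay * b1
        grad = np.concatenate(
            [g_W1.ravel(), g_b1, g_w2, np.array([g_b2])]
        )
        return loss, grad

    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-8, "gtol": 1e-8},
    )
    W1, b1, w2, b2 = unpack(res.x)
    return {
        "W1": W1,
        "b1": b1,
        "w2": w2,
        "b2": float(b2),
        "center": center,
        "scale": scale,
        "linear_hidden": linear_hidden,
        "converged": bool(res.success),
        "n_iter": int(res.nit),
    }


def _predict_nnet(fitted: FittedLearner, Xdf: pd.DataFrame) -> np.ndarray:
    st = fitted.state
    Z = (Xdf.to_numpy(dtype=float) - np.asarray(st["center"])) / np.asarray(st["scale"])
    A = Z @ np.asarray(st["W1"]) + np.asarray(st["b1"])
    Hout = A if st["linear_hidden"] else _sigmoid(A)
    return Hout @ np.asarray(st["w2"]) + st["b2"]


# ---------------------------------------------------------------------------
# public contract


def fit_learner(
    spec: LearnerSpec,
    X: CovariateTable | pd.DataFrame,
    y: Sequence[float] | pd.Series,
    seed: int = 0,
) -> FittedLearner:
    """Fit ``spec`` to (X, y); returns a :class:`FittedLearner`.

    ``seed`` controls the stochastic learners (forest bootstrap/feature
    sampling, boosting subsampling if enabled, network initialization);
    identical (spec, data, seed) give identical predictions.
    """
    Xdf, kinds = _as_frame(X)
    y = np.asarray(y, dtype=float)
    _check_inputs(Xdf, y)
    method = spec.method
    if method == "ols_rcs":
        state = _fit_ols_rcs(spec, Xdf, kinds, y)
    elif method in ("lasso", "ridge"):
        state = _fit_penalized(spec, Xdf, y)
    elif method == "boosted_trees":
        state = _fit_boosted(spec, Xdf, y, seed)
    elif method == "random_forest":
        state = _fit_forest(spec, Xdf, y, seed)
    elif method == "nnet1":
        state = _fit_nnet(spec, Xdf, y, seed)
    elif method == "intercept_only":
        state = {"constant": float(np.mean(y))}
    else:  # pragma: no cover - LearnerSpec already validates
        raise ValueError(f"unknown method {method!r}")
    return FittedLearner(
        spec=spec, schema=tuple(Xdf.columns), kinds=kinds, state=state
    )


def predict(fitted: FittedLearner, X: CovariateTable | pd.DataFrame) -> np.ndarray:
    """Predict with a fitted learner; ``X`` must carry the training schema."""
    Xdf, _ = _as_frame(X)
    missing = [c for c in fitted.schema if c not in Xdf.columns]
    extra = [c for c in Xdf.columns if c not in fitted.schema]
    if missing or extra:
        raise ValueError(
            f"schema mismatch: missing columns {missing}, unexpected {extra}"
        )
    Xdf = Xdf[list(fitted.schema)]
    if Xdf.isna().to_numpy().any():
        raise ValueError("inputs contain missing values")
    method = fitted.spec.method
    if method == "ols_rcs":
        return _predict_ols_rcs(fitted, Xdf)
    if method in ("lasso", "ridge"):
        return _predict_linear(fitted, Xdf)
    if method in ("boosted_trees", "random_forest"):
        return _predict_sklearn(fitted, Xdf)
    if method == "nnet1":
        return _predict_nnet(fitted, Xdf)
    if method == "intercept_only":
        return np.full(len(Xdf), fitted.state["constant"])
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization (versioned; round-trip tested)


def _encode_state(state: dict) -> dict:
    out = {}
    for key, val in state.items():
        if isinstance(val, np.ndarray):
            out[key] = {"__array__": val.tolist()}
        elif key == "estimator":
            blob = base64.b64encode(pickle.dumps(val)).decode("ascii")
            out[key] = {"__pickle__": blob}
        elif isinstance(val, dict):
            out[key] = {"__dict__": _encode_state(val)}
        elif isinstance(val, tuple):
            out[key] = {"__tuple__": list(val)}
        else:
            out[key] = val
    return out


def _decode_state(state: dict) -> dict:
    out = {}
    for key, val in state.items():
        if isinstance(val, dict) and "__array__" in val:
            out[key] = np.asarray(val["__array__"], dtype=float)
        elif isinstance(val, dict) and "__pickle__" in val:
            out[key] = pickle.loads(base64.b64decode(val["__pickle__"]))
        elif isinstance(val, dict) and "__dict__" in val:
            out[key] = _decode_state(val["__dict__"])
        elif isinstance(val, dict) and "__tuple__" in val:
            out[key] = tuple(val["__tuple__"])
        else:
            out[key] = val
    return out


def save_learner(fitted: FittedLearner, path: str | Path) -> None:
    """Serialize to the versioned learner file (JSON container)."""
    payload = {
        "format": _FORMAT_VERSION,
        "method": fitted.spec.method,
        "hyperparameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in fitted.spec.hyperparameters.items()
        },
        "schema": list(fitted.schema),
        "kinds": fitted.kinds,
        "state": _encode_state(fitted.state),
    }
    Path(path).write_text(json.dumps(payload))


def load_learner(path: str | Path) -> FittedLearner:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported learner file format {payload.get('format')!r}"
        )
    spec = LearnerSpec(payload["method"], payload["hyperparameters"])
    return FittedLearner(
        spec=spec,
        schema=tuple(payload["schema"]),
        kinds=dict(payload["kinds"]),
        state=_decode_state(payload["state"]),
    )
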