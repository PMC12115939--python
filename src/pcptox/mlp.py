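"""Small feed-forward networks for activity and toxic-effect prediction.

The network has three layers: a normalization layer (centering-reduction of
each raw input using training-set statistics), a hidden layer of 1-3 neurons
sharing one activation function (tanh, arctan, or exp), and a linear output
neuron.  Training minimizes the sum of squared errors by full-batch
quasi-Newton (L-BFGS) optimization capped at a fixed number of iterative
cycles (default 100) from a seeded random initialization.

Model development follows an architecture search: 3 hidden-layer sizes x 3
activation functions x 10 random restarts = 90 candidate models, compared on
the training data by coefficient of determination (ties broken by residual
standard deviation, then by enumeration order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

ACTIVATIONS = ("tanh", "arctan", "exp")
HIDDEN_SIZES = (1, 2, 3)

_MODEL_FORMAT = "pcptox-mlp"
_MODEL_VERSION = 1

#: guard against overflow of the exponential activation
_EXP_CLIP = 50.0


def _activation(name: str, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Value and derivative of the hidden activation, elementwise."""
    if name == "tanh":
        phi = np.tanh(a)
        return phi, 1.0 - phi**2
    if name == "arctan":
        return np.arctan(a), 1.0 / (1.0 + a**2)
    if name == "exp":
        phi = np.exp(np.minimum(a, _EXP_CLIP))
        return phi, np.where(a < _EXP_CLIP, phi, 0.0)
    raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")


def _unpack_theta(theta: np.ndarray, n_hidden: int, n_inputs: int):
    h, d = n_hidden, n_inputs
    W = theta[: h * d].reshape(h, d)
    b = theta[h * d : h * d + h]
    v = theta[h * d + h : h * d + 2 * h]
    c = theta[-1]
    return W, b, v, c


def sse_and_grad(
    theta: np.ndarray, Z: np.ndarray, y: np.ndarray, n_hidden: int, activation: str
) -> tuple[float, np.ndarray]:
    """Sum of squared errors and its analytic gradient in the packed weights.

    ``Z`` holds already-normalized inputs (one row per observation).
    """
    W, b, v, c = _unpack_theta(theta, n_hidden, Z.shape[1])
    A = Z @ W.T + b
    phi, dphi = _activation(activation, A)
    pred = phi @ v + c
    r = pred - y
    sse = float(r @ r)
    dpred = 2.0 * r
    M = (dpred[:, None] * v[None, :]) * dphi
    grad = np.concatenate([(M.T @ Z).ravel(), M.sum(axis=0), phi.T @ dpred, [dpred.sum()]])
    return sse, grad


class TinyMLPRegressor(BaseEstimator, RegressorMixin):
    """One-hidden-layer perceptron with linear output, trained by capped L-BFGS.

    Parameters
    ----------
    n_hidden : number of hidden neurons (1-3 in the study's protocol).
    activation : "tanh", "arctan" or "exp".
    n_cycles : iterative training cycles (full-batch optimizer iterations).
    random_state : seed of the weight initialization (uniform in [-0.7, 0.7]
        on normalized inputs; halved for the unbounded exp activation).
    output_bounds : optional (lo, hi) clip applied to predictions only —
        training always runs on the unclamped output.
    """

    def __init__(
        self,
        n_hidden: int = 1,
        activation: str = "tanh",
        n_cycles: int = 100,
        random_state: int | None = None,
        output_bounds: tuple[float, float] | None = None,
    ):
        self.n_hidden = n_hidden
        self.activation = activation
        self.n_cycles = n_cycles
        self.random_state = random_state
        self.output_bounds = output_bounds

    def _validate_params(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def fit(self, X, y):
        self._validate_params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree in number of rows")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("training data must be finite")

        self.input_mean_ = X.mean(axis=0)
        self.input_sd_ = X.std(axis=0)
        if np.any(self.input_sd_ == 0):
            bad = np.nonzero(self.input_sd_ == 0)[0].tolist()
            raise ValueError(f"input column(s) {bad} are constant; cannot normalize")
        Z = (X - self.input_mean_) / self.input_sd_

        h, d = self.n_hidden, X.shape[1]
        rng = np.random.default_rng(self.random_state)
        scale = 0.35 if self.activation == "exp" else 0.7
        theta0 = rng.uniform(-scale, scale, size=h * d + 2 * h + 1)

        def objective(theta):
            sse, grad = sse_and_grad(theta, Z, y, h, self.activation)
            if not np.isfinite(sse):
                return 1e25, np.zeros_like(theta)
            return sse, grad

        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.n_cycles, "maxcor": 20},
        )
        theta = res.x
        self.n_iter_ = int(res.nit)
        W, b, v, c = _unpack_theta(theta, h, d)
        self.hidden_weights_ = W
        self.hidden_biases_ = b
        self.output_weights_ = v
        self.output_bias_ = float(c)

        pred = self._raw_predict(X)
        resid = y - pred
        self.loss_ = float(resid @ resid)
        if not np.isfinite(self.loss_):
            raise FloatingPointError("training produced a non-finite loss")
        sst = float(((y - y.mean()) ** 2).sum())
        self.train_r2_ = max(0.0, 1.0 - self.loss_ / sst) if sst > 0 else 0.0
        self.train_resid_sd_ = float(resid.std(ddof=1)) if y.size > 1 else 0.0
        self.n_features_in_ = d
        return self

    def _raw_predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.input_mean_) / self.input_sd_
        A = Z @ self.hidden_weights_.T + self.hidden_biases_
        phi, _ = _activation(self.activation, A)
        return phi @ self.output_weights_ + self.output_bias_

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} input features, got {X.shape[1]}"
            )
        out = self._raw_predict(X)
        if self.output_bounds is not None:
            out = np.clip(out, *self.output_bounds)
        return out


def normalize(x, mean, sd) -> np.ndarray:
    """Centering-reduction of a raw input vector: (x - mean) / sd."""
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("normalization standard deviations must be positive")
    return (np.asarray(x, dtype=float) - np.asarray(mean, dtype=float)) / sd


def forward(model: TinyMLPRegressor, x) -> float:
    """Prediction of a fitted network for a single raw input vector."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return float(model.predict(x)[0])


@dataclass
class SearchReport:
    """All candidates of one architecture search, plus the winner."""

    report: pd.DataFrame  # one row per trained model
    best_model: TinyMLPRegressor
    best_index: int

    def __len__(self) -> int:
        return len(self.report)


def architecture_search(
    X,
    y,
    n_restarts: int = 10,
    n_cycles: int = 100,
    random_state: int = 0,
    hidden_sizes=HIDDEN_SIZES,
    activations=ACTIVATIONS,
    output_bounds: tuple[float, float] | None = None,
) -> SearchReport:
    """Train hidden-sizes x activations x restarts candidate models (default 90).

    Per-model seeds derive deterministically from ``random_state``.  Selection
    is by maximum training r-squared, ties broken by minimum residual standard
    deviation, then by enumeration order.  Restarts whose training fails
    (non-finite loss) are recorded and skipped; all restarts failing raises.
    """
    seeds = np.random.SeedSequence(random_state).generate_state(
        len(hidden_sizes) * len(activations) * n_restarts
    )
    rows = []
    models: list[TinyMLPRegressor | None] = []
    idx = 0
    for h in hidden_sizes:
        for act in activations:
            for restart in range(n_restarts):
                seed = int(seeds[idx])
                model = TinyMLPRegressor(
                    n_hidden=h,
                    activation=act,
                    n_cycles=n_cycles,
                    random_state=seed,
                    output_bounds=output_bounds,
                )
                try:
                    model.fit(X, y)
                    rows.append((h, act, restart, seed, model.train_r2_,
                                 model.train_resid_sd_, False))
                    models.append(model)
                except (FloatingPointError, np.linalg.LinAlgError):
                    rows.append((h, act, restart, seed, np.nan, np.nan, True))
                    models.append(None)
                idx += 1
    report = pd.DataFrame(
        rows,
        columns=["n_hidden", "activation", "restart", "seed", "train_r2",
                 "train_resid_sd", "failed"],
    )
    ok = report[~report["failed"]]
    if ok.empty:
        raise RuntimeError("all training restarts failed")
    best_index = int(
        ok.sort_values(
            ["train_r2", "train_resid_sd"], ascending=[False, True], kind="stable"
        ).index[0]
    )
    return SearchReport(report=report, best_model=models[best_index], best_index=best_index)


class MLPArchitectureSearch(BaseEstimator, RegressorMixin):
    """Estimator facade over :func:`architecture_search`.

    ``fit`` trains the full candidate grid and exposes the winner as
    ``best_model_`` (with ``report_`` holding every candidate's scores);
    ``predict`` delegates to the winner.
    """

    def __init__(
        self,
        n_restarts: int = 10,
        n_cycles: int = 100,
        random_state: int = 0,
        output_bounds: tuple[float, float] | None = None,
    ):
        self.n_restarts = n_restarts
        self.n_cycles = n_cycles
        self.random_state = random_state
        self.output_bounds = output_bounds

    def fit(self, X, y):
        result = architecture_search(
            X,
            y,
            n_restarts=self.n_restarts,
            n_cycles=self.n_cycles,
            random_state=self.random_state,
            output_bounds=self.output_bounds,
        )
        self.report_ = result.report
        self.best_model_ = result.best_model
        self.train_r2_ = result.best_model.train_r2_
        return self

    def predict(self, X):
        return self.best_model_.predict(X)


def save_model(model: TinyMLPRegressor, path) -> None:
    """Write a fitted model as versioned structured text (JSON)."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "architecture": {
            "n_inputs": int(model.n_features_in_),
            "n_hidden": int(model.n_hidden),
            "activation": model.activation,
        },
        "normalization": {
            "mean": model.input_mean_.tolist(),
            "sd": model.input_sd_.tolist(),
        },
        "weights": {
            "hidden_weights": model.hidden_weights_.tolist(),
            "hidden_biases": model.hidden_biases_.tolist(),
            "output_weights": model.output_weights_.tolist(),
            "output_bias": model.output_bias_,
        },
        "scores": {
            "train_r2": model.train_r2_,
            "train_resid_sd": model.train_resid_sd_,
        },
        "output_bounds": list(model.output_bounds) if model.output_bounds else None,
        "random_state": model.random_state,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> TinyMLPRegressor:
    """Read a model written by :func:`save_model`; round-trips predictions exactly."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model file {path}: {exc}") from exc
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a {_MODEL_FORMAT} model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('version')} "
            f"(expected {_MODEL_VERSION})"
        )
    arch = payload["architecture"]
    bounds = payload.get("output_bounds")
    model = TinyMLPRegressor(
        n_hidden=arch["n_hidden"],
        activation=arch["activation"],
        random_state=payload.get("random_state"),
        output_bounds=tuple(bounds) if bounds else None,
    )
    model.input_mean_ = np.array(payload["normalization"]["mean"], dtype=float)
    model.input_sd_ = np.array(payload["normalization"]["sd"], dtype=float)
    w = payload["weights"]
    model.hidden_weights_ = np.array(w["hidden_weights"], dtype=float)
    model.hidden_biases_ = np.array(w["hidden_biases"], dtype=float)
    model.output_weights_ = np.array(w["output_weights"], dtype=float)
    model.output_bias_ = float(w["output_bias"])
    model.train_r2_ = float(payload["scores"]["train_r2"])
    model.train_resid_sd_ = float(payload["scores"]["train_resid_sd"])
    model.n_features_in_ = int(arch["n_inputs"])
    return model
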