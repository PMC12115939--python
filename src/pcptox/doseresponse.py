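"""Hill and Weibull concentration-response estimators and EC50 tables.

Both models map PCP concentration (mg/L) to an inhibition fraction with a
fixed maximum of 1 (full respiratory arrest is reached at the top of the
tested range) and a fixed 0 at zero dose:

* Hill:    ``INH(C) = C^n / (EC50^n + C^n)``
* Weibull: ``INH(C) = 1 - exp(-(C/lambda)^k)``, with ``EC50 = lambda * ln(2)^(1/k)``

Each estimator is least-squares fit on the linear concentration scale with a
deterministic multi-start (log-spaced EC50-scale starts crossed with shape
starts).  Per abiotic combination the model with the larger r-squared between
observed and fitted inhibitions is retained; ties go to Hill.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

ABIOTIC_KEYS = ["ph", "temperature_c", "conductivity_ms_cm"]

EC50_COLUMNS = ABIOTIC_KEYS + ["model_name", "ec50_mg_l", "param1", "param2", "r2", "selected"]

_SHAPE_STARTS = (0.5, 1.0, 2.0)
_N_SCALE_STARTS = 5


def _fit_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation of observed and fitted values."""
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


class _DoseResponseCurve(BaseEstimator, RegressorMixin):
    """Shared multi-start least-squares machinery of the two curve families."""

    #: subclasses set: model_name, parameter names
    model_name: str = ""

    def __init__(self, max_nfev: int = 500):
        self.max_nfev = max_nfev

    # subclass hooks -------------------------------------------------
    def _curve(self, conc: np.ndarray, log_scale: float, log_shape: float) -> np.ndarray:
        raise NotImplementedError

    def _unpack(self, log_scale: float, log_shape: float) -> dict:
        raise NotImplementedError

    # ----------------------------------------------------------------
    @staticmethod
    def _validate(X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        inh = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != inh.shape:
            raise ValueError("concentrations and inhibitions differ in length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        levels = np.unique(conc)
        if levels.size < 4 or 0.0 not in levels:
            raise ValueError("need >= 4 concentration levels including 0")
        return conc, inh

    def fit(self, X, y):
        """Fit the curve to (concentration, inhibition) data.

        Sets ``converged_`` False (and leaves parameters at the best attempt)
        when the response carries no usable dose information — essentially
        constant, or no measurable effect anywhere.
        """
        conc, inh = self._validate(X, y)
        self.n_obs_ = conc.size

        degenerate = np.std(inh) < 1e-9 or float(np.max(inh)) < 1e-6
        pos = conc[conc > 0]
        scale_starts = np.linspace(
            math.log10(pos.min()), math.log10(pos.max()), _N_SCALE_STARTS
        )

        best = None
        for ls0 in scale_starts:
            for s0 in _SHAPE_STARTS:
                res = least_squares(
                    lambda th: self._curve(conc, th[0], th[1]) - inh,
                    x0=[ls0, math.log(s0)],
                    max_nfev=self.max_nfev,
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
                sse = float(2.0 * res.cost)
                if best is None or sse < best[0] - 1e-15:
                    best = (sse, res.x)
        sse, theta = best
        self.sse_ = sse
        fitted = self._curve(conc, theta[0], theta[1])
        self.r2_ = _fit_r2(inh, fitted)
        params = self._unpack(theta[0], theta[1])
        for name, val in params.items():
            setattr(self, name, val)
        self.converged_ = bool(
            not degenerate and np.isfinite(sse) and 1e-6 < self.ec50_ < 1e8
        )
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self._curve(conc, self._log_scale_, self._log_shape_)


class HillCurve(_DoseResponseCurve):
    """Two-parameter Hill curve; fitted attributes ``ec50_`` (mg/L) and ``n_``."""

    model_name = "hill"

    def _curve(self, conc, log_scale, log_shape):
        ec50 = 10.0**log_scale
        n = math.exp(log_shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(conc > 0, (conc / ec50) ** n, 0.0)
        return ratio / (1.0 + ratio)

    def _unpack(self, log_scale, log_shape):
        self._log_scale_, self._log_shape_ = log_scale, log_shape
        return {"ec50_": 10.0**log_scale, "n_": math.exp(log_shape)}

    @property
    def params_(self) -> tuple[float, float]:
        return (self.ec50_, self.n_)


class WeibullCurve(_DoseResponseCurve):
    """Two-parameter Weibull curve; fitted ``lambda_`` (mg/L scale), ``k_``,
    and the derived ``ec50_ = lambda * ln(2)^(1/k)``."""

    model_name = "weibull"

    def _curve(self, conc, log_scale, log_shape):
        lam = 10.0**log_scale
        k = math.exp(log_shape)
        return 1.0 - np.exp(-((conc / lam) ** k))

    def _unpack(self, log_scale, log_shape):
        self._log_scale_, self._log_shape_ = log_scale, log_shape
        lam = 10.0**log_scale
        k = math.exp(log_shape)
        return {"lambda_": lam, "k_": k, "ec50_": lam * math.log(2.0) ** (1.0 / k)}

    @property
    def params_(self) -> tuple[float, float]:
        return (self.lambda_, self.k_)


def fit_hill(concs, inhibitions) -> HillCurve:
    return HillCurve().fit(concs, inhibitions)


def fit_weibull(concs, inhibitions) -> WeibullCurve:
    return WeibullCurve().fit(concs, inhibitions)


def select_best_model(hill_fit: HillCurve, weibull_fit: WeibullCurve):
    """Return the converged fit with the larger r-squared; ties go to Hill."""
    h_ok = getattr(hill_fit, "converged_", False)
    w_ok = getattr(weibull_fit, "converged_", False)
    if not h_ok and not w_ok:
        raise ValueError("neither dose-response model converged")
    if h_ok and not w_ok:
        return hill_fit
    if w_ok and not h_ok:
        return weibull_fit
    return weibull_fit if weibull_fit.r2_ > hill_fit.r2_ else hill_fit


def ec50_table(inhibition_df: pd.DataFrame) -> pd.DataFrame:
    """Fit both curve families per abiotic combination and select the better.

    Expects the inhibition table (exposed wells only); zero-dose points with
    inhibition 0 are appended per replicate, since controls define the scale.
    Returns one row per (combination, model) with a ``selected`` flag —
    exactly one selected row per combination.
    """
    rows = []
    for key, grp in inhibition_df.groupby(ABIOTIC_KEYS, sort=True):
        n_zero = max(1, int(grp["replicate"].nunique()))
        conc = np.concatenate([np.zeros(n_zero), grp["pcp_mg_l"].to_numpy(float)])
        inh = np.concatenate([np.zeros(n_zero), grp["inhibition"].to_numpy(float)])
        try:
            hill = fit_hill(conc, inh)
            weib = fit_weibull(conc, inh)
            chosen = select_best_model(hill, weib)
        except ValueError as exc:
            raise ValueError(
                f"dose-response fit failed at (pH {key[0]}, {key[1]} C, "
                f"{key[2]} mS/cm): {exc}"
            ) from exc
        for fit in (hill, weib):
            rows.append(
                (*key, fit.model_name, fit.ec50_, *fit.params_, fit.r2_, fit is chosen)
            )
    return pd.DataFrame(rows, columns=EC50_COLUMNS)


def selected_ec50s(table: pd.DataFrame) -> pd.DataFrame:
    """The selected fit per abiotic combination from an :func:`ec50_table` result."""
    return table[table["selected"]].reset_index(drop=True)
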