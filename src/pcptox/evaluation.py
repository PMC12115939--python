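"""Factor screening, condition averaging, r-squared and held-out validation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mlp import TinyMLPRegressor

ABIOTIC_KEYS = ["ph", "temperature_c", "conductivity_ms_cm"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-distribution p-value.

    Requires at least 4 paired observations and non-constant vectors (the
    rank correlation of a constant vector is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class FactorScreeningResult:
    """Spearman screening of each abiotic factor against a response."""

    table: pd.DataFrame  # factor, rho, p_value, significant
    alpha: float

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["significant"], "factor"].tolist()

    @property
    def excluded(self) -> list[str]:
        return self.table.loc[~self.table["significant"], "factor"].tolist()


def screen_factors(
    df: pd.DataFrame,
    response: str,
    factors: list[str] | None = None,
    alpha: float = 0.05,
) -> FactorScreeningResult:
    """Test each factor against the response by Spearman correlation.

    Factors whose p-value reaches ``alpha`` are retained; the rest are flagged
    for exclusion (their conditions may be averaged over).  No multiplicity
    correction is applied across the factor tests.
    """
    if factors is None:
        factors = ABIOTIC_KEYS
    rows = []
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        rho, p = spearman(df[f], df[response])
        rows.append((f, rho, p, p < alpha))
    table = pd.DataFrame(rows, columns=["factor", "rho", "p_value", "significant"])
    return FactorScreeningResult(table=table, alpha=alpha)


def average_over_factor(
    df: pd.DataFrame, factor: str, response: str, extra_keys: list[str] | None = None
) -> pd.DataFrame:
    """Average the response over a screened-out factor.

    Groups by the remaining abiotic keys (plus any extra keys such as dose)
    and returns the group mean with an ``n`` replicate-bookkeeping column.
    """
    keys = [k for k in ABIOTIC_KEYS if k != factor and k in df.columns]
    if extra_keys:
        keys += [k for k in extra_keys if k in df.columns]
    out = (
        df.groupby(keys, sort=True)[response]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": response, "count": "n"})
    )
    return out


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted differ in length")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("r-squared undefined for a constant vector")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def r_squared_residual(observed, predicted) -> float:
    """1 - SSE/SST; the residual-based companion of :func:`r_squared`."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("residual r-squared undefined for constant observations")
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


@dataclass
class ValidationReport:
    """Held-out performance of a fitted effect model."""

    table: pd.DataFrame  # per-row observed and predicted inhibition
    r2: float  # squared Pearson correlation (headline)
    r2_residual: float  # 1 - SSE/SST companion
    prediction_band: pd.DataFrame | None = None  # 95% band of pred-vs-obs line


def prediction_band(observed, predicted, level: float = 0.95) -> pd.DataFrame:
    """Prediction interval of the simple regression of predicted on observed."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    slope, intercept = np.polyfit(obs, pred, 1)
    fitted = intercept + slope * obs
    s = np.sqrt(((pred - fitted) ** 2).sum() / (n - 2))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    xbar = obs.mean()
    sxx = ((obs - xbar) ** 2).sum()
    grid = np.linspace(obs.min(), obs.max(), 50)
    half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (grid - xbar) ** 2 / sxx)
    centre = intercept + slope * grid
    return pd.DataFrame(
        {"observed": grid, "fit": centre, "lower": centre - half, "upper": centre + half}
    )


def validate(
    model: TinyMLPRegressor,
    validation_df: pd.DataFrame,
    training_abiotics: set[tuple] | None = None,
    feature_cols: list[str] | None = None,
    response: str = "inhibition",
    with_band: bool = False,
) -> ValidationReport:
    """Score a fitted effect model on held-out conditions.

    If ``training_abiotics`` is given, any overlap between training and
    validation abiotic combinations raises — validation must be on novel
    conditions only.
    """
    if feature_cols is None:
        feature_cols = ABIOTIC_KEYS + ["pcp_mg_l"]
    if training_abiotics is not None:
        val_abiotics = {
            tuple(row) for row in validation_df[ABIOTIC_KEYS].drop_duplicates().to_numpy()
        }
        overlap = val_abiotics & set(training_abiotics)
        if overlap:
            raise ValueError(
                f"validation abiotic combinations overlap the training set: {sorted(overlap)[:5]}"
            )
    X = validation_df[feature_cols].to_numpy(float)
    obs = validation_df[response].to_numpy(float)
    pred = model.predict(X)
    table = validation_df[feature_cols + ["replicate"] if "replicate" in validation_df
                          else feature_cols].copy()
    table["observed"] = obs
    table["predicted"] = pred
    band = prediction_band(obs, pred) if with_band else None
    return ValidationReport(
        table=table,
        r2=r_squared(obs, pred),
        r2_residual=r_squared_residual(obs, pred),
        prediction_band=band,
    )
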