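"""Cell-count regression on morphological coverage, and flask variability.

Coverage alone (a confluence analogue) predicts cell number only
roughly, because the morphological zones differ strongly in cell
density: the dark central core packs far more cells per unit area than
the spread edge.  Regressing counts on the three per-class coverages
separately therefore improves the fit and yields density-ordered
coefficients (core > periphery > edge).  The flask statistics quantify
the competing sacrificial strategy: with flask-to-flask coefficient of
variation CV, predicting batch yield from m sacrificed units carries a
95% interval of +/- 1.96*CV/sqrt(m) of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z95 = 1.96


@dataclass
class RegressionFit:
    """An OLS fit of cell count on coverage predictor(s)."""

    params: pd.Series  # intercept ('const') + per-predictor coefficients
    bse: pd.Series  # standard errors
    r_squared_pct: float
    adj_r_squared_pct: float
    residual_sd: float
    n: int
    predictor_names: tuple[str, ...]
    _model: object = None  # fitted statsmodels results, for prediction
    _x_range: dict | None = None

    def __repr__(self) -> str:  # keep the statsmodels object out of repr
        return (
            f"RegressionFit(n={self.n}, R2={self.r_squared_pct:.1f}%, "
            f"predictors={self.predictor_names})"
        )


def _fit_ols(X: pd.DataFrame, y: np.ndarray) -> RegressionFit:
    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        r_squared_pct=100.0 * float(res.rsquared),
        adj_r_squared_pct=100.0 * float(res.rsquared_adj),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        n=len(y),
        predictor_names=tuple(X.columns),
        _model=res,
        _x_range={c: (float(X[c].min()), float(X[c].max())) for c in X.columns},
    )


def fit_single(total_coverage_pct, counts) -> RegressionFit:
    """OLS of cell count on total (non-background) coverage %."""
    x = np.asarray(total_coverage_pct, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched (coverage, count) pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the coverage predictor")
    return _fit_ols(pd.DataFrame({"total_pct": x}), y)


def fit_multi(edge_pct, periphery_pct, core_pct, counts) -> RegressionFit:
    """OLS of cell count on the three per-class coverages.

    The design must be full rank; a rank-deficient design raises with the
    collinear predictor set named.
    """
    X = pd.DataFrame(
        {
            "edge_pct": np.asarray(edge_pct, dtype=float),
            "periphery_pct": np.asarray(periphery_pct, dtype=float),
            "core_pct": np.asarray(core_pct, dtype=float),
        }
    )
    y = np.asarray(counts, dtype=float)
    if len(X) != y.size or len(X) < 5:
        raise ValueError("need >= 5 matched (coverage, count) rows")
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        degenerate = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
        if not degenerate:
            corr = X.corr().abs()
            degenerate = sorted(
                {
                    name
                    for i, a in enumerate(X.columns)
                    for b in X.columns[i + 1 :]
                    if corr.loc[a, b] > 1 - 1e-10
                    for name in (a, b)
                }
            ) or list(X.columns)
        raise ValueError(f"rank-deficient design; collinear predictors: {degenerate}")
    return _fit_ols(X, y)


def predict_count(fit: RegressionFit, coverages: dict) -> dict:
    """Point prediction with a 95% OLS prediction interval.

    ``coverages`` maps predictor names to values.  Predictions outside
    the training range of any predictor are flagged as extrapolation.
    """
    if fit._model is None:
        raise ValueError("model has not been fitted")
    missing = [p for p in fit.predictor_names if p not in coverages]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    row = pd.DataFrame({p: [float(coverages[p])] for p in fit.predictor_names})
    design = sm.add_constant(row, has_constant="add")
    pred = fit._model.get_prediction(design)
    frame = pred.summary_frame(alpha=0.05)
    extrapolating = any(
        not (fit._x_range[p][0] <= float(coverages[p]) <= fit._x_range[p][1])
        for p in fit.predictor_names
    )
    return {
        "estimate": float(frame["mean"].iloc[0]),
        "pi_low": float(frame["obs_ci_lower"].iloc[0]),
        "pi_high": float(frame["obs_ci_upper"].iloc[0]),
        "extrapolation": extrapolating,
    }


@dataclass
class FlaskStats:
    """Flask-to-flask count variability and m-unit sampling intervals."""

    n_flasks: int
    mean_count: float
    sd_count: float
    cv: float
    halfwidth_pct_of_mean: pd.Series  # indexed by m = 1..n_flasks


def flask_cv(counts_per_flask) -> FlaskStats:
    """CV of sacrificial counts and the 95% half-width (as % of the batch
    mean) when estimating yield from m sacrificed flasks, m = 1..n."""
    counts = np.asarray(counts_per_flask, dtype=float)
    if counts.size < 2:
        raise ValueError("need counts from >= 2 flasks")
    mean = float(counts.mean())
    if mean <= 0:
        raise ValueError("mean count must be positive")
    sd = float(counts.std(ddof=1))
    cv = sd / mean
    m = np.arange(1, counts.size + 1)
    half = pd.Series(100.0 * Z95 * cv / np.sqrt(m), index=m, name="halfwidth_pct")
    return FlaskStats(
        n_flasks=counts.size,
        mean_count=mean,
        sd_count=sd,
        cv=cv,
        halfwidth_pct_of_mean=half,
    )
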