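"""Parameter estimation from field-style data.

Three estimators feed the simulator's parameters:

* ``alpha_mle`` — the exponential dispersal kernel's rate from observed
  inter-patch movement distances: the MLE is the reciprocal of the mean
  distance travelled.
* ``rd_from_lambda`` — low-density growth rate from a finite rate of
  increase: r_d = ln(lambda).
* ``fit_k_volume`` — the K_volume density proxy as the slope of a
  least-squares regression of patch counts on habitat volume
  (depth x area), constrained through the origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["alpha_mle", "rd_from_lambda", "fit_k_volume", "compare_k_models"]


def alpha_mle(distances) -> float:
    """MLE of the exponential-kernel rate: 1 / mean(distances), in 1/m.

    Distances must be positive inter-patch movement lengths in meters.
    Outlier handling is the caller's responsibility.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("distances must be nonempty")
    if np.any(d <= 0) or np.any(~np.isfinite(d)):
        raise ValueError("distances must be positive and finite")
    return float(1.0 / d.mean())


def rd_from_lambda(lam: float) -> float:
    """r_d = ln(lambda) for a finite rate of increase lambda > 0."""
    if lam <= 0:
        raise ValueError(f"finite rate of increase must be > 0, got {lam}")
    return float(np.log(lam))


def fit_k_volume(n_values, volumes) -> dict:
    """Through-origin regression N = K_volume * volume + error.

    Returns the slope (voles per cm x ha) and the no-intercept R^2
    (uncentered).  The closed form is slope = sum(N*V) / sum(V^2); the fit
    is delegated to OLS without a constant, which computes exactly that.
    """
    n = np.asarray(n_values, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if n.shape != v.shape or n.size < 2:
        raise ValueError("n_values and volumes must be equal-length with >= 2 points")
    if np.allclose(v, 0.0):
        raise ValueError("volumes must not be all zero")
    res = sm.OLS(n, v).fit()
    return {"slope": float(res.params[0]), "r_squared": float(res.rsquared)}


def compare_k_models(n_values, predictors: dict) -> pd.DataFrame:
    """Through-origin fits of N on each candidate predictor set, with AIC.

    ``predictors`` maps a model name to a 1-D array or a dict of named
    columns; rows are sorted by AIC so the first row is the preferred
    (most parsimonious well-fitting) model.
    """
    n = np.asarray(n_values, dtype=float)
    rows = []
    for name, cols in predictors.items():
        if isinstance(cols, dict):
            x = np.column_stack([np.asarray(c, dtype=float) for c in cols.values()])
        else:
            x = np.asarray(cols, dtype=float).reshape(len(n), -1)
        res = sm.OLS(n, x).fit()
        rows.append(
            {
                "model": name,
                "r_squared": float(res.rsquared),
                "aic": float(res.aic),
                "n_predictors": x.shape[1],
            }
        )
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
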