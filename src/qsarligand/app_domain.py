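"""Leverage-based applicability domain: hat values, the h* threshold,
Williams-plot data (leverage vs standardized residual) and Insubria-plot
data (leverage vs predicted value for compounds without activities).

The leverage of a query descriptor vector x (augmented with an intercept 1)
against the training design X is h = x^T (X^T X)^-1 x; for training rows
this is the hat-matrix diagonal, whose trace equals k + 1. The warning
threshold is h* = 3 (k + 1) / n. Residual outliers are flagged beyond a
configurable sigma band (default 2.5 standard deviation units).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import MLRModel, predict

__all__ = [
    "leverages",
    "leverage_threshold",
    "williams_data",
    "insubria_data",
]

SIGMA_LIMIT = 2.5


def _augment(X: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"missing descriptor columns: {missing}")
    return np.column_stack([np.ones(len(X)), X[list(names)].to_numpy(float)])


def leverages(
    X_train: pd.DataFrame, X_query: Optional[pd.DataFrame] = None
) -> np.ndarray:
    """Leverage of each query row against the training design (with
    intercept). With no query, returns the training hat-matrix diagonal."""
    names = list(X_train.columns)
    A = _augment(X_train, names)
    xtx = A.T @ A
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise ValueError("singular X^T X: training design is rank deficient")
    xtx_inv = np.linalg.inv(xtx)
    Q = A if X_query is None else _augment(X_query, names)
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def leverage_threshold(k: int, n: int) -> float:
    """Warning leverage h* = 3 (k + 1) / n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (k + 1) / n


def williams_data(
    model: MLRModel,
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_test: Optional[pd.DataFrame] = None,
    y_test: Optional[Sequence[float]] = None,
    sigma_limit: float = SIGMA_LIMIT,
) -> pd.DataFrame:
    """Williams-plot table: leverage, standardized residual and flags.

    Residuals are standardized by their own set's RMSE (training rows by the
    training RMSE, test rows by the external RMSE). Flags mark |residual|
    beyond the sigma band or leverage above h* = 3(k+1)/n_train.
    """
    h_star = leverage_threshold(model.k, len(X_train))
    frames = []
    for X, y, tag in ((X_train, y_train, "train"), (X_test, y_test, "test")):
        if X is None or y is None:
            continue
        y = np.asarray(y, float)
        resid = y - predict(model, X)
        rmse = float(np.sqrt((resid**2).mean()))
        std_resid = resid / rmse if rmse > 0 else np.zeros_like(resid)
        h = leverages(X_train, None if tag == "train" else X)
        frames.append(
            pd.DataFrame(
                {
                    "id": [str(i) for i in X.index],
                    "leverage": h,
                    "std_residual": std_resid,
                    "set": tag,
                    "high_leverage": h > h_star,
                    "residual_outlier": np.abs(std_resid) > sigma_limit,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["h_star"] = h_star
    out.attrs["sigma_limit"] = sigma_limit
    return out


def insubria_data(
    model: MLRModel, X_train: pd.DataFrame, X_new: pd.DataFrame
) -> pd.DataFrame:
    """Insubria-plot table for compounds without experimental activities:
    leverage, predicted pIC50 and the in-domain flag (h <= h*)."""
    h_star = leverage_threshold(model.k, len(X_train))
    h = leverages(X_train, X_new)
    out = pd.DataFrame(
        {
            "id": [str(i) for i in X_new.index],
            "leverage": h,
            "predicted_pic50": predict(model, X_new),
            "in_domain": h <= h_star,
        }
    )
    out.attrs["h_star"] = h_star
    return out
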