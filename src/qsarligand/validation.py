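"""Fit, internal-validation and external-validation statistics for MLR
QSAR models.

Fit block: R^2, adjusted R^2, RMSE, MAE, standard error of estimate s,
F statistic, Friedman's lack-of-fit, and Lin's concordance correlation
coefficient. Internal validation: leave-one-out and leave-many-out
cross-validation and response scrambling (y-randomization). External
validation: PRESS/RMSE/MAE on the held-out set, R^2_ext, the predictive
coefficients Q^2_F1 (training-mean reference), Q^2_F2 (test-mean reference)
and Q^2_F3 (per-compound training variance reference), CCC_ext, and the
origin-forced r^2_m agreement metrics averaged over both regression
directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import MLRModel, fit_mlr, predict, loo_q2_ols

__all__ = [
    "FitStats",
    "ValidationReport",
    "fit_statistics",
    "concordance_ccc",
    "loo_cv",
    "lmo_cv",
    "y_scramble",
    "external_validation",
    "rm2_metrics",
    "f_from_r2",
    "s_from_rmse",
    "rmse_from_press",
    "validate_model",
]


def concordance_ccc(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (biased 1/n moments)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    my, mp = y.mean(), yhat.mean()
    sy = ((y - my) ** 2).mean()
    sp = ((yhat - mp) ** 2).mean()
    cov = ((y - my) * (yhat - mp)).mean()
    return float(2 * cov / (sy + sp + (my - mp) ** 2))


def f_from_r2(r2: float, n: int, k: int) -> float:
    """F statistic implied by R^2 with k regressors and n observations."""
    if r2 >= 1.0:
        return math.inf
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def s_from_rmse(rmse: float, n: int, k: int) -> float:
    """Standard error of estimate implied by the training RMSE:
    s = sqrt(n * RMSE^2 / (n - k - 1))."""
    return math.sqrt(n * rmse**2 / (n - k - 1))


def rmse_from_press(press: float, n: int) -> float:
    """RMSE implied by a predictive residual sum of squares over n points."""
    return math.sqrt(press / n)


@dataclass
class FitStats:
    r2: float
    r2_adj: float
    rmse: float
    mae: float
    s: float
    f_stat: float
    lof: float
    ccc: float
    n: int
    k: int


def fit_statistics(
    y: Sequence[float], yhat: Sequence[float], k: int, lof_smoothing: float = 0.5
) -> FitStats:
    """Training-fit statistics from observed and fitted responses.

    LOF is Friedman's lack-of-fit (RSS/n) / (1 - (k + 1 + d*k)/n)^2 with
    smoothing d (default 0.5); the smoothing parameter is a reporting
    convention, not a validated quantity.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = len(y)
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("zero-variance response")
    rss = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    rmse = math.sqrt(rss / n)
    mae = float(np.abs(y - yhat).mean())
    s = math.sqrt(rss / (n - k - 1))
    f_stat = f_from_r2(r2, n, k)
    lof_denom = (1.0 - (k + 1 + lof_smoothing * k) / n) ** 2
    lof = (rss / n) / lof_denom
    return FitStats(r2, r2_adj, rmse, mae, s, f_stat, lof, concordance_ccc(y, yhat), n, k)


def _default_fitter(X: pd.DataFrame, y: np.ndarray) -> MLRModel:
    return fit_mlr(X, y)


def loo_cv(
    X: pd.DataFrame,
    y: Sequence[float],
    fitter: Callable[[pd.DataFrame, np.ndarray], MLRModel] = _default_fitter,
) -> dict[str, float]:
    """Leave-one-out cross-validation with explicit refits.

    Each point is predicted by a model trained without it; Q^2_LOO =
    1 - PRESS/TSS. For plain OLS the result equals the hat-matrix shortcut
    e_i/(1 - h_ii) to machine precision.
    """
    y = np.asarray(y, float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            model = fitter(X.iloc[mask], y[mask])
        except ValueError as exc:
            raise ValueError(f"LOO sub-fit failed leaving out index {i}: {exc}") from exc
        preds[i] = predict(model, X.iloc[[i]])[0]
    press = float(((y - preds) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return {
        "q2_loo": 1.0 - press / tss,
        "press_cv": press,
        "rmse_cv": math.sqrt(press / n),
        "mae_cv": float(np.abs(y - preds).mean()),
        "ccc_cv": concordance_ccc(y, preds),
    }


def lmo_cv(
    X: pd.DataFrame,
    y: Sequence[float],
    fraction: float = 0.30,
    iters: int = 2000,
    seed: int = 0,
) -> dict[str, object]:
    """Leave-many-out cross-validation: per iteration a random ``fraction``
    of the training compounds is held out, the model refit on the rest, and
    the held-out squared errors accumulated. The headline Q^2_LMO pools
    PRESS and TSS over all iterations (1 - sum PRESS / sum TSS, deviations
    about the retained subset's mean), which is stable for small held-out
    blocks and converges to the LOO value as the fraction shrinks to 1/n;
    the per-iteration Q^2 distribution is returned alongside."""
    y = np.asarray(y, float)
    n = len(y)
    n_out = max(1, int(round(fraction * n)))
    if n - n_out <= X.shape[1] + 1:
        raise ValueError("too few retained compounds to refit")
    rng = np.random.default_rng(seed)
    q2s = []
    press_total = tss_total = 0.0
    skipped = 0
    for _ in range(iters):
        out_idx = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out_idx] = False
        try:
            model = fitter_safe(X, y, mask)
        except ValueError:
            skipped += 1
            continue
        preds = predict(model, X.iloc[out_idx])
        press = ((y[out_idx] - preds) ** 2).sum()
        tss = ((y[out_idx] - y[mask].mean()) ** 2).sum()
        if tss == 0:
            skipped += 1
            continue
        press_total += press
        tss_total += tss
        q2s.append(1.0 - press / tss)
    return {
        "q2_lmo": float(1.0 - press_total / tss_total),
        "distribution": np.asarray(q2s),
        "skipped": skipped,
    }


def fitter_safe(X: pd.DataFrame, y: np.ndarray, mask: np.ndarray) -> MLRModel:
    return fit_mlr(X.iloc[mask], y[mask])


def y_scramble(
    X: pd.DataFrame, y: Sequence[float], iters: int = 2000, seed: int = 0
) -> dict[str, float]:
    """Response scrambling: refit after random permutations of y.

    Reports the mean R^2 and mean leave-one-out Q^2 of the scrambled models
    and the average scrambled RMSE. A real structure-activity signal shows
    up as scrambled means far below the true-model statistics (and Q^2
    typically negative)."""
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    names = list(X.columns)
    A = np.column_stack([np.ones(len(X)), X[names].to_numpy(float)])
    h = np.einsum("ij,ji->i", A, np.linalg.pinv(A))
    r2s, q2s, rmses = [], [], []
    n = len(y)
    for _ in range(iters):
        ys = rng.permutation(y)
        beta, *_ = np.linalg.lstsq(A, ys, rcond=None)
        resid = ys - A @ beta
        tss = ((ys - ys.mean()) ** 2).sum()
        rss = resid @ resid
        r2s.append(1.0 - rss / tss)
        press = ((resid / (1.0 - h)) ** 2).sum()
        q2s.append(1.0 - press / tss)
        rmses.append(math.sqrt(rss / n))
    return {
        "r2_yscr": float(np.mean(r2s)),
        "q2_yscr": float(np.mean(q2s)),
        "rmse_av_yscr": float(np.mean(rmses)),
    }


def rm2_metrics(y_obs: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """Origin-forced r^2_m agreement metrics in both regression directions.

    r^2_m = r^2 * (1 - sqrt(r^2 - r0^2)) where r0^2 comes from the
    zero-intercept regression; computed observed-vs-predicted and
    predicted-vs-observed, then averaged and differenced."""

    def one_direction(a: np.ndarray, b: np.ndarray) -> float:
        # a regressed on b: r0^2 from slope k = sum(ab)/sum(b^2)
        if a.std() == 0 or b.std() == 0:
            return float("nan")  # agreement undefined for constant series
        r = np.corrcoef(a, b)[0, 1]
        r2 = r**2
        kslope = float((a * b).sum() / (b * b).sum())
        r0_2 = 1.0 - float(((a - kslope * b) ** 2).sum() / ((a - a.mean()) ** 2).sum())
        inner = max(r2 - r0_2, 0.0)
        return r2 * (1.0 - math.sqrt(inner))

    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    rm2_fwd = one_direction(y_obs, y_pred)
    rm2_rev = one_direction(y_pred, y_obs)
    return {
        "rm2_aver": (rm2_fwd + rm2_rev) / 2.0,
        "rm2_delta": abs(rm2_fwd - rm2_rev),
    }


def external_validation(
    model: MLRModel, X_ext: pd.DataFrame, y_ext: Sequence[float]
) -> dict[str, float]:
    """External-set predictivity statistics for a fitted model.

    Q^2_F1 references the training mean, Q^2_F2 the external mean, and
    Q^2_F3 the per-compound training variance (TSS_tr/n_tr); the model must
    carry its training mean and TSS. Q^2_F2 <= Q^2_F1 always.
    """
    y_ext = np.asarray(y_ext, float)
    n_ext = len(y_ext)
    if n_ext < 3:
        raise ValueError("need at least 3 external compounds")
    if model.y_mean_train is None or model.tss_train is None or not model.n_train:
        raise ValueError("model lacks training metadata (y_mean_train/tss_train)")
    preds = predict(model, X_ext)
    press = float(((y_ext - preds) ** 2).sum())
    r = (
        np.corrcoef(y_ext, preds)[0, 1]
        if preds.std() > 0 and y_ext.std() > 0
        else float("nan")
    )
    out = {
        "press_ext": press,
        "rmse_ext": math.sqrt(press / n_ext),
        "mae_ext": float(np.abs(y_ext - preds).mean()),
        "r2_ext": float(r**2),
        "q2_f1": 1.0 - press / float(((y_ext - model.y_mean_train) ** 2).sum()),
        "q2_f2": 1.0 - press / float(((y_ext - y_ext.mean()) ** 2).sum()),
        "q2_f3": 1.0 - (press / n_ext) / (model.tss_train / model.n_train),
        "ccc_ext": concordance_ccc(y_ext, preds),
    }
    out.update(rm2_metrics(y_ext, preds))
    return out


@dataclass
class ValidationReport:
    """Full fit/internal/external validation bundle for one model."""

    fit: FitStats
    internal: dict[str, float] = field(default_factory=dict)
    external: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fit": asdict(self.fit),
            "internal": {k: v for k, v in self.internal.items() if np.isscalar(v)},
            "external": dict(self.external),
        }


def validate_model(
    X_train: pd.DataFrame,
    y_train: Sequence[float],
    X_ext: Optional[pd.DataFrame] = None,
    y_ext: Optional[Sequence[float]] = None,
    lmo_iters: int = 2000,
    yscr_iters: int = 2000,
    seed: int = 0,
) -> tuple[MLRModel, ValidationReport]:
    """Fit an MLR model and assemble the complete validation report."""
    y_train = np.asarray(y_train, float)
    model = fit_mlr(X_train, y_train)
    yhat = predict(model, X_train)
    fit = fit_statistics(y_train, yhat, k=model.k)
    internal: dict[str, float] = {}
    internal.update(loo_cv(X_train, y_train))
    lmo = lmo_cv(X_train, y_train, iters=lmo_iters, seed=seed)
    internal["q2_lmo"] = lmo["q2_lmo"]
    internal.update(y_scramble(X_train, y_train, iters=yscr_iters, seed=seed + 1))
    external: dict[str, float] = {}
    if X_ext is not None and y_ext is not None:
        external = external_validation(model, X_ext, y_ext)
    return model, ValidationReport(fit=fit, internal=internal, external=external)
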