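"""Regression metrics and the general-solubility-equation consistency audit.

Metrics are the coefficient of determination r² (1 − SS_res/SS_tot, which
can be negative for models worse than the mean predictor — deliberately
*not* the squared Pearson correlation), Spearman's rho, Pearson's r and
RMSE.  Cross-validation reports average the per-fold values; folds are
never pooled.

The general solubility equation (Yalkowsky) links aqueous solubility to
melting point and the octanol-water partition coefficient:

    logSw = −0.01 (LMP − 25) − log10(Kow) + 0.5

with logSw in log10 mol/L and LMP in °C.  The consistency audit feeds a
model's melting-point and logD predictions (logD standing in for log Kow)
through the equation and correlates the result with the model's own
solubility predictions — a check that the model respects the physics
without having been trained on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["r2", "rmse", "pearson_r", "spearman_rho", "gse_logS",
           "gse_consistency", "GseConsistency", "metrics_frame", "fold_report"]


def _validate(pred, obs):
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-d arrays of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 observations")
    return pred, obs


def r2(pred, obs) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    pred, obs = _validate(pred, obs)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant observations")
    return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot


def rmse(pred, obs) -> float:
    pred, obs = _validate(pred, obs)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pearson_r(pred, obs) -> float:
    pred, obs = _validate(pred, obs)
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(pred, obs).statistic)


def spearman_rho(pred, obs) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    pred, obs = _validate(pred, obs)
    if np.unique(pred).size < 2 or np.unique(obs).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(pred, obs).statistic)


def gse_logS(lmp_celsius, log_kow):
    """General solubility equation: logSw = −0.01(LMP−25) − logKow + 0.5."""
    return -0.01 * (np.asarray(lmp_celsius, float) - 25.0) - np.asarray(log_kow, float) + 0.5


@dataclass
class GseConsistency:
    """Pearson correlations of the GSE audit.

    ``predicted``: corr(GSE(predicted LMP, predicted logD), predicted logS);
    ``measured``: same on measured values (None when not supplied);
    ``anticorrelation``: corr(−predicted logD, predicted logS) — the
    ablation showing how much of the consistency is mere logD/solubility
    anticorrelation.
    """

    predicted: float
    anticorrelation: float
    measured: float | None = None


def gse_consistency(pred_lmp, pred_logd, pred_logs,
                    measured_lmp=None, measured_logd=None, measured_logs=None) -> GseConsistency:
    """Audit model predictions against the general solubility equation.

    All solubility inputs must be on the log10 mol/L scale and melting
    points in °C; logD stands in for log Kow.
    """
    pred_lmp, pred_logs = np.asarray(pred_lmp, float), np.asarray(pred_logs, float)
    pred_logd = np.asarray(pred_logd, float)
    if not (pred_lmp.shape == pred_logd.shape == pred_logs.shape):
        raise ValueError("prediction vectors must align")
    if pred_lmp.size < 3:
        raise ValueError("need at least 3 compounds for the GSE audit")
    predicted = pearson_r(gse_logS(pred_lmp, pred_logd), pred_logs)
    anticorrelation = pearson_r(-pred_logd, pred_logs)
    measured = None
    if measured_lmp is not None:
        measured = pearson_r(gse_logS(np.asarray(measured_lmp, float),
                                      np.asarray(measured_logd, float)),
                             np.asarray(measured_logs, float))
    return GseConsistency(predicted=predicted, anticorrelation=anticorrelation,
                          measured=measured)


def metrics_frame(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray,
                  endpoint_codes: list[str], fold: int | str = 0,
                  min_labels: int = 3) -> pd.DataFrame:
    """Per-task metrics over the masked cells of one evaluation set."""
    columns = ["endpoint", "fold", "n", "r2", "spearman_rho", "pearson_r", "rmse"]
    rows = []
    for t, code in enumerate(endpoint_codes):
        cells = mask[:, t]
        if cells.sum() < min_labels:
            continue
        p, o = pred[cells, t], obs[cells, t]
        rows.append({"endpoint": code, "fold": fold, "n": int(cells.sum()),
                     "r2": r2(p, o), "spearman_rho": spearman_rho(p, o),
                     "pearson_r": pearson_r(p, o), "rmse": rmse(p, o)})
    return pd.DataFrame(rows, columns=columns)


def fold_report(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Average per-fold metrics per endpoint, with standard deviations."""
    grouped = per_fold.groupby("endpoint")[["r2", "spearman_rho", "pearson_r", "rmse"]]
    means = grouped.mean().add_suffix("_mean")
    sds = grouped.std(ddof=0).add_suffix("_sd")
    out = means.join(sds)
    out["n_folds"] = per_fold.groupby("endpoint")["fold"].count()
    return out.reset_index()
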