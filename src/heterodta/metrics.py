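"""Evaluation metrics for affinity regression.

Six metrics are reported: MAE, RMSE, Pearson correlation (PCC), Spearman
correlation, concordance index (CI) and the coefficient of determination
R^2.  The concordance index follows the standard affinity-benchmark
convention: over all pairs with distinct true values, a pair is concordant
when the predicted ordering matches the true ordering, and tied predictions
score 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "compute_metrics", "concordance_index"]


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    pcc: float
    spearman: float
    ci: float
    r2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _validate(y_true, y_pred, min_n=2):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    if y_true.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} samples")
    return y_true, y_pred


def concordance_index(y_true, y_pred) -> float:
    """Fraction of comparable pairs ranked consistently by the predictions.

    Pairs with equal true values are not comparable; prediction ties count
    0.5.  Returns NaN (with a warning) when no pair is comparable.
    """
    y_true, y_pred = _validate(y_true, y_pred)
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    comparable = np.triu(dt != 0.0, k=1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        warnings.warn("concordance index undefined: all true values equal")
        return float("nan")
    agree = np.sign(dt) == np.sign(dp)
    tied = dp == 0.0
    score = agree[comparable].sum() + 0.5 * tied[comparable].sum()
    return float(score / n_pairs)


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """All six regression metrics at once.

    With zero variance in either vector, PCC and Spearman are undefined and
    reported as NaN with a warning.
    """
    y_true, y_pred = _validate(y_true, y_pred)
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")

    if np.std(y_true) == 0.0 or np.std(y_pred) == 0.0:
        warnings.warn("correlation undefined: zero variance input")
        pcc = spearman = float("nan")
    else:
        pcc = float(stats.pearsonr(y_true, y_pred).statistic)
        spearman = float(stats.spearmanr(y_true, y_pred).statistic)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = concordance_index(y_true, y_pred)
    return MetricsReport(
        mae=mae, rmse=rmse, pcc=pcc, spearman=spearman, ci=ci, r2=r2,
        n=int(y_true.shape[0]),
    )
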