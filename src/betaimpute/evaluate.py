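"""Accuracy metrics on artificially masked entries.

Only positions whose ground truth is known (the artificial mask) are scored:

    RMSE = sqrt( sum (beta - beta_imp)^2 / |NA| )
    MAE  =       sum |beta - beta_imp|  / |NA|

plus the Pearson correlation of (beta, beta_imp) pairs and the mean absolute
percentage error, MAPE = 100 * mean |(beta - beta_imp) / beta| restricted to
positions with beta >= 0.01 (division by near-zero truth is unstable; the
retained count is reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import BetaMatrix

__all__ = ["EvaluationResult", "evaluate"]

#: truth values below this are excluded from MAPE
MAPE_MIN_TRUTH = 0.01


@dataclass
class EvaluationResult:
    """Imputation accuracy restricted to the artificial-NA positions."""

    rmse: float
    mae: float
    pcc: float
    mape: float
    n_scored: int       # positions entering RMSE/MAE/PCC
    n_evaluated: int    # positions retained for MAPE (truth >= 0.01)
    n_unimputed: int    # masked positions still missing in the imputed matrix

    def to_dict(self) -> dict[str, float | int]:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "pcc": self.pcc,
            "mape": self.mape,
            "n_scored": self.n_scored,
            "n_evaluated": self.n_evaluated,
            "n_unimputed": self.n_unimputed,
        }


def evaluate(
    complete: BetaMatrix,
    imputed: BetaMatrix,
    mask: list[tuple[int, int]] | np.ndarray,
) -> EvaluationResult:
    """Score imputed against true values on the masked positions only.

    Positions still missing in the imputed matrix (unimputable groups) are
    excluded from all metrics and counted in ``n_unimputed``. An empty mask
    is rejected; a mask position missing in the complete matrix has no
    ground truth and is likewise rejected.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("empty mask: nothing to evaluate")
    if mask.ndim != 2 or mask.shape[1] != 2:
        raise ValueError(f"mask must be a sequence of (row, col) pairs, got shape {mask.shape}")
    rows, cols = mask[:, 0], mask[:, 1]
    truth = complete.values[rows, cols]
    if np.any(np.isnan(truth)):
        raise ValueError("mask positions missing in the complete matrix")
    pred = imputed.values[rows, cols]

    scored = ~np.isnan(pred)
    n_unimputed = int((~scored).sum())
    truth, pred = truth[scored], pred[scored]
    if truth.size == 0:
        raise ValueError("no masked position was imputed; nothing to score")

    err = truth - pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if truth.size >= 2 and np.ptp(truth) > 0 and np.ptp(pred) > 0:
        pcc = float(stats.pearsonr(truth, pred).statistic)
    else:
        pcc = float("nan")
    retained = truth >= MAPE_MIN_TRUTH
    if retained.any():
        mape = float(100.0 * np.mean(np.abs(err[retained] / truth[retained])))
    else:
        mape = float("nan")
    return EvaluationResult(
        rmse=rmse,
        mae=mae,
        pcc=pcc,
        mape=mape,
        n_scored=int(truth.size),
        n_evaluated=int(retained.sum()),
        n_unimputed=n_unimputed,
    )
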