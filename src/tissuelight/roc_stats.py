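"""Empirical ROC curves, Mann-Whitney AUC and operating-point metrics.

The ROC sweeps thresholds over the pooled unique sample values; a value is
called positive when it is >= the threshold.  With trapezoidal integration
over the tied jumps, the area under this curve equals the midrank
Mann-Whitney statistic exactly — the module exposes both routes and tests
rely on that identity.  The operating point maximizes Youden's J
(sensitivity + specificity - 1), ties broken toward higher specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import InvalidParameterError

__all__ = [
    "ROCResult",
    "empirical_roc",
    "auc_mann_whitney",
    "pairwise_power_report",
    "DEFAULT_POWER_PAIRS",
]

DEFAULT_POWER_PAIRS = (
    (150.0, 200.0),
    (200.0, 225.0),
    (225.0, 250.0),
    (250.0, 300.0),
    (300.0, 350.0),
    (150.0, 350.0),
)


@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep with AUC and Youden operating-point metrics."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity_at_op: float
    specificity_at_op: float
    accuracy_at_op: float


def _as_sample(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidParameterError(f"{name} sample is empty")
    return arr


def empirical_roc(negatives, positives) -> ROCResult:
    """Empirical ROC between a negative and a positive sample.

    Thresholds descend over the pooled unique values (prefixed with +inf so
    the curve starts at (0, 0)); a value is classified positive when
    >= threshold, so the curve ends at (1, 1).
    """
    neg = _as_sample(negatives, "negatives")
    pos = _as_sample(positives, "positives")
    thresholds = np.concatenate(
        ([np.inf], np.unique(np.concatenate([neg, pos]))[::-1])
    )
    # broadcast threshold sweep
    se = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    sp = 1.0 - fpr

    auc = float(np.trapezoid(se, fpr))

    j = se + sp - 1.0
    best_j = j.max()
    candidates = np.nonzero(j == best_j)[0]
    # tie-break toward higher specificity (lower FPR)
    op = candidates[np.argmin(fpr[candidates])]
    n_pos, n_neg = pos.size, neg.size
    tp = se[op] * n_pos
    tn = sp[op] * n_neg
    accuracy = (tp + tn) / (n_pos + n_neg)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=se,
        one_minus_specificity=fpr,
        auc=auc,
        youden_threshold=float(thresholds[op]),
        sensitivity_at_op=float(se[op]),
        specificity_at_op=float(sp[op]),
        accuracy_at_op=float(accuracy),
    )


def auc_mann_whitney(negatives, positives) -> float:
    """Midrank Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg).

    Computed from pooled midranks; exactly equals the trapezoidal area
    under :func:`empirical_roc`.
    """
    neg = _as_sample(negatives, "negatives")
    pos = _as_sample(positives, "positives")
    pooled = np.concatenate([neg, pos])
    ranks = rankdata(pooled)
    rank_sum_pos = ranks[neg.size:].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def pairwise_power_report(
    values: pd.DataFrame,
    pairs=DEFAULT_POWER_PAIRS,
    value_column: str = "value",
) -> pd.DataFrame:
    """Operating-point metrics for each pair of incident powers.

    ``values`` has columns ``power_mw`` and ``value_column`` (one row per
    replicate).  For each (low, high) pair the lower power is the negative
    class; if the raw AUC is below 0.5 the labels are flipped (recorded in
    the ``flipped`` column) so the reported AUC is >= 0.5.

    Returns one row per pair with columns
    ``pair, power_low_mw, power_high_mw, sensitivity, specificity, auc,
    accuracy, flipped``.
    """
    if "power_mw" not in values.columns or value_column not in values.columns:
        raise InvalidParameterError(
            f"values table needs columns 'power_mw' and {value_column!r}"
        )
    present = set(values["power_mw"].unique())
    rows = []
    for low, high in pairs:
        for p in (low, high):
            if p not in present:
                raise InvalidParameterError(
                    f"power {p:g} mW not present in the values table"
                )
        neg = values.loc[values["power_mw"] == low, value_column].to_numpy()
        pos = values.loc[values["power_mw"] == high, value_column].to_numpy()
        roc = empirical_roc(neg, pos)
        flipped = False
        if roc.auc < 0.5:
            roc = empirical_roc(pos, neg)
            flipped = True
        rows.append(
            {
                "pair": f"{low:g} and {high:g} mW",
                "power_low_mw": low,
                "power_high_mw": high,
                "sensitivity": roc.sensitivity_at_op,
                "specificity": roc.specificity_at_op,
                "auc": roc.auc,
                "accuracy": roc.accuracy_at_op,
                "flipped": flipped,
            }
        )
    return pd.DataFrame(rows)
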