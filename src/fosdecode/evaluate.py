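"""Decoding performance: confusion matrix, ROC/AUC, permutation nulls, ITR.

AUC significance follows the label-shuffling scheme: the class labels are
randomly permuted against the fixed scores many times, the statistic is
recomputed on each draw, and the p-value is the add-one-smoothed exceedance
rate ``(1 + #{null >= observed}) / (1 + n_perm)`` (never exactly zero).
Shuffled-label AUCs are computed through the rank (Mann-Whitney) identity,
which makes a million draws affordable.

The information transfer rate uses the Wolpaw definition: with N classes
and accuracy P, bits per selection

    B = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1)),

scaled to bits/min by the response time (one 512 ms window per decision).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, roc_curve

from .decode import PredictionSet
from .errors import DataError

__all__ = [
    "DecodingResult",
    "confusion_and_rates",
    "roc_auc",
    "permutation_pvalue",
    "auc_permutation_pvalue",
    "accuracy_permutation_pvalue",
    "wolpaw_itr",
    "evaluate_predictions",
]

RESPONSE_TIME_S = 0.512


def confusion_and_rates(y_true, y_pred) -> dict:
    """2x2 confusion counts plus accuracy, sensitivity, specificity.

    Class 1 is 'positive': sensitivity = TP / (TP + FN),
    specificity = TN / (TN + FP).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise DataError("empty prediction set")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    return {
        "confusion": cm,
        "accuracy": (tp + tn) / cm.sum(),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


def _rank_auc(scores_ranked: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity on pre-ranked scores."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise DataError("both classes must be present")
    u = scores_ranked[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR by threshold sweep) and trapezoid AUC.

    Tied scores are handled by the sweep itself, which is equivalent to the
    midrank statistic. Constant scores give AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise DataError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise DataError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant decision scores: AUC defaults to 0.5")
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray], float],
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Generic label-shuffling permutation test (observed, p).

    ``statistic_fn`` maps a label vector to a scalar; the observed value is
    ``statistic_fn(labels)`` and the null is its distribution over label
    permutations. Prefer :func:`auc_permutation_pvalue` /
    :func:`accuracy_permutation_pvalue` for large ``n_perm``.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100 for a meaningful p-value")
    labels = np.asarray(labels)
    observed = float(statistic_fn(labels))
    if not np.isfinite(observed):
        raise DataError("degenerate statistic: observed value is not finite")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if statistic_fn(rng.permutation(labels)) >= observed:
            exceed += 1
    return observed, (1 + exceed) / (1 + n_perm)


def _null_counts(labels: np.ndarray, values: np.ndarray, observed: float,
                 n_perm: int, seed: int, batch: int = 2000) -> int:
    """#{permuted-label statistic >= observed} for sum-based statistics.

    The statistic must be a monotone function of ``values[labels == 1].sum()``
    after permutation; the caller converts the observed value to that scale.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    exceed = 0
    done = 0
    base = np.asarray(labels, dtype=np.int8)
    while done < n_perm:
        m = min(batch, n_perm - done)
        perms = np.tile(base, (m, 1))
        rng.permuted(perms, axis=1, out=perms)
        sums = perms.astype(float) @ values
        exceed += int(np.sum(sums >= observed - 1e-12))
        done += m
    return exceed


def auc_permutation_pvalue(
    scores, labels, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """AUC and its label-shuffling permutation p-value (rank fast path)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ranks = rankdata(scores)
    auc_obs = _rank_auc(ranks, labels)
    # AUC is monotone in the rank-sum of the positive class
    n1 = int(labels.sum())
    obs_sum = auc_obs * (len(labels) - n1) * n1 + n1 * (n1 + 1) / 2.0
    exceed = _null_counts(labels, ranks, obs_sum, n_perm, seed)
    return auc_obs, (1 + exceed) / (1 + n_perm)


def accuracy_permutation_pvalue(
    y_pred, y_true, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Accuracy and its label-shuffling permutation p-value.

    The true labels are shuffled against the fixed predictions; accuracy
    equals a linear function of the permuted positive-class mass on
    predicted-positive rows, so the same fast path applies.
    """
    y_pred = np.asarray(y_pred, dtype=int)
    y_true = np.asarray(y_true, dtype=int)
    # matches = N0_pred + sum over true-positives of (2*pred - 1)
    values = 2.0 * y_pred - 1.0
    const = float(np.sum(y_pred == 0))
    obs_matches = float(np.sum(y_pred == y_true))
    acc_obs = obs_matches / len(y_true)
    exceed = _null_counts(y_true, values, obs_matches - const, n_perm, seed)
    return acc_obs, (1 + exceed) / (1 + n_perm)


def wolpaw_itr(
    accuracy: float, n_classes: int = 2, response_time: float = RESPONSE_TIME_S
) -> float:
    """Wolpaw information transfer rate in bits per minute.

    Below-chance accuracy carries no usable information under this model and
    returns 0 with a warning; perfect binary accuracy at 512 ms gives
    ``60 / 0.512 = 117.1875`` bpm.
    """
    if response_time <= 0:
        raise DataError("response_time must be positive")
    if n_classes < 2:
        raise DataError("need at least 2 classes")
    chance = 1.0 / n_classes
    if accuracy < chance:
        warnings.warn("accuracy below chance: ITR clipped to 0 bpm")
        return 0.0
    p = min(float(accuracy), 1.0)
    bits = np.log2(n_classes)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n_classes - 1))
    return float(bits * 60.0 / response_time)


@dataclass
class DecodingResult:
    """Complete evaluation of one decoding run."""

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    auc_p: float
    acc_p: float
    itr_bpm: float
    response_time: float = RESPONSE_TIME_S
    n_permutations: int = 10_000
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "auc_p": self.auc_p,
            "acc_p": self.acc_p,
            "itr_bpm": self.itr_bpm,
            "response_time": self.response_time,
            "n_permutations": self.n_permutations,
            "meta": self.meta,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_roc_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"fpr": self.roc_fpr, "tpr": self.roc_tpr}).to_csv(
            path, sep="\t", index=False
        )


def per_subject_accuracy(preds: PredictionSet):
    """Out-of-fold accuracy per subject (the across-participant spread)."""
    import pandas as pd

    df = preds.to_frame()
    return df.assign(hit=df["true"] == df["predicted"]).groupby("subject")["hit"].mean()


def evaluate_predictions(
    preds: PredictionSet,
    n_permutations: int = 10_000,
    seed: int = 0,
    response_time: float = RESPONSE_TIME_S,
    meta: dict | None = None,
) -> DecodingResult:
    """Full evaluation of an out-of-fold prediction set."""
    rates = confusion_and_rates(preds.y_true, preds.y_pred)
    fpr, tpr, auc = roc_auc(preds.score, preds.y_true)
    auc_obs, auc_p = auc_permutation_pvalue(
        preds.score, preds.y_true, n_permutations, seed
    )
    acc_obs, acc_p = accuracy_permutation_pvalue(
        preds.y_pred, preds.y_true, n_permutations, seed + 1
    )
    return DecodingResult(
        confusion=rates["confusion"],
        accuracy=rates["accuracy"],
        sensitivity=rates["sensitivity"],
        specificity=rates["specificity"],
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        auc_p=auc_p,
        acc_p=acc_p,
        itr_bpm=wolpaw_itr(rates["accuracy"], 2, response_time),
        response_time=response_time,
        n_permutations=n_permutations,
        meta=meta or {},
    )
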