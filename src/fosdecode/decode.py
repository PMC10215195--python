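"""Subject-grouped cross-validated RBF-SVM decoding of quadrant features.

All rows (trials) of one subject are assigned to a single fold, so every
test subject is unseen during training — the grouping that protects
across-subject generalization claims. Within each fold split, features
are z-scored with statistics estimated on the training rows only and an
RBF-kernel SVM produces labels and continuous decision scores for the
held-out rows.

The kernel exponent gamma = 0.5 is a standard value *for z-scored
inputs*, which only makes sense as a dimension-free convention: between
z-scored rows the squared distance concentrates around 2P (P features),
so the meaningful kernel is ``k(u, v) = exp(-gamma ||u - v||^2 / P)``
(the default, ``gamma_convention="normalized"``). The literal
``exp(-gamma ||u - v||^2)`` is available as ``gamma_convention="raw"``;
at P in the hundreds it degenerates to an identity kernel (off-diagonal
entries ~ exp(-P)) and the classifier collapses to the majority class.

Fitting the normalization on the training folds only is a deliberate
leakage guard; ``normalization="global"`` restores whole-matrix z-scoring
for comparison. The z-score uses the population (divide-by-n) standard
deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import DecodeError
from .features import FeatureMatrix

__all__ = [
    "ClassifierConfig",
    "PredictionSet",
    "zscore_fit_apply",
    "grouped_folds",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM and cross-validation settings."""

    gamma: float = 0.5
    gamma_convention: str = "normalized"  # exponent -gamma*d^2/P; or "raw"
    C: float = 1.0
    n_folds: int = 5
    seed: int = 0
    normalization: str = "per_fold"  # or "global"
    threshold: str = "zero"  # or "youden" (tuned on training folds)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DecodeError("gamma must be positive")
        if self.gamma_convention not in ("normalized", "raw"):
            raise DecodeError("gamma_convention must be 'normalized' or 'raw'")
        if self.C <= 0:
            raise DecodeError("C must be positive")
        if self.n_folds < 2:
            raise DecodeError("n_folds must be >= 2")
        if self.normalization not in ("per_fold", "global"):
            raise DecodeError("normalization must be 'per_fold' or 'global'")
        if self.threshold not in ("zero", "youden"):
            raise DecodeError("threshold must be 'zero' or 'youden'")


@dataclass
class PredictionSet:
    """Out-of-fold predictions: one entry per feature-matrix row."""

    y_true: np.ndarray
    y_pred: np.ndarray
    score: np.ndarray
    fold: np.ndarray
    subjects: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject": self.subjects,
                "fold": self.fold,
                "true": self.y_true,
                "predicted": self.y_pred,
                "score": self.score,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def zscore_fit_apply(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Column z-scoring with statistics estimated on ``train`` only.

    Population (ddof=0) standard deviation. Zero-variance columns are
    mapped to zeros (with a logged warning) rather than NaN.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise DecodeError("need at least 2 training rows to estimate z-scores")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance feature column(s) zeroed", int(dead.sum()))
        sd = np.where(dead, 1.0, sd)
    ztr = (train - mean) / sd
    ztr[:, dead] = 0.0
    if test is None:
        return ztr, None
    zte = (np.asarray(test, dtype=float) - mean) / sd
    zte[:, dead] = 0.0
    return ztr, zte


def grouped_folds(subjects: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Per-row fold ids keeping each subject's rows in exactly one fold.

    Subjects are shuffled by the seed and dealt round-robin, so fold sizes
    differ by at most one subject.
    """
    subjects = np.asarray(subjects)
    uniq = pd_unique_ordered(subjects)
    if len(uniq) < n_folds:
        raise DecodeError(
            f"{len(uniq)} subjects cannot populate {n_folds} grouped folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of = {uniq[j]: int(i % n_folds) for i, j in enumerate(order)}
    return np.array([fold_of[s] for s in subjects], dtype=int)


def pd_unique_ordered(values: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def cross_validate(features: FeatureMatrix, config: ClassifierConfig | None = None) -> PredictionSet:
    """Out-of-fold predictions under subject-grouped k-fold CV.

    Every row is predicted exactly once, by a model whose training data
    exclude that row's subject. Deterministic for a fixed config seed.
    """
    config = config or ClassifierConfig()
    X = features.values
    y = np.asarray(features.labels, dtype=int)
    subjects = np.asarray(features.subjects)
    folds = grouped_folds(subjects, config.n_folds, config.seed)

    if config.normalization == "global":
        X, _ = zscore_fit_apply(X)

    gamma_eff = config.gamma
    if config.gamma_convention == "normalized":
        gamma_eff = config.gamma / X.shape[1]

    y_pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    for k in range(config.n_folds):
        test_mask = folds == k
        train_mask = ~test_mask
        ytr = y[train_mask]
        if len(np.unique(ytr)) < 2:
            raise DecodeError(f"training split of fold {k} contains a single class")
        if config.normalization == "per_fold":
            Xtr, Xte = zscore_fit_apply(X[train_mask], X[test_mask])
        else:
            Xtr, Xte = X[train_mask], X[test_mask]
        clf = SVC(kernel="rbf", gamma=gamma_eff, C=config.C)
        clf.fit(Xtr, ytr)
        s_te = clf.decision_function(Xte)
        score[test_mask] = s_te
        if config.threshold == "youden":
            s_tr = clf.decision_function(Xtr)
            thr = _youden_threshold(s_tr, ytr)
            y_pred[test_mask] = (s_te >= thr).astype(int)
        else:
            y_pred[test_mask] = clf.predict(Xte)
        logger.info(
            "fold %d: %d train rows, %d test rows, subjects %s",
            k,
            int(train_mask.sum()),
            int(test_mask.sum()),
            sorted(set(subjects[test_mask].tolist())),
        )
    return PredictionSet(
        y_true=y, y_pred=y_pred, score=score, fold=folds, subjects=subjects
    )


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing TPR - FPR (Youden's J) on given data."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return float(thr[np.argmax(tpr - fpr)])
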