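"""ErrP detection: Fisher-score feature ranking, shrinkage LDA, and
word-wise blocked cross-validation.

Features are the flattened channel x time samples of each (downsampled,
realigned) epoch. Each spelled word forms one CV fold, so temporally
adjacent epochs never straddle the train/test boundary. Within every fold,
realignment templates, Fisher ranking and the LDA are fit on training words
only and applied label-blind to the held-out word.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from .preprocess import EpochSet
from .realign import apply_template_shifts, realign_epochs, realigned_data

__all__ = [
    "FeatureMatrix", "FoldMetrics", "CVResult",
    "fisher_scores", "select_top_features",
    "train_lda", "score_lda", "predict_lda", "auc",
    "crossvalidate_by_word",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Epochs x features matrix with a feature -> (channel, time) index.

    Features are flattened channel-major: feature ``c * n_times + t`` is
    channel ``c`` at time sample ``t``.
    """

    values: np.ndarray
    channel_idx: np.ndarray
    time_idx: np.ndarray
    labels: np.ndarray   # boolean, True = error epoch
    word_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features contain NaN or Inf")
        n, f = self.values.shape
        if len(self.channel_idx) != f or len(self.time_idx) != f:
            raise ValueError("feature index does not cover all features")
        if len(self.labels) != n or len(self.word_ids) != n:
            raise ValueError("label/word_id length mismatch")

    @classmethod
    def from_epochs(cls, epochs: EpochSet) -> "FeatureMatrix":
        """Flatten (shift-corrected) epochs into a feature matrix."""
        data = realigned_data(epochs)
        n_ep, n_ch, n_t = data.shape
        ch_idx, t_idx = np.divmod(np.arange(n_ch * n_t), n_t)
        return cls(values=data.reshape(n_ep, n_ch * n_t),
                   channel_idx=ch_idx, time_idx=t_idx,
                   labels=epochs.is_error, word_ids=epochs.word_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def fisher_scores(features: FeatureMatrix) -> np.ndarray:
    """Per-feature Fisher discriminant score
    ``|mean_error - mean_correct| / sqrt(var_error + var_correct)``.

    Variances are unbiased (ddof=1; classes with a single epoch contribute
    zero variance). A zero-variance feature scores 0 when the class means
    coincide; when they differ it is reported as ten times the largest
    finite score, with a warning, rather than infinity.
    """
    y = features.labels
    if y.all() or not y.any():
        raise ValueError("Fisher scores require both classes")
    return _fisher_from_arrays(features.values, y)


def _fisher_from_arrays(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    def _var(a: np.ndarray) -> np.ndarray:
        return a.var(axis=0, ddof=1) if a.shape[0] > 1 else np.zeros(a.shape[1])

    x1, x0 = x[y], x[~y]
    diff = np.abs(x1.mean(axis=0) - x0.mean(axis=0))
    denom = np.sqrt(_var(x1) + _var(x0))
    scores = np.zeros_like(diff)
    ok = denom > 0
    scores[ok] = diff[ok] / denom[ok]
    degenerate = ~ok & (diff > 1e-12)
    if np.any(degenerate):
        cap = 10.0 * (scores[ok].max() if np.any(ok) else 1.0)
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance features with unequal "
            "class means; scoring them at 10x the largest finite score",
            stacklevel=2)
        scores[degenerate] = cap
    return scores


def select_top_features(scores: np.ndarray, k: int,
                        time_idx: np.ndarray | None = None,
                        channel_idx: np.ndarray | None = None) -> np.ndarray:
    """Indices of the ``k`` largest scores; ties break toward the earlier
    time sample, then the lower channel index."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= len(scores):
        raise ValueError(f"k must be in [1, {len(scores)}], got {k}")
    n = len(scores)
    t_key = time_idx if time_idx is not None else np.arange(n)
    c_key = channel_idx if channel_idx is not None else np.zeros(n)
    # lexsort: last key is primary
    order = np.lexsort((c_key, t_key, -scores))
    return np.sort(order[:k])


@dataclass
class LDAModel:
    """Shrinkage-regularised linear discriminant for error vs correct.

    Wraps scikit-learn's lsqr-solver LDA (Ledoit-Wolf ``shrinkage='auto'``
    by default); ``feature_idx`` records which columns of the full feature
    grid the model consumes. Scores are signed distances to the decision
    boundary, positive toward the error class; the predict threshold sits at
    the boundary implied by the training class frequencies.
    """

    estimator: LinearDiscriminantAnalysis
    feature_idx: np.ndarray = field(default=None)  # type: ignore[assignment]


def train_lda(values: np.ndarray, labels: np.ndarray,
              shrinkage: float | str | None = "auto") -> LDAModel:
    """Fit a binary LDA (classes: correct=0, error=1) on epochs x features.

    ``shrinkage``: ``'auto'`` for Ledoit-Wolf, a float in [0, 1], or
    ``0``/``None`` for the empirical pooled covariance. A singular empirical
    covariance falls back to a small shrinkage floor, logged.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 epochs of each class")
    if shrinkage == 0:
        shrinkage = None
    est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    x = np.asarray(values, dtype=float)
    y = labels.astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinearity warnings
            est.fit(x, y)
        if not np.all(np.isfinite(est.coef_)):
            raise np.linalg.LinAlgError("non-finite discriminant")
    except np.linalg.LinAlgError:
        logger.info("singular pooled covariance; refitting with shrinkage floor")
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-4)
        est.fit(x, y)
    return LDAModel(estimator=est)


def score_lda(model: LDAModel, values: np.ndarray) -> np.ndarray:
    """Signed distance to the decision boundary (positive = error class)."""
    return model.estimator.decision_function(np.asarray(values, dtype=float))


def predict_lda(model: LDAModel, values: np.ndarray) -> np.ndarray:
    """Boolean class labels (True = error) at the prior-adjusted boundary."""
    return model.estimator.predict(np.asarray(values, dtype=float)).astype(bool)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation: the probability
    that a random error epoch outscores a random correct epoch, ties
    counting one half."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class FoldMetrics:
    auc: float
    accuracy: float
    balanced_accuracy: float
    recall_error: float
    recall_correct: float
    n_test: int


@dataclass
class CVResult:
    """Word-wise cross-validation outcome for one subject x condition.

    Fold means/SDs are unweighted across folds, matching the convention of
    reporting means and standard deviations across CV iterations. Plain
    accuracy sits at the prior-adjusted LDA boundary; because the classes
    are roughly 80/20, balanced accuracy and per-class recalls are carried
    alongside so the imbalance stays visible.
    """

    per_fold: dict[int, FoldMetrics]

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([m.auc for m in self.per_fold.values()])

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.per_fold.values()])

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.fold_aucs.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) if len(self.per_fold) > 1 else 0.0

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    @property
    def n_test_total(self) -> int:
        return int(sum(m.n_test for m in self.per_fold.values()))


def _fold_groups(epochs: EpochSet) -> list[list[int]]:
    """Word ids grouped into folds; a word missing one class is merged with
    its neighbouring word (logged) so every test fold carries both classes."""
    words = sorted(set(epochs.word_ids.tolist()))
    groups: list[list[int]] = []
    for w in words:
        mask = epochs.word_ids == w
        has_both = epochs.is_error[mask].any() and (~epochs.is_error[mask]).any()
        if has_both or not groups:
            groups.append([w])
        else:
            logger.info("word %s lacks a class; merging with previous fold", w)
            groups[-1].append(w)
    # a deficient first group merges forward
    if len(groups) > 1:
        mask = np.isin(epochs.word_ids, groups[0])
        if not (epochs.is_error[mask].any() and (~epochs.is_error[mask]).any()):
            logger.info("first fold lacks a class; merging with the next")
            groups[1] = groups[0] + groups[1]
            groups = groups[1:]
    return groups


def crossvalidate_by_word(
    epochs: EpochSet,
    k_features: int = 60,
    shrinkage: float | str | None = "auto",
    realign: bool = True,
    max_shift: float = 0.075,
    max_iter: int = 20,
) -> CVResult:
    """Leave-one-word-out evaluation of the full detection chain.

    Per fold: realign the training error epochs (when ``realign``), freeze
    the training template, rank features by Fisher score on the training
    words, fit the shrinkage LDA, then shift the held-out word's epochs
    label-blind against the frozen template and score them. No held-out
    epoch ever influences its own training set.
    """
    groups = _fold_groups(epochs)
    if len(groups) < 2:
        raise ValueError("need at least 2 usable folds")

    per_fold: dict[int, FoldMetrics] = {}
    for fold_id, group in enumerate(groups):
        test_mask = np.isin(epochs.word_ids, group)
        train = epochs.select_epochs(~test_mask)
        test = epochs.select_epochs(test_mask)

        if realign and int(train.is_error.sum()) >= 2:
            rr = realign_epochs(train, max_shift=max_shift, max_iter=max_iter)
            train = rr.aligned
            test = apply_template_shifts(test, rr.template, max_shift=max_shift)

        fm_train = FeatureMatrix.from_epochs(train)
        scores = fisher_scores(fm_train)
        k = min(k_features, fm_train.n_features)
        sel = select_top_features(scores, k, fm_train.time_idx,
                                  fm_train.channel_idx)
        model = train_lda(fm_train.values[:, sel], fm_train.labels, shrinkage)

        fm_test = FeatureMatrix.from_epochs(test)
        test_scores = score_lda(model, fm_test.values[:, sel])
        pred = predict_lda(model, fm_test.values[:, sel])
        y = fm_test.labels
        rec_err = float(np.mean(pred[y])) if y.any() else np.nan
        rec_cor = float(np.mean(~pred[~y])) if (~y).any() else np.nan
        per_fold[fold_id] = FoldMetrics(
            auc=auc(test_scores, y),
            accuracy=float(np.mean(pred == y)),
            balanced_accuracy=float(np.nanmean([rec_err, rec_cor])),
            recall_error=rec_err,
            recall_correct=rec_cor,
            n_test=len(test),
        )
    return CVResult(per_fold=per_fold)
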