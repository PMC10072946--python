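"""Evaluation metrics and traditional early-warning-signal baselines.

Provides the Kendall-tau trend classifier (the conventional EWS detector: a
monotone-trend score on a single indicator channel, thresholded), F1-score
versus lead time, ROC/AUC by explicit threshold sweep, normalized confusion
matrices and AR(1) surrogate null series for scalar records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from .indicators import CHANNEL_NAMES, FeatureSet, featurize_dataset, subset_channels

__all__ = [
    "TrendClassifier",
    "EvaluationResult",
    "kendall_tau",
    "classify_by_trend",
    "roc_auc",
    "f1_by_lead",
    "ar1_null",
    "evaluate_binary",
    "normalized_confusion",
]


def kendall_tau(series: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b of a series against its time index.

    An all-tied (constant) series has no defined trend and returns 0.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0.0:
        return 0.0
    tau = stats.kendalltau(np.arange(x.size), x).statistic
    return float(tau)


@dataclass(frozen=True)
class TrendClassifier:
    """Threshold on the Kendall tau of one indicator channel.

    ``direction=+1`` flags a run as 'transition' when the trend score
    ``direction * tau`` meets the threshold (rising variance/autocorrelation
    are the classic precursors).
    """

    channel: Union[int, str]
    threshold: float = 0.5
    direction: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [-1, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def channel_index(self) -> int:
        if isinstance(self.channel, str):
            return CHANNEL_NAMES.index(self.channel)
        return int(self.channel)

    def scores(self, features: FeatureSet) -> np.ndarray:
        """Trend score (signed tau over the unpadded span) for each run."""
        ch = self.channel_index
        total = features.X.shape[1]
        out = np.empty(len(features))
        for i in range(len(features)):
            span = features.X[i, total - features.lengths[i] :, ch]
            out[i] = self.direction * kendall_tau(span)
        return out

    def predict(self, features: FeatureSet) -> np.ndarray:
        return (self.scores(features) >= self.threshold).astype(int)


def classify_by_trend(
    features: FeatureSet, channel: Union[int, str], threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1 = transition) and tau scores for one indicator channel."""
    clf = TrendClassifier(channel=channel, threshold=threshold)
    scores = clf.scores(features)
    return (scores >= threshold).astype(int), scores


@dataclass
class EvaluationResult:
    """Metrics for one model/dataset pair."""

    accuracy: Optional[float] = None
    auc: Optional[float] = None
    roc_fpr: Optional[np.ndarray] = None
    roc_tpr: Optional[np.ndarray] = None
    leads: Optional[np.ndarray] = None
    f1_scores: Optional[np.ndarray] = None
    confusion: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> EvaluationResult:
    """ROC curve by threshold sweep over the unique scores, AUC by trapezoid.

    Runs sharing a score enter the positive set simultaneously, which gives
    tied pairs half credit -- identical to the Mann-Whitney pair-counting
    formulation.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last entry of each tied block (simultaneous inclusion)
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[last_of_block] / n_pos]
    fpr = np.r_[0.0, fp[last_of_block] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationResult(
        auc=auc, roc_fpr=fpr, roc_tpr=tpr, metadata={"n_pos": n_pos, "n_neg": n_neg}
    )


def _score_features(classifier, features: FeatureSet) -> np.ndarray:
    """Transition score from either a neural model or a trend classifier."""
    if isinstance(classifier, TrendClassifier):
        return classifier.scores(features)
    X = subset_channels(features.X, getattr(classifier, "channel_subset", "full"))
    return classifier.transition_score(X)


def _decision_threshold(classifier) -> float:
    return classifier.threshold if isinstance(classifier, TrendClassifier) else 0.5


def f1_by_lead(
    classifier,
    runs: Sequence,
    *,
    leads: Sequence[int] = tuple(range(0, 251, 25)),
    seed: int = 0,
    min_length: int = 50,
    featurize_kwargs: Optional[dict] = None,
) -> EvaluationResult:
    """F1 of the transition class at increasing lead times to the transition.

    For each lead the runs are re-truncated that many steps before their
    transition and re-featurized causally, then classified (probability 0.5
    for neural models, the tau threshold for trend classifiers).
    """
    featurize_kwargs = dict(featurize_kwargs or {})
    featurize_kwargs.setdefault("min_length", min_length)
    f1s = []
    for lead in leads:
        features = featurize_dataset(runs, lead=int(lead), seed=seed, **featurize_kwargs)
        scores = _score_features(classifier, features)
        pred = (scores >= _decision_threshold(classifier)).astype(int)
        f1s.append(_sk_f1(features.y, pred, zero_division=0.0))
    return EvaluationResult(
        leads=np.asarray(list(leads), dtype=int),
        f1_scores=np.asarray(f1s, dtype=float),
        metadata={"seed": seed, "n_runs": len(runs)},
    )


def normalized_confusion(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: Optional[int] = None
) -> np.ndarray:
    """Confusion matrix with rows normalized to classification rates."""
    labels = None if n_classes is None else list(range(n_classes))
    cm = _sk_confusion(y_true, y_pred, labels=labels).astype(float)
    row = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)


def evaluate_binary(classifier, features: FeatureSet) -> EvaluationResult:
    """Accuracy, ROC/AUC and confusion matrix of a binary detector."""
    scores = _score_features(classifier, features)
    pred = (scores >= _decision_threshold(classifier)).astype(int)
    res = roc_auc(scores, features.y)
    res.accuracy = float((pred == features.y).mean())
    res.confusion = normalized_confusion(features.y, pred, n_classes=2)
    res.metadata.update({"n_runs": len(features)})
    return res


def ar1_null(
    segment: np.ndarray,
    n_replicates: int,
    seed: int = 0,
    length: Optional[int] = None,
) -> np.ndarray:
    """Stationary AR(1) surrogate null series matched to an observed segment.

    The lag-1 coefficient and innovation variance are estimated from the
    segment; surrogates start in the stationary distribution and are shifted
    to the segment mean.  Returns shape (n_replicates, length).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 10:
        raise ValueError("segment must have length >= 10")
    length = int(length or x.size)
    mu = x.mean()
    d = x - mu
    var = d.var()
    if var <= 0:
        raise ValueError("segment is constant; cannot fit an AR(1) model")
    phi = float(np.dot(d[1:], d[:-1]) / np.dot(d[:-1], d[:-1]))
    phi = float(np.clip(phi, -0.999, 0.999))
    innov_sd = float(np.sqrt(max(var * (1.0 - phi**2), 1e-30)))
    rng = np.random.default_rng(seed)
    out = np.empty((n_replicates, length))
    state = rng.normal(0.0, np.sqrt(var), size=n_replicates)
    for t in range(length):
        out[:, t] = state
        state = phi * state + rng.normal(0.0, innov_sd, size=n_replicates)
    return out + mu
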