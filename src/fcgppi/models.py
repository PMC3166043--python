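"""Classifiers, score fusion, abstract-wise cross-validation and metrics.

Two classifier routes mirror the two feature types: a linear SVM on the
Boolean lexical features, and a truncated-SVD projection (top 200 left-
singular directions by default) followed by an RBF-kernel SVM (C=3,
gamma=20 in the exp(-gamma * ||a-b||^2) convention) on the dense coupling
features.  Their raw decision values are fused by a fixed weighted sum,
3/5 lexical + 2/5 coupling, and thresholded at 0.

Evaluation is abstract-wise: cross-validation folds partition *documents*,
so two sentences from the same abstract never straddle the train/test
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, LinearSVC

from fcgppi.corpus_io import LABEL_POSITIVE, Example

logger = logging.getLogger(__name__)

DEFAULT_SVD_K = 200
DEFAULT_RBF_COST = 3.0
DEFAULT_RBF_GAMMA = 20.0
DEFAULT_FUSION_WEIGHTS = (0.6, 0.4)


def abstract_cv_split(
    examples: Sequence[Example], folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign every example to a fold by its abstract (doc_id).

    Abstracts are shuffled with the seeded generator and dealt round-robin,
    so fold sizes differ by at most one abstract and no doc_id ever spans
    two folds.
    """
    doc_ids = sorted({ex.doc_id for ex in examples})
    if len(doc_ids) < folds:
        raise ValueError(
            f"need at least {folds} abstracts for {folds} folds, got {len(doc_ids)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(doc_ids))
    fold_of_doc = {doc_ids[j]: i % folds for i, j in enumerate(order)}
    return np.array([fold_of_doc[ex.doc_id] for ex in examples])


def labels_vector(examples: Sequence[Example]) -> np.ndarray:
    """+1/-1 label vector (positives are +1)."""
    return np.array([1 if ex.label == LABEL_POSITIVE else -1 for ex in examples])


class BooleanVectorizer:
    """String-keyed Boolean feature sets -> sparse indicator matrix."""

    def __init__(self, feature_sets: Sequence[set[str]]):
        vocab = sorted(set().union(*feature_sets)) if feature_sets else []
        self.vocabulary: dict[str, int] = {key: i for i, key in enumerate(vocab)}

    def transform(self, feature_sets: Sequence[set[str]]) -> sparse.csr_matrix:
        indptr = [0]
        indices: list[int] = []
        vocab = self.vocabulary
        for feats in feature_sets:
            cols = sorted(vocab[f] for f in feats if f in vocab)
            indices.extend(cols)
            indptr.append(len(indices))
        data = np.ones(len(indices))
        return sparse.csr_matrix(
            (data, indices, indptr), shape=(len(feature_sets), max(len(vocab), 1))
        )


def train_linear(features: sparse.spmatrix, labels: np.ndarray) -> LinearSVC:
    """Linear SVM with default regularisation on Boolean features."""
    _require_two_classes(labels)
    model = LinearSVC(C=1.0, random_state=0, max_iter=5000)
    model.fit(features, labels)
    return model


@dataclass
class SvdRbfModel:
    """Truncated-SVD projection followed by an RBF-kernel SVM."""

    k: int = DEFAULT_SVD_K
    cost: float = DEFAULT_RBF_COST
    gamma: float = DEFAULT_RBF_GAMMA

    def fit(
        self,
        train_matrix: np.ndarray,
        labels: np.ndarray,
        basis_matrix: np.ndarray | None = None,
    ) -> "SvdRbfModel":
        """Fit the projection and the classifier.

        ``basis_matrix`` controls the SVD fit scope: pass the full
        (train + test) matrix for the transductive variant, or omit it to
        fit the basis on training rows only.  Labels are never involved in
        the projection either way.
        """
        _require_two_classes(labels)
        basis = train_matrix if basis_matrix is None else basis_matrix
        k = min(self.k, min(basis.shape) - 1) if min(basis.shape) > 1 else 1
        if k < self.k:
            logger.warning("SVD components clipped from %d to %d (matrix rank)", self.k, k)
        # deterministic full SVD of the (dense, modest-sized) FCD matrix
        _, _, vt = np.linalg.svd(np.asarray(basis), full_matrices=False)
        self.components_ = vt[:k]
        self.svm_ = SVC(kernel="rbf", C=self.cost, gamma=self.gamma)
        self.svm_.fit(self.project(train_matrix), labels)
        return self

    def project(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix) @ self.components_.T

    def decision_function(self, matrix: np.ndarray) -> np.ndarray:
        return self.svm_.decision_function(self.project(matrix))


def _require_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")


def fuse(
    score_lex: np.ndarray | float,
    score_fcd: np.ndarray | float,
    weights: tuple[float, float] = DEFAULT_FUSION_WEIGHTS,
) -> np.ndarray | float:
    """Weighted sum of the two raw decision values (classify at 0)."""
    w_lex, w_fcd = weights
    return w_lex * np.asarray(score_lex) + w_fcd * np.asarray(score_fcd)


@dataclass
class EvalReport:
    """Positive-class precision/recall/F plus ROC AUC, on the 0..1 scale."""

    precision: float
    recall: float
    f_score: float
    auc: float
    n: int
    n_positive: int

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "auc": self.auc,
            "n": self.n,
            "n_positive": self.n_positive,
        }


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> EvalReport:
    """Threshold metrics for the positive class plus rank-based AUC.

    *labels* are +1/-1; predictions are ``score > threshold``.  AUC is the
    Wilcoxon rank statistic and is invariant to monotone transforms of the
    scores; the thresholded metrics are not.  Degenerate single-class
    inputs yield AUC = nan.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred_pos = scores > threshold
    actual_pos = y > 0
    tp = int(np.count_nonzero(pred_pos & actual_pos))
    fp = int(np.count_nonzero(pred_pos & ~actual_pos))
    fn = int(np.count_nonzero(~pred_pos & actual_pos))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    if actual_pos.all() or not actual_pos.any():
        auc = float("nan")
    else:
        auc = float(roc_auc_score(actual_pos, scores))
    return EvalReport(precision, recall, f_score, auc, len(y), int(actual_pos.sum()))
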