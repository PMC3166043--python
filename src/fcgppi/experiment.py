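"""End-to-end experiment runs: fold loop, stage wiring, reproducible metrics.

The cross-validation loop keeps training-fold hygiene: CDFs are selected on
each fold's training examples only, and no classifier ever sees test-fold
labels.  Co-occurrence counting touches no labels at all, so the unlabeled
corpus is scanned once against the union of the per-fold CDF sets; each
fold's transform then reads only its own CDFs' counts, which is count-for-
count identical to scanning inside the loop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from fcgppi.corpus_io import LABEL_POSITIVE, Example
from fcgppi.fcd_engine import (
    FAMILY_EXTRACTORS,
    CooccurrenceStore,
    FcdConfig,
    FcdVectorizer,
    count,
)
from fcgppi.feature_selection import CdfSet, select_cdfs_from_sets
from fcgppi.lexical_features import ALL_FAMILIES, cdf_candidates, extract_lexical
from fcgppi.models import (
    DEFAULT_FUSION_WEIGHTS,
    BooleanVectorizer,
    SvdRbfModel,
    abstract_cv_split,
    evaluate,
    fuse,
    labels_vector,
    train_linear,
)
from fcgppi.synthetic_corpus import feature_counts, frequency_filter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All experiment knobs, with the method's reference defaults.

    400 CDFs, smoothing b=1, 200 SVD components, RBF SVM with C=3 and
    gamma=20, fusion weights 3/5 lexical + 2/5 coupling, 10 abstract-wise
    folds.
    """

    lexical_families: tuple[str, ...] = ALL_FAMILIES
    edf_families: tuple[str, ...] = ("sp",)
    k_cdfs: int = 400
    fcd_measure: str = "smoothed_pmi"
    fcd_b: float = 1.0
    svd_k: int = 200
    rbf_cost: float = 3.0
    rbf_gamma: float = 20.0
    fusion_weights: tuple[float, float] = DEFAULT_FUSION_WEIGHTS
    folds: int = 10
    seed: int = 0
    use_lexical: bool = True
    use_fcd: bool = True
    transductive_svd: bool = True
    normalize_fcd: bool = True
    lexical_max_count: int | None = None
    edf_max_count: int | None = None

    def fcd_config(self) -> FcdConfig:
        return FcdConfig(measure=self.fcd_measure, b=self.fcd_b)


def _labeled_edf_keys(
    examples: Sequence[Example],
    families: Sequence[str],
    max_count: int | None = None,
) -> frozenset[str]:
    """EDF keys occurring in the labelled examples, optionally restricted to
    the sparse tail (corpus presence count <= max_count)."""
    per_example = []
    for ex in examples:
        keys: set[str] = set()
        for fam in families:
            keys.update(e.key for e in FAMILY_EXTRACTORS[fam](ex))
        per_example.append(keys)
    if max_count is None:
        return frozenset().union(*per_example) if per_example else frozenset()
    counts = feature_counts(per_example)
    return frozenset(k for k, v in counts.items() if v <= max_count)


def per_fold_cdfs(
    config: RunConfig, labeled: Sequence[Example], fold_of: np.ndarray | None = None
) -> dict[int, CdfSet]:
    """CDF sets selected on each fold's training examples only."""
    labeled = list(labeled)
    if fold_of is None:
        fold_of = abstract_cv_split(labeled, folds=config.folds, seed=config.seed)
    candidate_sets = [cdf_candidates(ex) for ex in labeled]
    positive = [ex.label == LABEL_POSITIVE for ex in labeled]
    out: dict[int, CdfSet] = {}
    for f in range(config.folds):
        train = fold_of != f
        out[f] = select_cdfs_from_sets(
            [s for s, m in zip(candidate_sets, train) if m],
            [p for p, m in zip(positive, train) if m],
            k=config.k_cdfs,
        )
    return out


def run_experiment(
    config: RunConfig,
    labeled: Sequence[Example],
    unlabeled: Sequence[Example] = (),
    store: CooccurrenceStore | None = None,
) -> dict:
    """Run abstract-wise cross-validation and return pooled + per-fold metrics.

    A prebuilt co-occurrence ``store`` (counted against a superset of the
    per-fold CDF keys) can be passed to reuse counting across runs, e.g.
    along an unlabeled-corpus-size ladder; otherwise ``unlabeled`` is
    counted here.
    """
    labeled = list(labeled)
    fold_of = abstract_cv_split(labeled, folds=config.folds, seed=config.seed)
    y = labels_vector(labeled)

    # stage: per-example feature sets, computed once
    lexical_sets = [extract_lexical(ex, config.lexical_families) for ex in labeled]
    if config.lexical_max_count is not None:
        lexical_sets = frequency_filter(lexical_sets, config.lexical_max_count)

    # stage: per-fold CDF selection on training folds only
    fold_cdfs: dict[int, CdfSet] = {}
    if config.use_fcd:
        fold_cdfs = per_fold_cdfs(config, labeled, fold_of)

    # stage: one label-free counting pass over the unlabeled corpus
    edf_filter = None
    if config.use_fcd:
        edf_filter = _labeled_edf_keys(
            labeled, config.edf_families, config.edf_max_count
        )
        if store is None:
            union_cdfs = sorted({k for s in fold_cdfs.values() for k in s.keys})
            store = count(
                unlabeled,
                union_cdfs,
                families=config.edf_families,
                edf_filter=set(edf_filter),
                ds_targets=labeled if "ds" in config.edf_families else None,
            )

    scores_lex = np.zeros(len(labeled))
    scores_fcd = np.zeros(len(labeled))
    per_fold = []
    for f in range(config.folds):
        train_idx = np.flatnonzero(fold_of != f)
        test_idx = np.flatnonzero(fold_of == f)
        if config.use_lexical:
            vec = BooleanVectorizer([lexical_sets[i] for i in train_idx])
            x_train = vec.transform([lexical_sets[i] for i in train_idx])
            x_test = vec.transform([lexical_sets[i] for i in test_idx])
            model = train_linear(x_train, y[train_idx])
            scores_lex[test_idx] = model.decision_function(x_test)
        if config.use_fcd:
            fcd_vec = FcdVectorizer(
                store,
                fold_cdfs[f],
                families=config.edf_families,
                config=config.fcd_config(),
                normalize=config.normalize_fcd,
                edf_filter=edf_filter,
            )
            fold_examples = [labeled[i] for i in np.concatenate([train_idx, test_idx])]
            matrix = fcd_vec.transform(fold_examples)
            m_train = matrix[: len(train_idx)]
            m_test = matrix[len(train_idx) :]
            rbf = SvdRbfModel(
                k=config.svd_k, cost=config.rbf_cost, gamma=config.rbf_gamma
            )
            rbf.fit(
                m_train,
                y[train_idx],
                basis_matrix=matrix if config.transductive_svd else None,
            )
            scores_fcd[test_idx] = rbf.decision_function(m_test)
        fold_scores = _active_scores(config, scores_lex, scores_fcd)[test_idx]
        per_fold.append(evaluate(fold_scores, y[test_idx]).as_dict())

    fused = _active_scores(config, scores_lex, scores_fcd)
    result = {
        "config": _config_dict(config),
        "pooled": evaluate(fused, y).as_dict(),
        "per_fold": per_fold,
    }
    if config.use_lexical:
        result["lexical"] = evaluate(scores_lex, y).as_dict()
    if config.use_fcd:
        result["fcd"] = evaluate(scores_fcd, y).as_dict()
        result["n_unlabeled"] = store.N
    return result


def _active_scores(
    config: RunConfig, scores_lex: np.ndarray, scores_fcd: np.ndarray
) -> np.ndarray:
    if config.use_lexical and config.use_fcd:
        return np.asarray(fuse(scores_lex, scores_fcd, config.fusion_weights))
    return scores_lex if config.use_lexical else scores_fcd


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
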