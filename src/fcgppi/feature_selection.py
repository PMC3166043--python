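"""Chi-square ranking of lexical features; the top-K become CDFs.

Class-distinguishing features (CDFs) are lexical cues that correlate with
the interaction label, e.g. ``P1_Right=interacts with``.  They are selected
on labelled *training* data only — inside each cross-validation fold — and
are later used solely to index co-occurrence counts on unlabeled text, not
as classifier inputs.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from fcgppi.corpus_io import LABEL_POSITIVE, Example
from fcgppi.lexical_features import cdf_candidates

logger = logging.getLogger(__name__)

DEFAULT_K = 400


def chi_square(feature_presence: Sequence[bool], labels: Sequence[bool]) -> float:
    """One-degree-of-freedom chi-square statistic of a 2x2 presence/label table.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with a = present &
    positive, b = present & negative, c = absent & positive, d = absent &
    negative.  Returns 0 when any margin is 0 (feature always/never present,
    or single-class labels).  No continuity correction: the statistic is
    used for ranking only.
    """
    presence = np.asarray(feature_presence, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if presence.shape != y.shape:
        raise ValueError("feature_presence and labels must have the same length")
    n = presence.size
    a = int(np.count_nonzero(presence & y))
    b = int(np.count_nonzero(presence & ~y))
    c = int(np.count_nonzero(~presence & y))
    d = n - a - b - c
    return _chi_square_cells(a, b, c, d)


def _chi_square_cells(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    num = a * d - b * c
    return n * num * num / denom


@dataclass
class CdfSet:
    """Ordered CDF selection: ``entries`` non-increasing by chi-square score."""

    entries: list[tuple[str, float]]
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        self._key_set = frozenset(key for key, _ in self.entries)
        if len(self._key_set) != len(self.entries):
            raise ValueError("CDF keys must be unique")

    @property
    def keys(self) -> list[str]:
        return [key for key, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self._key_set

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, score in self.entries:
                fh.write(f"{key}\t{score:.10g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "CdfSet":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                key, _, score = line.rstrip("\n").rpartition("\t")
                entries.append((key, float(score)))
        return cls(entries, k=len(entries))


def select_cdfs(
    examples: Iterable[Example],
    k: int = DEFAULT_K,
    candidate_extractor: Callable[[Example], set[str]] = cdf_candidates,
) -> CdfSet:
    """Rank candidate lexical features by chi-square and keep the top *k*.

    The candidate pool is every GA/SA/SP n-gram key present in the training
    examples (Boolean presence per example).  Ties are broken
    lexicographically by key so the selection is order-independent.
    """
    examples = list(examples)
    return select_cdfs_from_sets(
        [candidate_extractor(ex) for ex in examples],
        [ex.label == LABEL_POSITIVE for ex in examples],
        k=k,
    )


def select_cdfs_from_sets(
    feature_sets: Sequence[set[str]], positive: Sequence[bool], k: int = DEFAULT_K
) -> CdfSet:
    """As :func:`select_cdfs`, on precomputed per-example candidate sets."""
    if len(feature_sets) != len(positive):
        raise ValueError("feature_sets and positive must have the same length")
    pos_count: Counter[str] = Counter()
    total_count: Counter[str] = Counter()
    n = len(feature_sets)
    n_pos = int(sum(positive))
    for feats, is_pos in zip(feature_sets, positive):
        for key in feats:
            total_count[key] += 1
            if is_pos:
                pos_count[key] += 1
    if n == 0:
        raise ValueError("select_cdfs needs at least one labelled example")

    scored = []
    for key, present in total_count.items():
        a = pos_count.get(key, 0)
        b = present - a
        c = n_pos - a
        d = (n - n_pos) - b
        scored.append((key, _chi_square_cells(a, b, c, d)))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    if len(scored) < k:
        logger.warning("only %d CDF candidates available (requested %d)", len(scored), k)
    return CdfSet(scored[:k], k=k)
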