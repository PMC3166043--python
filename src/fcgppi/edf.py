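"""Example-distinguishing features (EDFs) and their root mappings.

An EDF is a feature specific enough to act as a near-signature of the
example that produced it.  Three families:

* SP-EDF — the offset-keyed n-grams of :func:`fcgppi.lexical_features.sp_lex`,
  rooted by the general area (Left/Inner/Right) containing the n-gram's
  final token.
* CP-EDF — the conjunct-position patterns of
  :func:`fcgppi.lexical_features.cp_lex`, rooted by the (P1 side, P2 side)
  pair; four roots.
* DS-EDF — discretised-similarity memberships ``SimWith_<target>_Over_<t>``:
  an example carries the key when its cosine similarity to the target
  example is at least the threshold.  All DS-EDFs share a single root; when
  an example's coupling vector is assembled only the keys targeting that
  example itself are summed, so unlabeled sentences similar to it act as
  carriers of its co-occurrence statistics.

Roots matter because coupling features are indexed by (root, CDF, measure):
every EDF sharing a root pools its unlabeled-corpus evidence into the same
coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from fcgppi.corpus_io import Example
from fcgppi.lexical_features import (
    _adjacent_ngrams,
    _sp_items,
    discretize_distance,
    surrounding_areas,
)

SP_ROOTS = ("Left_Area", "Inner_Area", "Right_Area")
CP_ROOTS = (
    "P1_Left^P2_Left",
    "P1_Left^P2_Right",
    "P1_Right^P2_Left",
    "P1_Right^P2_Right",
)
DS_ROOT = "DS"
DS_ROOTS = (DS_ROOT,)

DS_THRESHOLDS = (0.1, 0.2, 0.3, 0.5, 0.8)

#: SA-window terms are repeated this many times in similarity vectors.
DS_SA_WEIGHT = 3


@dataclass(frozen=True)
class Edf:
    key: str
    root: str
    family: str


def _sp_root(x: int, i1: int, i2: int) -> str:
    """General area holding final-token index *x*; the protein indices
    themselves fold into the area to their right (i1 -> Inner, i2 -> Right)."""
    if x < i1:
        return "Left_Area"
    if x < i2:
        return "Inner_Area"
    return "Right_Area"


def sp_edfs(example: Example, window: int = 5) -> list[Edf]:
    """SP-EDFs: identical key set to ``sp_lex``, rooted by general area."""
    i1, i2 = example.i1, example.i2
    seen: dict[str, Edf] = {}
    for ngram, x in _sp_items(example, window):
        root = _sp_root(x, i1, i2)
        for key in (f"{x - i1}_From_P1={ngram}", f"{x - i2}_From_P2={ngram}"):
            if key not in seen:
                seen[key] = Edf(key, root, "SP")
    return list(seen.values())


def cp_edfs(example: Example) -> list[Edf]:
    """CP-EDFs: identical key set to ``cp_lex``, rooted by the side pair."""
    bucket = discretize_distance(example.distance)
    out: list[Edf] = []
    seen: set[str] = set()
    for side1 in ("Left", "Right"):
        grams1 = _adjacent_ngrams(example, example.i1, side1)
        for side2 in ("Left", "Right"):
            root = f"P1_{side1}^P2_{side2}"
            for g1 in grams1:
                for g2 in _adjacent_ngrams(example, example.i2, side2):
                    key = f"P1_{side1}={g1}^P2_{side2}={g2}^{bucket}"
                    if key not in seen:
                        seen.add(key)
                        out.append(Edf(key, root, "CP"))
    return out


# ---------------------------------------------------------------------------
# discretised similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsVector:
    """Weighted offset-keyed 2/3-gram vector used for example similarity.

    Unigrams are dropped (too generic to distinguish examples); terms whose
    final token falls inside a 4-token surrounding window count
    :data:`DS_SA_WEIGHT`-fold.  Similarity is gated on equal protein
    distance, making the match deliberately strict.
    """

    weights: tuple[tuple[str, int], ...]
    distance: int

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for _, w in self.weights))


def ds_vector(example: Example) -> DsVector:
    """Build the similarity vector: whole-sentence window, no unigrams."""
    i1, i2 = example.i1, example.i2
    sa_indices: set[int] = set()
    for start, stop in surrounding_areas(example).values():
        sa_indices.update(range(max(0, start), stop + 1))

    weights: dict[str, int] = {}
    tokens = example.tokens
    for x in range(example.end + 1):
        w = DS_SA_WEIGHT if x in sa_indices else 1
        for n in (2, 3):
            start = x - n + 1
            if start < 0:
                break
            ngram = " ".join(tokens[start : x + 1])
            for key in (f"{x - i1}_From_P1={ngram}", f"{x - i2}_From_P2={ngram}"):
                if key not in weights:
                    weights[key] = w
    return DsVector(tuple(sorted(weights.items())), example.distance)


def ds_similarity(a: DsVector, b: DsVector) -> float:
    """Cosine similarity, zeroed when the protein distances differ."""
    if a.distance != b.distance:
        return 0.0
    na, nb = a.norm, b.norm
    if na == 0.0 or nb == 0.0:
        return 0.0
    wb = dict(b.weights)
    dot = sum(w * wb[key] for key, w in a.weights if key in wb)
    return dot / (na * nb)


def ds_key(target_id: str, threshold: float) -> str:
    return f"SimWith_{target_id}_Over_{threshold:g}"


def ds_edfs(
    example: Example,
    targets: Sequence[Example],
    thresholds: Iterable[float] = DS_THRESHOLDS,
    target_vectors: Sequence[DsVector] | None = None,
    example_vector: DsVector | None = None,
) -> list[Edf]:
    """DS-EDFs of *example* against every target example.

    Emits ``SimWith_<target>_Over_<t>`` for each threshold the similarity
    reaches, so a key at 0.8 implies the keys at all lower thresholds.
    Precomputed vectors can be passed to avoid repeated construction.
    """
    vec = example_vector if example_vector is not None else ds_vector(example)
    if target_vectors is None:
        target_vectors = [ds_vector(t) for t in targets]
    thresholds = sorted(thresholds)
    out: list[Edf] = []
    for target, tvec in zip(targets, target_vectors):
        sim = ds_similarity(vec, tvec)
        for theta in thresholds:
            if sim >= theta:
                out.append(Edf(ds_key(target.example_id, theta), DS_ROOT, "DS"))
    return out


def ds_self_edfs(
    example: Example, thresholds: Iterable[float] = DS_THRESHOLDS
) -> list[Edf]:
    """The DS-EDFs an example contributes to its *own* coupling vector.

    Of all DS keys present in an example, only those targeting the example
    itself share its root; self-similarity is 1 whenever the vector is
    nonzero, so these are simply the example's own keys at every threshold.
    """
    if ds_vector(example).norm == 0.0:
        return []
    return [
        Edf(ds_key(example.example_id, theta), DS_ROOT, "DS")
        for theta in sorted(thresholds)
    ]
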