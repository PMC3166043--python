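"""Boolean local lexical features around a marked protein pair.

Five families, all derived from token positions relative to the two focus
proteins at indices ``i1`` (prot1) and ``i2`` (prot2):

* F1 ``ga_bow``    — bag of words per general area (left / inner / right).
* F2 ``ga_lex``    — 1–3-grams per general area.
* F3 ``sa_lex``    — 1–3-grams fully inside the four 4-token surrounding
  windows (``P1_Left``, ``P1_Right``, ``P2_Left``, ``P2_Right``).
* F4 ``sp_lex``    — 1–3-grams keyed by the signed offset of their final
  token from each protein, for final tokens within 5 of either protein.
* F5 ``cp_lex``    — conjunctions of one n-gram adjacent to each protein
  plus the discretised protein distance.

Features are Boolean (set semantics); multiple occurrences of the same key
in one sentence collapse.  N-grams may contain the placeholder tokens
``prot1``/``prot2``/``prot0`` — patterns like ``0_From_P2=with prot2`` are
informative and deliberately kept.

Positional convention: an n-gram's position is the index of its FINAL
token, so ``-3_From_P1=the results`` names a bigram spanning ``i1-4..i1-3``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

from fcgppi.corpus_io import Example

Span = tuple[int, int]  # inclusive [start, end]; empty when start > end

GENERAL_AREAS = ("Left_Area", "Inner_Area", "Right_Area")
SURROUNDING_AREAS = ("P1_Left", "P1_Right", "P2_Left", "P2_Right")

SA_WINDOW = 4
SP_WINDOW = 5

ALL_FAMILIES = ("F1", "F2", "F3", "F4", "F5")

DISTANCE_BUCKETS = (
    "0", "1", "2", "3", "4", "5",
    "6~7", "8~10", "11~15", "16~20", "21~30", "31~40", "40~",
)

_BUCKET_EDGES = (
    (0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, "4"), (5, "5"),
    (7, "6~7"), (10, "8~10"), (15, "11~15"), (20, "16~20"),
    (30, "21~30"), (40, "31~40"),
)


def discretize_distance(d: int) -> str:
    """Map a nonnegative token distance to its bucket label.

    Buckets: 0–5 singletons, then 6~7, 8~10, 11~15, 16~20, 21~30, 31~40,
    and 40~ for everything above 40 (range bounds read as inclusive).
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    for upper, label in _BUCKET_EDGES:
        if d <= upper:
            return label
    return "40~"


def general_areas(example: Example) -> dict[str, Span]:
    """The three areas split by the protein pair, clipped to the sentence."""
    return {
        "Left_Area": (0, example.i1 - 1),
        "Inner_Area": (example.i1 + 1, example.i2 - 1),
        "Right_Area": (example.i2 + 1, example.end),
    }


def surrounding_areas(example: Example) -> dict[str, Span]:
    """4-token windows beside each protein, clipped to the sentence.

    A window beside one protein may reach across the other protein when the
    pair is close; only the window's own anchor index is excluded.
    """
    i1, i2, end = example.i1, example.i2, example.end
    return {
        "P1_Left": (max(0, i1 - SA_WINDOW), i1 - 1),
        "P1_Right": (i1 + 1, min(end, i1 + SA_WINDOW)),
        "P2_Left": (max(0, i2 - SA_WINDOW), i2 - 1),
        "P2_Right": (i2 + 1, min(end, i2 + SA_WINDOW)),
    }


def extract_ngrams(
    tokens: Sequence[str], span: Span, n_max: int = 3
) -> list[tuple[str, int]]:
    """All 1..n_max-grams fully contained in *span*, with final-token index."""
    start, stop = span
    start = max(start, 0)
    stop = min(stop, len(tokens) - 1)
    out: list[tuple[str, int]] = []
    for i in range(start, stop + 1):
        for n in range(1, n_max + 1):
            j = i + n - 1
            if j > stop:
                break
            out.append((" ".join(tokens[i : j + 1]), j))
    return out


def ga_bow(example: Example) -> set[str]:
    """F1: bag of words per general area, e.g. ``Left_Area=expression``."""
    feats: set[str] = set()
    for area, (start, stop) in general_areas(example).items():
        for i in range(max(start, 0), stop + 1):
            feats.add(f"{area}={example.tokens[i]}")
    return feats


def ga_lex(example: Example) -> set[str]:
    """F2: 1–3-grams per general area."""
    feats: set[str] = set()
    for area, span in general_areas(example).items():
        for ngram, _ in extract_ngrams(example.tokens, span):
            feats.add(f"{area}={ngram}")
    return feats


def sa_lex(example: Example) -> set[str]:
    """F3: 1–3-grams fully inside each 4-token surrounding window."""
    feats: set[str] = set()
    for area, span in surrounding_areas(example).items():
        for ngram, _ in extract_ngrams(example.tokens, span):
            feats.add(f"{area}={ngram}")
    return feats


def _sp_items(example: Example, window: int) -> Iterator[tuple[str, int]]:
    """(ngram, final index) pairs whose final token is within *window* of
    either protein.  N-grams may start before the window; the position is
    carried by the final token alone."""
    tokens = example.tokens
    i1, i2, end = example.i1, example.i2, example.end
    xs = set(range(max(0, i1 - window), min(end, i1 + window) + 1))
    xs.update(range(max(0, i2 - window), min(end, i2 + window) + 1))
    for x in sorted(xs):
        for n in (1, 2, 3):
            start = x - n + 1
            if start < 0:
                break
            yield " ".join(tokens[start : x + 1]), x


def sp_lex(example: Example, window: int = SP_WINDOW) -> set[str]:
    """F4: offset-keyed n-grams near either protein.

    Every qualifying n-gram emits BOTH keys ``m_From_P1=ngram`` (m = x-i1)
    and ``n_From_P2=ngram`` (n = x-i2); the offset relative to the other
    protein may exceed the window (e.g. ``-9_From_P2=the`` when the pair is
    5 apart), which ties the two views of the same token together.
    """
    i1, i2 = example.i1, example.i2
    feats: set[str] = set()
    for ngram, x in _sp_items(example, window):
        feats.add(f"{x - i1}_From_P1={ngram}")
        feats.add(f"{x - i2}_From_P2={ngram}")
    return feats


def _adjacent_ngrams(example: Example, protein: int, side: str) -> list[str]:
    """1–3-grams whose token run touches the protein index on *side*."""
    tokens = example.tokens
    out = []
    if side == "Left":
        for n in (1, 2, 3):
            start = protein - n
            if start < 0:
                break
            out.append(" ".join(tokens[start:protein]))
    else:
        for n in (1, 2, 3):
            stop = protein + n
            if stop > example.end:
                break
            out.append(" ".join(tokens[protein + 1 : stop + 1]))
    return out


def cp_lex(example: Example) -> set[str]:
    """F5: conjunct-position patterns joining both proteins' neighbours.

    One n-gram adjacent to prot1, one adjacent to prot2, and the
    discretised distance, e.g. ``P1_Left=show that^P2_Left=prot0 and^5``.
    """
    bucket = discretize_distance(example.distance)
    feats: set[str] = set()
    for side1 in ("Left", "Right"):
        grams1 = _adjacent_ngrams(example, example.i1, side1)
        if not grams1:
            continue
        for side2 in ("Left", "Right"):
            for g1 in grams1:
                for g2 in _adjacent_ngrams(example, example.i2, side2):
                    feats.add(f"P1_{side1}={g1}^P2_{side2}={g2}^{bucket}")
    return feats


_FAMILY_EXTRACTORS = {
    "F1": ga_bow,
    "F2": ga_lex,
    "F3": sa_lex,
    "F4": sp_lex,
    "F5": cp_lex,
}


def extract_lexical(
    example: Example, families: Iterable[str] = ALL_FAMILIES
) -> set[str]:
    """Union of the selected feature families for one example."""
    feats: set[str] = set()
    for fam in families:
        try:
            extractor = _FAMILY_EXTRACTORS[fam]
        except KeyError:
            raise ValueError(f"unknown feature family {fam!r}") from None
        feats |= extractor(example)
    return feats


def cdf_candidates(example: Example) -> set[str]:
    """The CDF candidate pool for one example: GA + SA + SP n-gram keys."""
    return ga_lex(example) | sa_lex(example) | sp_lex(example)
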