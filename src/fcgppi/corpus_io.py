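"""Reading, normalising, masking and serialising relation examples.

An *example* is one candidate protein pair in one sentence.  The two focus
proteins are masked to the placeholder tokens ``prot1`` and ``prot2`` (in
sentence order) and every other tagged protein mention to ``prot0``, so that
downstream features describe the lexical context rather than the names.

Two labelled-corpus input routes are supported: a one-record-per-line TSV
(the package's native format) and a minimal interaction-XML dialect in the
style of the publicly used pair-annotation corpora (document -> sentence ->
entity/pair with character offsets).
"""

from __future__ import annotations

import hashlib
import html
import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

PROT1 = "prot1"
PROT2 = "prot2"
PROT0 = "prot0"

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"
LABEL_UNLABELED = "unlabeled"

_LABEL_TO_CHAR = {LABEL_POSITIVE: "1", LABEL_NEGATIVE: "0", LABEL_UNLABELED: "U"}
_CHAR_TO_LABEL = {v: k for k, v in _LABEL_TO_CHAR.items()}

# Maximal letter/digit runs stay together; every other non-space character
# becomes its own token.  Underscore is not a letter/digit, hence the split.
_TOKEN_RE = re.compile(r"[^\W_]+|[^\w\s]|_", re.UNICODE)

#: Sentences with more than this many tagged proteins are dropped when
#: enumerating unlabeled pairs.
MAX_PROTEINS_PER_SENTENCE = 10

#: Fixed replacement sentence for pairs whose character spans overlap
#: (self-interactions and nested mentions).
OVERLAP_TOKENS = (PROT1, PROT2, ".")


def normalize_and_tokenize(text: str) -> list[str]:
    """Lowercase, decode XML character entities, and tokenize.

    Maximal runs of letters/digits are kept as single tokens; every other
    non-space character is emitted on its own, e.g. ``"wild-type (d)"`` ->
    ``["wild", "-", "type", "(", "d", ")"]``.  Empty or whitespace-only
    input yields an empty list.
    """
    decoded = html.unescape(text).lower()
    return _TOKEN_RE.findall(decoded)


@dataclass(frozen=True)
class Example:
    """One candidate protein pair in one tokenized, masked sentence."""

    example_id: str
    doc_id: str
    tokens: tuple[str, ...]
    i1: int
    i2: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in _LABEL_TO_CHAR:
            raise ValueError(f"unknown label {self.label!r}")
        end = len(self.tokens) - 1
        if not (0 <= self.i1 < self.i2 <= end):
            raise ValueError(
                f"focus indices must satisfy 0 <= i1 < i2 <= END, "
                f"got i1={self.i1}, i2={self.i2}, END={end}"
            )
        if self.tokens[self.i1] != PROT1 or self.tokens[self.i2] != PROT2:
            raise ValueError("tokens at i1/i2 must be the prot1/prot2 placeholders")

    @property
    def end(self) -> int:
        """Index of the last token."""
        return len(self.tokens) - 1

    @property
    def distance(self) -> int:
        """Token distance ``i2 - i1`` between the two focus proteins."""
        return self.i2 - self.i1


def make_example(
    tokens: Sequence[str],
    label: str,
    example_id: str = "",
    doc_id: str = "",
) -> Example:
    """Build an :class:`Example`, locating ``prot1``/``prot2`` in *tokens*."""
    toks = tuple(tokens)
    try:
        i1 = toks.index(PROT1)
        i2 = toks.index(PROT2)
    except ValueError as exc:
        raise ValueError("tokens must contain prot1 and prot2") from exc
    return Example(example_id, doc_id, toks, i1, i2, label)


@dataclass(frozen=True)
class ProteinSpan:
    """Inclusive character span ``[start, end]`` of one protein mention."""

    span_id: str
    start: int
    end: int

    def overlaps(self, other: "ProteinSpan") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class RawSentence:
    """Unmasked sentence text with tagged protein mention spans."""

    doc_id: str
    text: str
    protein_spans: tuple[ProteinSpan, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for span in self.protein_spans:
            if not (0 <= span.start <= span.end < len(self.text)):
                raise ValueError(f"span {span.span_id} outside sentence text")
            if span.span_id in seen:
                raise ValueError(f"duplicate span id {span.span_id}")
            seen.add(span.span_id)


def _pair_example_id(sentence: RawSentence, id_a: str, id_b: str) -> str:
    """Deterministic id for one (sentence, pair) so repeated runs agree."""
    key = "\x1f".join((sentence.doc_id, sentence.text, id_a, id_b))
    return hashlib.md5(key.encode("utf-8")).hexdigest()[:16]


def mask_pair(
    sentence: RawSentence,
    pair: tuple[str, str],
    label: str = LABEL_UNLABELED,
    example_id: str | None = None,
) -> Example:
    """Mask one focus pair to ``prot1``/``prot2`` and the rest to ``prot0``.

    The focus protein occurring first in the text becomes ``prot1``.  If the
    two focus spans overlap in character space (self-interactions, nested
    mentions) the whole example collapses to the fixed sentence
    ``prot1 prot2 .``.
    """
    id_a, id_b = pair
    if id_a == id_b:
        raise ValueError("focus pair must consist of two distinct span ids")
    by_id = {s.span_id: s for s in sentence.protein_spans}
    try:
        span_a, span_b = by_id[id_a], by_id[id_b]
    except KeyError as exc:
        raise ValueError(f"unknown span id {exc.args[0]!r}") from None
    if example_id is None:
        example_id = _pair_example_id(sentence, id_a, id_b)

    first, second = sorted((span_a, span_b), key=lambda s: (s.start, s.end))
    if first.overlaps(second):
        return Example(example_id, sentence.doc_id, OVERLAP_TOKENS, 0, 1, label)

    placeholders = {first.span_id: PROT1, second.span_id: PROT2}
    spans = sorted(sentence.protein_spans, key=lambda s: (s.start, s.end))
    tokens: list[str] = []
    cursor = 0
    for span in spans:
        if span.start < cursor:
            # a non-focus mention nested in / overlapping an already-masked
            # one: skip it, the earlier placeholder covers the characters
            continue
        tokens.extend(normalize_and_tokenize(sentence.text[cursor : span.start]))
        tokens.append(placeholders.get(span.span_id, PROT0))
        cursor = span.end + 1
    tokens.extend(normalize_and_tokenize(sentence.text[cursor:]))
    return make_example(tokens, label, example_id, sentence.doc_id)


def enumerate_unlabeled_examples(sentence: RawSentence) -> list[Example]:
    """One unlabeled example per unordered protein pair.

    Sentences with more than :data:`MAX_PROTEINS_PER_SENTENCE` tagged
    proteins are skipped entirely (they are expensive and rarely carry a
    clean pairwise assertion).
    """
    spans = sentence.protein_spans
    if len(spans) < 2 or len(spans) > MAX_PROTEINS_PER_SENTENCE:
        return []
    out = []
    for a, b in itertools.combinations(spans, 2):
        out.append(mask_pair(sentence, (a.span_id, b.span_id), LABEL_UNLABELED))
    return out


# ---------------------------------------------------------------------------
# native TSV record format:  example_id \t doc_id \t {1,0,U} \t tokens
# ---------------------------------------------------------------------------


class RecordError(ValueError):
    """Raised for malformed records, naming the offending line."""


def read_examples(path: str | Path) -> Iterator[Example]:
    """Stream :class:`Example` records from the native TSV format."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise RecordError(f"{path}:{lineno}: expected 4 tab-separated fields")
            example_id, doc_id, label_char, token_str = parts
            if label_char not in _CHAR_TO_LABEL:
                raise RecordError(f"{path}:{lineno}: unknown label {label_char!r}")
            try:
                yield make_example(
                    token_str.split(" "),
                    _CHAR_TO_LABEL[label_char],
                    example_id,
                    doc_id,
                )
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc


def write_examples(examples: Iterable[Example], path: str | Path) -> int:
    """Write examples to the native TSV format; returns the record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(
                "\t".join(
                    (ex.example_id, ex.doc_id, _LABEL_TO_CHAR[ex.label], " ".join(ex.tokens))
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# minimal interaction-XML reader
# ---------------------------------------------------------------------------


def _parse_offset(value: str) -> tuple[int, int]:
    start_s, _, end_s = value.partition("-")
    return int(start_s), int(end_s)


def read_xml_sentences(path: str | Path) -> Iterator[tuple[RawSentence, etree._Element]]:
    """Yield (RawSentence, sentence element) pairs from the XML dialect.

    Layout: ``corpus > document(id) > sentence(id, text) >
    entity(id, charOffset="start-end") / pair(e1, e2, interaction)``.
    Character offsets are inclusive and sentence-relative.
    """
    tree = etree.parse(str(path))
    for document in tree.iter("document"):
        doc_id = document.get("id", "")
        for sent_el in document.iter("sentence"):
            spans = tuple(
                ProteinSpan(ent.get("id"), *_parse_offset(ent.get("charOffset")))
                for ent in sent_el.iter("entity")
            )
            yield RawSentence(doc_id, sent_el.get("text", ""), spans), sent_el


def read_interaction_xml(path: str | Path) -> Iterator[Example]:
    """Read labelled pair examples from the simplified interaction-XML dialect."""
    for sentence, sent_el in read_xml_sentences(path):
        for pair_el in sent_el.iter("pair"):
            label = (
                LABEL_POSITIVE
                if pair_el.get("interaction", "").lower() == "true"
                else LABEL_NEGATIVE
            )
            pair_id = pair_el.get("id") or _pair_example_id(
                sentence, pair_el.get("e1"), pair_el.get("e2")
            )
            yield mask_pair(
                sentence,
                (pair_el.get("e1"), pair_el.get("e2")),
                label,
                example_id=pair_id,
            )
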