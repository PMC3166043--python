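"""Co-occurrence counting over unlabeled text and the FCD feature transform.

The feature coupling degree (FCD) of an EDF *e* and a CDF *c* is a
smoothed, pointwise-mutual-information-style relatedness score computed
from four example-level counts on an unlabeled corpus: the corpus size N,
the marginals cnt(e) and cnt(c), and the joint co(e, c).  Presence is
Boolean per example — a key occurring twice in one sentence counts once.

An example's FCD vector is indexed by triples (EDF root h, CDF c, measure
t); the coordinate value is the sum of FCD(e, c) over every EDF e present
in the example with root(e) = h.  EDFs never seen in the unlabeled corpus
contribute the co = 0 baseline rather than being dropped, so absence of
evidence is itself informative.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import sparse

from fcgppi.corpus_io import Example
from fcgppi.edf import CP_ROOTS, DS_ROOTS, SP_ROOTS, Edf, cp_edfs, ds_self_edfs, sp_edfs
from fcgppi.feature_selection import CdfSet

MEASURES = ("smoothed_pmi", "log_count_pmi")

FAMILY_ROOTS: dict[str, tuple[str, ...]] = {
    "sp": SP_ROOTS,
    "cp": CP_ROOTS,
    "ds": DS_ROOTS,
}

FAMILY_EXTRACTORS: dict[str, Callable[[Example], list[Edf]]] = {
    "sp": sp_edfs,
    "cp": cp_edfs,
    "ds": ds_self_edfs,
}


@dataclass(frozen=True)
class FcdConfig:
    """Functional form and smoothing of the coupling measure.

    measure
        ``smoothed_pmi`` (default): ``log((co+b)(N+b) / ((cnt_e+b)(cnt_c+b)))``
        — PMI with additive smoothing, finite at co = 0.
        ``log_count_pmi``: the same ratio computed on log-damped counts
        ``l(x) = log(x+b)``, i.e. ``log((l(co)+b)(l(N)+b) /
        ((l(cnt_e)+b)(l(cnt_c)+b)))``, which compresses the dynamic range of
        very large corpora.
    b
        additive smoothing constant, default 1.
    """

    measure: str = "smoothed_pmi"
    b: float = 1.0
    fcd_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("smoothing factor b must be positive")
        types = self.fcd_types or (self.measure,)
        for t in types:
            if t not in MEASURES:
                raise ValueError(f"unknown FCD measure {t!r}")
        object.__setattr__(self, "fcd_types", tuple(types))


@dataclass
class CooccurrenceStore:
    """Example-level presence counts accumulated over an unlabeled corpus."""

    N: int = 0
    cnt_e: Counter = field(default_factory=Counter)
    cnt_c: Counter = field(default_factory=Counter)
    co: Counter = field(default_factory=Counter)

    def update(self, edf_keys: Iterable[str], cdf_keys: Iterable[str]) -> None:
        """Record one unlabeled example's Boolean presence sets."""
        edf_keys = set(edf_keys)
        cdf_keys = set(cdf_keys)
        self.N += 1
        for e in edf_keys:
            self.cnt_e[e] += 1
        for c in cdf_keys:
            self.cnt_c[c] += 1
        if cdf_keys:
            for e in edf_keys:
                for c in cdf_keys:
                    self.co[(e, c)] += 1

    def merge(self, other: "CooccurrenceStore") -> "CooccurrenceStore":
        """Add another shard's counts into this store (in place)."""
        self.N += other.N
        self.cnt_e.update(other.cnt_e)
        self.cnt_c.update(other.cnt_c)
        self.co.update(other.co)
        return self

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "meta.json").write_text(json.dumps({"N": self.N}))
        for name, counter in (("cnt_e", self.cnt_e), ("cnt_c", self.cnt_c)):
            with open(directory / f"{name}.tsv", "w", encoding="utf-8") as fh:
                for key in sorted(counter):
                    fh.write(f"{key}\t{counter[key]}\n")
        with open(directory / "co.tsv", "w", encoding="utf-8") as fh:
            for e, c in sorted(self.co):
                fh.write(f"{e}\t{c}\t{self.co[(e, c)]}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "CooccurrenceStore":
        directory = Path(directory)
        store = cls(N=json.loads((directory / "meta.json").read_text())["N"])
        for name, counter in (("cnt_e", store.cnt_e), ("cnt_c", store.cnt_c)):
            with open(directory / f"{name}.tsv", encoding="utf-8") as fh:
                for line in fh:
                    key, _, count = line.rstrip("\n").rpartition("\t")
                    counter[key] = int(count)
        with open(directory / "co.tsv", encoding="utf-8") as fh:
            for line in fh:
                e, c, count = line.rstrip("\n").split("\t")
                store.co[(e, c)] = int(count)
        return store


def count(
    unlabeled: Iterable[Example],
    cdfs: CdfSet | Iterable[str],
    families: Sequence[str] = ("sp",),
    edf_filter: set[str] | None = None,
    ds_targets: Sequence[Example] | None = None,
) -> CooccurrenceStore:
    """Count EDF/CDF presence over an unlabeled corpus.

    ``edf_filter`` restricts counting to EDF keys of interest (those
    occurring in the labelled/test examples whose vectors will be built);
    the resulting store is identical on those keys to an unrestricted one.
    For the DS family each unlabeled example emits similarity keys against
    ``ds_targets`` (the labelled + test examples).
    """
    from fcgppi.edf import ds_edfs, ds_vector  # local: avoids cycle at import

    cdf_keys = frozenset(cdfs.keys if isinstance(cdfs, CdfSet) else cdfs)
    store = CooccurrenceStore()
    target_vectors = None
    if "ds" in families:
        if ds_targets is None:
            raise ValueError("counting the ds family requires ds_targets")
        target_vectors = [ds_vector(t) for t in ds_targets]

    from fcgppi.lexical_features import ga_lex, sa_lex, sp_lex

    for ex in unlabeled:
        edf_keys: set[str] = set()
        sp_keys: set[str] | None = None
        for fam in families:
            if fam == "ds":
                edf_keys.update(
                    e.key
                    for e in ds_edfs(ex, ds_targets, target_vectors=target_vectors)
                )
            else:
                fam_keys = {e.key for e in FAMILY_EXTRACTORS[fam](ex)}
                if fam == "sp":
                    sp_keys = fam_keys
                edf_keys.update(fam_keys)
        if edf_filter is not None:
            edf_keys &= edf_filter
        # CDF presence = GA/SA/SP candidate keys; reuse the sp extraction
        candidates = ga_lex(ex) | sa_lex(ex) | (sp_keys if sp_keys is not None else sp_lex(ex))
        store.update(edf_keys, candidates & cdf_keys)
    return store


def fcd(
    store: CooccurrenceStore,
    e: str,
    c: str,
    config: FcdConfig = FcdConfig(),
    measure: str | None = None,
) -> float:
    """Feature coupling degree of EDF key *e* and CDF key *c*."""
    if store.N < 1:
        raise ValueError("co-occurrence store is empty (N=0)")
    return _fcd_counts(
        store.co.get((e, c), 0),
        store.cnt_e.get(e, 0),
        store.cnt_c.get(c, 0),
        store.N,
        config.b,
        measure or config.fcd_types[0],
    )


def _damp(measure: str, b: float) -> Callable[[float], float]:
    """Per-count term of the measure.  Both measures are separable:
    ``fcd = g(co) + g(N) - g(cnt_e) - g(cnt_c)`` with g below."""
    if measure == "smoothed_pmi":
        return lambda x: math.log(x + b)
    if measure == "log_count_pmi":
        return lambda x: math.log(math.log(x + b) + b)
    raise ValueError(f"unknown FCD measure {measure!r}")


def _fcd_counts(
    co: int, cnt_e: int, cnt_c: int, n: int, b: float, measure: str
) -> float:
    g = _damp(measure, b)
    return g(co) + g(n) - g(cnt_e) - g(cnt_c)


class FcdVectorizer:
    """Maps examples to coupling-feature vectors indexed by (root, CDF, type).

    The column layout concatenates the family blocks in the order given at
    construction; within a block, columns run over (root, cdf, measure) in
    row-major order.  Dimension = sum over families of
    ``len(roots) * len(cdfs) * len(measures)``.
    """

    def __init__(
        self,
        store: CooccurrenceStore,
        cdfs: CdfSet | Sequence[str],
        families: Sequence[str] = ("sp",),
        config: FcdConfig = FcdConfig(),
        normalize: bool = True,
        edf_filter: frozenset[str] | None = None,
    ) -> None:
        self.store = store
        self.edf_filter = edf_filter
        self.cdf_keys = list(cdfs.keys if isinstance(cdfs, CdfSet) else cdfs)
        missing = [c for c in self.cdf_keys if c not in store.cnt_c]
        if store.cnt_c and len(missing) == len(self.cdf_keys):
            raise ValueError(
                "CDF set shares no keys with the store; was the store counted "
                "with a different CDF set?"
            )
        self.families = tuple(families)
        self.config = config
        self.normalize = normalize
        self._columns: dict[tuple[str, str, str], int] = {}
        for fam in self.families:
            for root in FAMILY_ROOTS[fam]:
                for c in self.cdf_keys:
                    for t in config.fcd_types:
                        self._columns[(root, c, t)] = len(self._columns)
        self._prepare()

    def _prepare(self) -> None:
        """Precompute what the separable measures allow.

        For g = the measure's damping, FCD(e, c) = g(co) + g(N) - g(cnt_e)
        - g(cnt_c).  Summing over the EDFs of one root therefore splits
        into a per-root baseline (k_h terms of g(0) + g(N) - g(cnt_c),
        minus the sum of g(cnt_e)) plus corrections g(co) - g(0) on the
        sparse co > 0 pairs only.
        """
        b = self.config.b
        n = self.store.N
        self._g = {t: _damp(t, b) for t in self.config.fcd_types}
        self._g0 = {t: g(0) for t, g in self._g.items()}
        # per (cdf, type): g(N) - g(cnt_c), the column-constant part
        self._col_const = {
            (c, t): g(n) - g(self.store.cnt_c.get(c, 0))
            for c in self.cdf_keys
            for t, g in self._g.items()
        }
        cdf_pos = {c: i for i, c in enumerate(self.cdf_keys)}
        # EDF key -> [(cdf position, co count), ...] for co > 0 pairs
        self._co_index: dict[str, list[tuple[int, int]]] = {}
        for (e, c), joint in self.store.co.items():
            pos = cdf_pos.get(c)
            if pos is not None:
                self._co_index.setdefault(e, []).append((pos, joint))
        self._n_types = len(self.config.fcd_types)
        self._root_offset: dict[str, int] = {}
        if self.cdf_keys:
            first = (self.cdf_keys[0], self.config.fcd_types[0])
            for (root, c, t), col in self._columns.items():
                if (c, t) == first:
                    self._root_offset[root] = col
        # baseline row per column: g(N) - g(cnt_c); the g(0) of the co term
        # and the -g(0) of the cnt_e term cancel, leaving corrections of
        # g(count) - g(0) only where a count is nonzero.
        self._base_row = np.array(
            [
                self._col_const[(c, t)]
                for c in self.cdf_keys
                for t in self.config.fcd_types
            ]
        )

    @property
    def dimension(self) -> int:
        return len(self._columns)

    def column_index(self, root: str, cdf: str, measure: str) -> int:
        return self._columns[(root, cdf, measure)]

    def example_edfs(self, example: Example) -> list[Edf]:
        edfs: list[Edf] = []
        for fam in self.families:
            edfs.extend(FAMILY_EXTRACTORS[fam](example))
        if self.edf_filter is not None:
            edfs = [e for e in edfs if e.key in self.edf_filter]
        return edfs

    def transform_one(self, example: Example) -> np.ndarray:
        """Dense FCD vector for one example (zero when it has no EDFs)."""
        vec = np.zeros(self.dimension)
        if not self.cdf_keys:
            return vec
        cnt_e = self.store.cnt_e
        block = len(self._base_row)
        g = self._g
        g0 = self._g0
        types = self.config.fcd_types
        n_types = self._n_types
        seen: set[str] = set()
        for edf in self.example_edfs(example):
            if edf.key in seen:
                continue
            seen.add(edf.key)
            off = self._root_offset[edf.root]
            sl = vec[off : off + block]
            sl += self._base_row
            ce = cnt_e.get(edf.key, 0)
            if ce:
                for k, t in enumerate(types):
                    sl[k::n_types] -= g[t](ce) - g0[t]
            for pos, joint in self._co_index.get(edf.key, ()):
                for k, t in enumerate(types):
                    sl[pos * n_types + k] += g[t](joint) - g0[t]
        if self.normalize:
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
        return vec

    def transform(self, examples: Sequence[Example]) -> np.ndarray:
        """Stacked FCD matrix, one row per example."""
        if not examples:
            return np.zeros((0, self.dimension))
        return np.vstack([self.transform_one(ex) for ex in examples])


def build_fcd_vector(
    example: Example,
    store: CooccurrenceStore,
    cdfs: CdfSet | Sequence[str],
    families: Sequence[str] = ("sp",),
    config: FcdConfig = FcdConfig(),
    normalize: bool = True,
    edf_filter: frozenset[str] | None = None,
) -> np.ndarray:
    """One-shot convenience wrapper around :class:`FcdVectorizer`."""
    return FcdVectorizer(
        store, cdfs, families, config, normalize, edf_filter
    ).transform_one(example)
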