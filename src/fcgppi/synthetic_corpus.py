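"""Synthetic labelled/unlabeled corpora with a controllable sparsity regime.

The generator emulates the situation feature coupling is designed for:
*trigger* n-grams that decide the interaction label are each confined to a
single abstract and occur only a handful of times in labelled data — so
abstract-wise cross-validation guarantees a supervised learner never sees a
test trigger at training time — while the same triggers are abundant in the
unlabeled corpus, where they co-occur with common *cue* words.  The cues
are frequent enough in labelled data to be picked up as CDFs, so the
trigger -> cue co-occurrence statistics are the only channel through which
the unlabeled corpus can help.

Sentence skeleton: left filler, ``prot1``, inner filler with the optional
trigger adjacent to prot1 and the optional cue adjacent to prot2,
``prot2``, right filler.  Filler lengths are drawn per sentence so every
area/offset code path (including empty areas) is exercised; an occasional
``prot0`` mention is planted in the filler.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from fcgppi.corpus_io import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    LABEL_UNLABELED,
    PROT0,
    PROT1,
    PROT2,
    Example,
)


@dataclass(frozen=True)
class TriggerPattern:
    """An n-gram planted at a fixed position relative to a protein.

    Only the ``P1_Right`` placement (n-gram starting immediately after
    prot1) is generated; it yields stable ``m_From_P1`` offset keys
    regardless of the protein distance.
    """

    tokens: tuple[str, ...]
    placement: str = "P1_Right"

    def sp_keys(self) -> list[str]:
        """The prot1-anchored offset keys this pattern always produces."""
        keys = []
        for i in range(len(self.tokens)):
            for n in range(1, i + 2):
                ngram = " ".join(self.tokens[i - n + 1 : i + 1])
                keys.append(f"{i + 1}_From_P1={ngram}")
        return keys


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give the sparse-trigger regime.

    ``trigger_freq_labeled`` is the *expected* number of labelled
    occurrences of each trigger (actual counts vary Poisson-like since
    labels are drawn per sentence); each trigger lives in exactly one
    abstract.  ``trigger_freq_unlabeled`` is the expected occurrences of
    each trigger in the full unlabeled corpus.
    """

    vocab_size: int = 300
    n_abstracts: int = 100
    sentences_per_abstract: int = 6
    n_unlabeled: int = 100_000
    n_triggers: int = 100
    trigger_patterns: tuple[TriggerPattern, ...] | None = None
    trigger_freq_labeled: float = 2.0
    trigger_freq_unlabeled: float = 1000.0
    cue_words: tuple[str, ...] = ("cuea", "cueb")
    cue_pos_rate: float = 0.5
    cue_neg_rate: float = 0.1
    cue_given_trigger: float = 0.9
    cue_background: float = 0.05
    noise_rate: float = 0.0
    prot0_rate: float = 0.1
    left_len: tuple[int, int] = (0, 4)
    inner_len: tuple[int, int] = (3, 7)
    right_len: tuple[int, int] = (0, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5)")
        for name in ("vocab_size", "n_abstracts", "sentences_per_abstract", "n_triggers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trigger_patterns is None:
            self.trigger_patterns = tuple(
                TriggerPattern((f"tga{i:03d}", f"tgb{i:03d}"))
                for i in range(self.n_triggers)
            )
        else:
            self.trigger_patterns = tuple(self.trigger_patterns)
            self.n_triggers = len(self.trigger_patterns)
        max_trigger = max(len(p.tokens) for p in self.trigger_patterns)
        if max_trigger + 1 > self.inner_len[0]:
            raise ValueError(
                "inner area too short: the longest trigger plus the cue slot "
                f"needs {max_trigger + 1} tokens, inner_len starts at {self.inner_len[0]}"
            )

    @property
    def positive_rate(self) -> float:
        return min(0.9, self.trigger_freq_labeled / self.sentences_per_abstract)

    @property
    def trigger_rate_unlabeled(self) -> float:
        """Per-sentence probability that an unlabeled sentence carries a trigger."""
        return min(
            0.9, self.n_triggers * self.trigger_freq_unlabeled / self.n_unlabeled
        )


@dataclass
class SynthCorpus:
    labeled: list[Example]
    unlabeled: list[Example]
    truth: dict


def _draw_lengths(rng, bounds: tuple[int, int], n: int) -> np.ndarray:
    lo, hi = bounds
    return rng.integers(lo, hi + 1, n)


def _build_sentences(
    cfg: SynthConfig,
    rng: np.random.Generator,
    n: int,
    has_trigger: np.ndarray,
    trigger_ids: np.ndarray,
    has_cue: np.ndarray,
    doc_ids: Sequence[str],
    labels: Sequence[str],
    id_prefix: str,
) -> list[Example]:
    vocab = np.array([f"w{i:03d}" for i in range(cfg.vocab_size)])
    left = _draw_lengths(rng, cfg.left_len, n)
    inner = _draw_lengths(rng, cfg.inner_len, n)
    right = _draw_lengths(rng, cfg.right_len, n)
    total_fill = int(left.sum() + inner.sum() + right.sum())
    fill_words = vocab[rng.integers(0, cfg.vocab_size, total_fill)]
    has_prot0 = rng.random(n) < cfg.prot0_rate

    out: list[Example] = []
    pos = 0
    for idx in range(n):
        nl, ni, nr = int(left[idx]), int(inner[idx]), int(right[idx])
        lw = list(fill_words[pos : pos + nl]); pos += nl
        iw = list(fill_words[pos : pos + ni]); pos += ni
        rw = list(fill_words[pos : pos + nr]); pos += nr
        if has_trigger[idx]:
            pat = cfg.trigger_patterns[int(trigger_ids[idx])]
            iw[: len(pat.tokens)] = list(pat.tokens)
        if has_cue[idx]:
            iw[-1] = cfg.cue_words[idx % len(cfg.cue_words)]
        if has_prot0[idx] and nr >= 1:
            rw[0] = PROT0
        tokens = (*lw, PROT1, *iw, PROT2, *rw)
        i1 = nl
        out.append(
            Example(
                f"{id_prefix}{idx}",
                doc_ids[idx],
                tokens,
                i1,
                i1 + ni + 1,
                labels[idx],
            )
        )
    return out


def generate(config: SynthConfig) -> SynthCorpus:
    """Generate labelled and unlabeled corpora plus the ground truth.

    Returns labelled examples grouped into abstracts (trigger *i* confined
    to abstract *i*), an unlabeled corpus sharing the trigger -> cue
    co-occurrence structure but no labels, and a truth record listing the
    planted patterns.
    """
    rng = np.random.default_rng(config.seed)
    n_lab = config.n_abstracts * config.sentences_per_abstract

    # labelled corpus: true label decides trigger presence
    is_pos = rng.random(n_lab) < config.positive_rate
    doc_of = np.repeat(np.arange(config.n_abstracts), config.sentences_per_abstract)
    trig_ids = doc_of % config.n_triggers
    cue_draw = rng.random(n_lab)
    has_cue = np.where(is_pos, cue_draw < config.cue_pos_rate, cue_draw < config.cue_neg_rate)
    flipped = rng.random(n_lab) < config.noise_rate
    observed_pos = is_pos ^ flipped
    labels = [LABEL_POSITIVE if p else LABEL_NEGATIVE for p in observed_pos]
    labeled = _build_sentences(
        config,
        rng,
        n_lab,
        has_trigger=is_pos,
        trigger_ids=trig_ids,
        has_cue=has_cue,
        doc_ids=[f"abs{int(d):04d}" for d in doc_of],
        labels=labels,
        id_prefix="L",
    )

    # unlabeled corpus: no labels, only the trigger -> cue coupling
    n_unl = config.n_unlabeled
    has_trig_u = rng.random(n_unl) < config.trigger_rate_unlabeled
    trig_ids_u = rng.integers(0, config.n_triggers, n_unl)
    cue_draw_u = rng.random(n_unl)
    has_cue_u = np.where(
        has_trig_u,
        cue_draw_u < config.cue_given_trigger,
        cue_draw_u < config.cue_background,
    )
    unlabeled = _build_sentences(
        config,
        rng,
        n_unl,
        has_trigger=has_trig_u,
        trigger_ids=trig_ids_u,
        has_cue=has_cue_u,
        doc_ids=[f"unl{i}" for i in range(n_unl)],
        labels=[LABEL_UNLABELED] * n_unl,
        id_prefix="U",
    )

    truth = {
        "trigger_patterns": [list(p.tokens) for p in config.trigger_patterns],
        "trigger_sp_keys": sorted(
            {k for p in config.trigger_patterns for k in p.sp_keys()}
        ),
        "cue_words": list(config.cue_words),
        "trigger_abstract": {
            f"abs{a:04d}": int(a % config.n_triggers) for a in range(config.n_abstracts)
        },
        "n_positive_true": int(is_pos.sum()),
        "positive_rate": config.positive_rate,
    }
    return SynthCorpus(labeled, unlabeled, truth)


def feature_counts(feature_sets: Iterable[set[str]]) -> Counter:
    """Example-level presence counts of every feature key."""
    counts: Counter = Counter()
    for feats in feature_sets:
        counts.update(feats)
    return counts


def frequency_filter(
    feature_sets: Sequence[set[str]],
    max_count: int | None,
    counts: Counter | None = None,
) -> list[set[str]]:
    """Keep only features occurring in at most *max_count* examples.

    ``max_count=None`` is the identity; ``max_count=0`` empties every set.
    Used to probe how much of the signal lives in the sparse tail of the
    feature distribution.
    """
    if max_count is None:
        return [set(s) for s in feature_sets]
    if counts is None:
        counts = feature_counts(feature_sets)
    return [{f for f in s if counts[f] <= max_count} for s in feature_sets]
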