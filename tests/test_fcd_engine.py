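"""Co-occurrence store, FCD measure and the coupling-feature transform."""

import math
from collections import Counter

import numpy as np
import pytest

from fcgppi.corpus_io import make_example
from fcgppi.edf import CP_ROOTS, SP_ROOTS
from fcgppi.fcd_engine import (
    FAMILY_EXTRACTORS,
    CooccurrenceStore,
    FcdConfig,
    FcdVectorizer,
    build_fcd_vector,
    count,
    fcd,
)
from fcgppi.lexical_features import cdf_candidates
from fcgppi.synthetic_corpus import SynthConfig, generate


def brute_force_fcd_vector(example, store, cdf_keys, families, config):
    """Independent oracle: literal double loop over (EDF, CDF) pairs."""

    def fcd_value(e, c):
        b = config.b
        if config.fcd_types[0] == "smoothed_pmi":
            g = lambda x: math.log(x + b)
        else:
            g = lambda x: math.log(math.log(x + b) + b)
        return (
            g(store.co.get((e, c), 0))
            + g(store.N)
            - g(store.cnt_e.get(e, 0))
            - g(store.cnt_c.get(c, 0))
        )

    from fcgppi.edf import CP_ROOTS, DS_ROOTS, SP_ROOTS

    roots = {"sp": SP_ROOTS, "cp": CP_ROOTS, "ds": DS_ROOTS}
    vec = []
    for fam in families:
        edfs = {e.key: e.root for e in FAMILY_EXTRACTORS[fam](example)}
        for root in roots[fam]:
            for c in cdf_keys:
                for t in config.fcd_types:
                    vec.append(
                        sum(fcd_value(e, c) for e, r in edfs.items() if r == root)
                    )
    return np.array(vec)


def _random_store(rng, edf_keys, cdf_keys, n=50):
    """A store consistent with counting n examples (co <= marginals <= N)."""
    store = CooccurrenceStore(N=n)
    for e in edf_keys:
        store.cnt_e[e] = int(rng.integers(0, n + 1))
    for c in cdf_keys:
        store.cnt_c[c] = int(rng.integers(0, n + 1))
    for e in edf_keys:
        for c in cdf_keys:
            hi = min(store.cnt_e[e], store.cnt_c[c])
            joint = int(rng.integers(0, hi + 1))
            if joint:
                store.co[(e, c)] = joint
    return store


class TestStore:
    def test_single_example(self):
        store = CooccurrenceStore()
        store.update({"e1"}, {"c1"})
        assert store.N == 1
        assert store.cnt_e["e1"] == 1
        assert store.cnt_c["c1"] == 1
        assert store.co[("e1", "c1")] == 1

    def test_presence_is_boolean(self):
        store = CooccurrenceStore()
        store.update(["e1", "e1"], ["c1", "c1"])
        assert store.cnt_e["e1"] == 1 and store.co[("e1", "c1")] == 1

    def test_shard_merge_equals_single_pass(self):
        corpus = generate(SynthConfig(n_unlabeled=400, n_abstracts=10, n_triggers=10, seed=5))
        cdfs = ["Inner_Area=cuea", "P2_Left=cueb", "-1_From_P2=cuea"]
        whole = count(corpus.unlabeled, cdfs, families=("sp",))
        merged = count(corpus.unlabeled[:150], cdfs, families=("sp",))
        merged.merge(count(corpus.unlabeled[150:], cdfs, families=("sp",)))
        assert merged.N == whole.N
        assert merged.cnt_e == whole.cnt_e
        assert merged.cnt_c == whole.cnt_c
        assert merged.co == whole.co

    def test_counts_match_quadratic_oracle(self):
        corpus = generate(SynthConfig(n_unlabeled=50, n_abstracts=10, n_triggers=10, seed=2))
        cdfs = ["Inner_Area=cuea", "P2_Left=cueb"]
        store = count(corpus.unlabeled, cdfs, families=("sp",))
        expected = CooccurrenceStore()
        for ex in corpus.unlabeled:
            edfs = {e.key for e in FAMILY_EXTRACTORS["sp"](ex)}
            present = {c for c in cdfs if c in cdf_candidates(ex)}
            expected.N += 1
            for e in edfs:
                expected.cnt_e[e] += 1
            for c in present:
                expected.cnt_c[c] += 1
            for e in edfs:
                for c in present:
                    expected.co[(e, c)] += 1
        assert store.N == expected.N
        assert store.cnt_e == expected.cnt_e
        assert store.cnt_c == expected.cnt_c
        assert store.co == expected.co

    def test_empty_corpus(self):
        store = count([], ["c1"], families=("sp",))
        assert store.N == 0 and not store.cnt_e

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        store = _random_store(rng, ["e1", "e 2"], ["c1", "c2"])
        store.save(tmp_path / "store")
        back = CooccurrenceStore.load(tmp_path / "store")
        assert (back.N, back.cnt_e, back.cnt_c, back.co) == (
            store.N,
            store.cnt_e,
            store.cnt_c,
            store.co,
        )


class TestFcdMeasure:
    @pytest.mark.parametrize("measure", ["smoothed_pmi", "log_count_pmi"])
    def test_finite_at_zero_cooccurrence(self, measure):
        store = CooccurrenceStore(N=100, cnt_e=Counter(e=10), cnt_c=Counter(c=20))
        value = fcd(store, "e", "c", FcdConfig(measure=measure))
        assert math.isfinite(value)

    @pytest.mark.parametrize("measure", ["smoothed_pmi", "log_count_pmi"])
    def test_strictly_increasing_in_co(self, measure):
        cfg = FcdConfig(measure=measure)
        store = CooccurrenceStore(N=1000, cnt_e=Counter(e=50), cnt_c=Counter(c=80))
        values = []
        for joint in range(0, 50, 7):
            store.co[("e", "c")] = joint
            values.append(fcd(store, "e", "c", cfg))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_closed_form_value(self):
        # hand-built store: N=8, cnt_e=4, cnt_c=2, co=1, b=1
        store = CooccurrenceStore(
            N=8, cnt_e=Counter(e=4), cnt_c=Counter(c=2), co=Counter({("e", "c"): 1})
        )
        expected = math.log((1 + 1) * (8 + 1) / ((4 + 1) * (2 + 1)))
        assert fcd(store, "e", "c") == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments_with_marginals(self):
        store = CooccurrenceStore(
            N=30,
            cnt_e=Counter({"x": 5, "y": 9}),
            cnt_c=Counter({"x": 5, "y": 9}),
            co=Counter({("x", "y"): 3, ("y", "x"): 3}),
        )
        assert fcd(store, "x", "y") == pytest.approx(fcd(store, "y", "x"))

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError):
            fcd(CooccurrenceStore(), "e", "c")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FcdConfig(b=0)
        with pytest.raises(ValueError):
            FcdConfig(measure="nonsense")


class TestFcdVector:
    def test_no_edfs_gives_zero_vector(self):
        ex = make_example(["prot1", "x", "prot2"], "unlabeled", example_id="z")
        store = CooccurrenceStore(N=5)
        vec = build_fcd_vector(
            ex, store, ["c1"], families=("sp",), edf_filter=frozenset()
        )
        assert vec.shape == (3,)
        assert not vec.any()

    def test_single_edf_single_cdf_block(self, short_example):
        store = CooccurrenceStore(N=10, cnt_e=Counter(), cnt_c=Counter())
        vec = build_fcd_vector(
            short_example, store, ["c1"], families=("cp",), normalize=False
        )
        assert vec.shape == (len(CP_ROOTS),)
        # prot1 has left context and prot2 right context, so all four side
        # pairs exist; each coordinate sums its root's EDFs
        assert np.all(vec != 0)

    @pytest.mark.parametrize("measure", ["smoothed_pmi", "log_count_pmi"])
    def test_matches_brute_force_oracle(self, measure, table1_example, short_example):
        rng = np.random.default_rng(11)
        cfg = FcdConfig(measure=measure)
        for ex in (table1_example, short_example):
            edf_keys = sorted(
                {e.key for fam in ("sp", "cp") for e in FAMILY_EXTRACTORS[fam](ex)}
            )
            cdf_keys = ["c1", "c2"]
            store = _random_store(rng, edf_keys[:40], cdf_keys)
            got = build_fcd_vector(
                ex, store, cdf_keys, families=("sp", "cp"), config=cfg, normalize=False
            )
            want = brute_force_fcd_vector(ex, store, cdf_keys, ("sp", "cp"), cfg)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_linearity_over_disjoint_edf_sets(self, table1_example):
        # restricting the EDF set partitions the (pre-normalisation) sum
        rng = np.random.default_rng(4)
        all_keys = sorted({e.key for e in FAMILY_EXTRACTORS["sp"](table1_example)})
        half = len(all_keys) // 2
        store = _random_store(rng, all_keys, ["c1"])
        kw = dict(cdfs=["c1"], families=("sp",), store=store, normalize=False)
        full = build_fcd_vector(table1_example, **kw)
        part_a = build_fcd_vector(
            table1_example, edf_filter=frozenset(all_keys[:half]), **kw
        )
        part_b = build_fcd_vector(
            table1_example, edf_filter=frozenset(all_keys[half:]), **kw
        )
        np.testing.assert_allclose(full, part_a + part_b, atol=1e-10)

    def test_dimension_bookkeeping(self, table1_example):
        store = CooccurrenceStore(N=3)
        cdfs = ["c1", "c2", "c3"]
        vec = FcdVectorizer(store, cdfs, families=("sp", "cp", "ds"))
        assert vec.dimension == (3 + 4 + 1) * 3 * 1

    def test_normalized_vector_has_unit_norm(self, table1_example):
        rng = np.random.default_rng(9)
        keys = sorted({e.key for e in FAMILY_EXTRACTORS["sp"](table1_example)})
        store = _random_store(rng, keys, ["c1", "c2"])
        vec = build_fcd_vector(table1_example, store, ["c1", "c2"], families=("sp",))
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_mismatched_cdf_set_rejected(self):
        store = CooccurrenceStore(N=10, cnt_c=Counter({"other": 3}))
        with pytest.raises(ValueError, match="CDF set"):
            FcdVectorizer(store, ["c1", "c2"], families=("sp",))
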