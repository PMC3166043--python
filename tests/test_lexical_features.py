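"""Positional n-gram feature families and the distance buckets."""

import itertools

import pytest

from fcgppi.corpus_io import make_example
from fcgppi.lexical_features import (
    ALL_FAMILIES,
    DISTANCE_BUCKETS,
    cp_lex,
    discretize_distance,
    extract_lexical,
    extract_ngrams,
    ga_bow,
    ga_lex,
    general_areas,
    sa_lex,
    sp_lex,
    surrounding_areas,
)


def enumerate_span_ngrams(tokens, start, stop, n_max=3):
    """Brute-force oracle: every n-gram whose tokens all lie in [start, stop]."""
    out = []
    for i in range(max(0, start), min(stop, len(tokens) - 1) + 1):
        for j in range(i, min(i + n_max - 1, stop) + 1):
            out.append((" ".join(tokens[i : j + 1]), j))
    return sorted(out)


class TestNgrams:
    def test_two_token_span(self):
        grams = extract_ngrams(["the", "results"], (0, 1))
        assert sorted(g for g, _ in grams) == ["results", "the", "the results"]

    @pytest.mark.parametrize("k", range(2, 8))
    def test_count_closed_form(self, k):
        tokens = [f"w{i}" for i in range(k)]
        grams = extract_ngrams(tokens, (0, k - 1))
        assert len(grams) == 3 * k - 3
        assert sorted(grams) == enumerate_span_ngrams(tokens, 0, k - 1)

    def test_empty_span(self):
        assert extract_ngrams(["a", "b"], (1, 0)) == []


class TestDistanceBuckets:
    @pytest.mark.parametrize("d,bucket", [(5, "5"), (7, "6~7"), (40, "31~40"), (41, "40~")])
    def test_boundaries(self, d, bucket):
        assert discretize_distance(d) == bucket

    def test_partition_and_monotone_over_0_to_100(self):
        order = {b: i for i, b in enumerate(DISTANCE_BUCKETS)}
        seen = [order[discretize_distance(d)] for d in range(101)]
        assert seen == sorted(seen)
        assert set(seen) == set(range(len(DISTANCE_BUCKETS)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            discretize_distance(-1)


class TestGeneralAreaFeatures:
    def test_ga_bow_left_area_word(self):
        ex = make_example(["expression", "of", "prot1", "binds", "prot2"], "positive")
        assert "Left_Area=expression" in ga_bow(ex)

    def test_empty_left_area(self):
        ex = make_example(["prot1", "binds", "prot2"], "positive")
        assert not any(f.startswith("Left_Area=") for f in ga_bow(ex) | ga_lex(ex))

    def test_ga_lex_matches_enumeration_oracle(self, table1_example):
        ex = table1_example
        expected = set()
        for area, (start, stop) in general_areas(ex).items():
            for ngram, _ in enumerate_span_ngrams(ex.tokens, start, stop):
                expected.add(f"{area}={ngram}")
        assert ga_lex(ex) == expected


class TestSurroundingAreaFeatures:
    def test_example_key(self, short_example):
        assert "P1_Right=interacts with" in sa_lex(short_example)

    def test_keys_start_with_sa_names(self, table1_example):
        prefixes = ("P1_Left=", "P1_Right=", "P2_Left=", "P2_Right=")
        assert all(f.startswith(prefixes) for f in sa_lex(table1_example))

    def test_adjacent_pair_clips_windows(self):
        # i2 - i1 = 1: all four windows exist but the inner-derived parts are empty
        ex = make_example(["a", "b", "prot1", "prot2", "c", "d"], "negative")
        expected = set()
        for area, (start, stop) in surrounding_areas(ex).items():
            for ngram, _ in enumerate_span_ngrams(ex.tokens, start, stop):
                expected.add(f"{area}={ngram}")
        feats = sa_lex(ex)
        assert feats == expected
        assert "P1_Right=prot2" in feats  # window crosses the other protein


class TestSpecificPositionFeatures:
    def test_interacts_with_offsets(self, short_example):
        feats = sp_lex(short_example)
        for key in (
            "1_From_P1=interacts",
            "2_From_P1=with",
            "-1_From_P2=with",
            "2_From_P1=interacts with",
        ):
            assert key in feats

    def test_both_protein_offsets_for_one_token(self, table1_example):
        feats = sp_lex(table1_example)
        assert "-4_From_P1=the" in feats and "-9_From_P2=the" in feats

    def test_window_boundary(self):
        tokens = [f"w{i}" for i in range(8)] + ["prot1", "x", "prot2"]
        ex = make_example(tokens, "negative")
        feats = sp_lex(ex)
        assert "-5_From_P1=w3" in feats  # x = i1 - 5 included
        assert "-6_From_P1=w2" not in feats  # x = i1 - 6 excluded

    def test_offset_within_window_for_some_protein(self, table1_example):
        ex = table1_example
        for key in sp_lex(ex):
            scope, _, _ = key.partition("=")
            offset = int(scope.split("_")[0])
            x = offset + (ex.i1 if "From_P1" in scope else ex.i2)
            assert min(abs(x - ex.i1), abs(x - ex.i2)) <= 5

    def test_paired_offsets_differ_by_distance(self, table1_example):
        ex = table1_example
        feats = sp_lex(ex)
        by_ngram = {}
        for key in feats:
            scope, _, ngram = key.partition("=")
            offset, anchor = int(scope.split("_")[0]), scope.split("_From_")[1]
            by_ngram.setdefault(ngram, {})[anchor] = offset
        for ngram, offs in by_ngram.items():
            if {"P1", "P2"} <= set(offs):
                assert offs["P2"] == offs["P1"] - ex.distance


class TestConjunctFeatures:
    def test_component_split_is_lossless(self, table1_example):
        sp_keys = sp_lex(table1_example)
        for key in cp_lex(table1_example):
            left, mid, bucket = key.split("^")
            assert left.startswith(("P1_Left=", "P1_Right="))
            assert mid.startswith(("P2_Left=", "P2_Right="))
            assert bucket == discretize_distance(table1_example.distance)
            # each side is an adjacency that also exists as an SP n-gram
            for part, (anchor, side) in ((left, ("P1", left)), (mid, ("P2", mid))):
                name, _, ngram = part.partition("=")
                n = ngram.count(" ") + 1
                offset = -1 if name.endswith("Left") else n
                assert f"{offset}_From_{anchor}={ngram}" in sp_keys

    def test_no_left_side_when_prot1_first(self):
        ex = make_example(["prot1", "binds", "prot2", "end"], "positive")
        assert all(k.startswith("P1_Right=") for k in cp_lex(ex))


class TestExtractLexical:
    def test_union_of_families(self, table1_example):
        per_family = [
            ga_bow(table1_example),
            ga_lex(table1_example),
            sa_lex(table1_example),
            sp_lex(table1_example),
            cp_lex(table1_example),
        ]
        assert extract_lexical(table1_example, ALL_FAMILIES) == set().union(*per_family)
        assert extract_lexical(table1_example, ()) == set()
        assert extract_lexical(table1_example, ("F1",)) <= extract_lexical(
            table1_example, ("F1", "F2")
        )

    def test_pure_and_deterministic(self, table1_example):
        assert extract_lexical(table1_example) == extract_lexical(table1_example)

    def test_unknown_family_rejected(self, table1_example):
        with pytest.raises(ValueError):
            extract_lexical(table1_example, ("F9",))
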