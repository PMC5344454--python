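import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abstractqual.corpus import Document
from abstractqual.features import (
    baseline_metrics,
    count_syllables,
    feature_panel,
    feature_table,
    flesch_score,
    herdan_c,
    ngram_table,
    syntactic_proportions,
)
from abstractqual._text import porter_stem


class TestBaselineMetrics:
    def test_toy_text(self, toy_doc):
        p = baseline_metrics(toy_doc)
        assert p.chars_per_word == pytest.approx(3.0)
        assert p.words_per_sentence == pytest.approx(3.0)
        assert p.sentences_per_100_words == pytest.approx(100 * 2 / 6)
        assert p.word_count == 6

    def test_single_letter_word(self):
        doc = Document.from_text("a", "A")
        p = baseline_metrics(doc)
        assert p.chars_per_word == 1.0
        assert p.word_count == 1
        assert doc.n_sentences == 1

    def test_chars_identity(self, six_word_doc):
        p = baseline_metrics(six_word_doc)
        assert p.chars_per_100_words == pytest.approx(100 * p.chars_per_word)

    def test_zero_tokens_error(self):
        doc = Document(id="x", text="...", tokens=[], sentences=[])
        with pytest.raises(ValueError):
            baseline_metrics(doc)

    def test_duplication_invariance(self, toy_doc):
        double = Document.from_text("d", toy_doc.text + " " + toy_doc.text)
        a, b = baseline_metrics(toy_doc), baseline_metrics(double)
        assert b.chars_per_word == pytest.approx(a.chars_per_word)
        assert b.words_per_sentence == pytest.approx(a.words_per_sentence)
        assert b.word_count == 2 * a.word_count  # additive over concatenation


class TestSyntacticProportions:
    def _doc(self, pos):
        return Document(
            id="p", text="x", tokens=["w"] * len(pos),
            sentences=[(0, len(pos))], pos=pos,
        )

    def test_hand_ratio(self):
        noun, verb, conj = syntactic_proportions(
            self._doc(["NOUN", "NOUN", "VERB", "OTHER"])
        )
        assert (noun, verb, conj) == (50.0, 25.0, 0.0)

    def test_all_noun(self):
        assert syntactic_proportions(self._doc(["NOUN"] * 5)) == (100.0, 0.0, 0.0)

    def test_partition_sums_to_100(self, rng):
        pos = list(rng.choice(["NOUN", "VERB", "CONJ", "OTHER"], size=50))
        noun, verb, conj = syntactic_proportions(self._doc(pos))
        other = 100.0 * pos.count("OTHER") / 50
        assert noun + verb + conj + other == pytest.approx(100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            syntactic_proportions(self._doc([]))


class TestSyllables:
    @pytest.mark.parametrize(
        "word,n",
        [
            ("cat", 1), ("table", 2), ("e", 1), ("same", 1), ("beautiful", 3),
            ("patient", 2), ("study", 2), ("randomized", 4), ("free", 1),
        ],
    )
    def test_known_words(self, word, n):
        assert count_syllables(word) == n

    def test_no_letters_error(self):
        with pytest.raises(ValueError):
            count_syllables("123")

    @given(st.from_regex(r"[a-zA-Z]{1,15}", fullmatch=True))
    def test_at_least_one(self, word):
        assert count_syllables(word) >= 1


class TestFlesch:
    def test_six_word_fixture(self, six_word_doc):
        assert flesch_score(six_word_doc) == pytest.approx(116.145, abs=1e-9)

    def test_duplication_invariance(self, six_word_doc):
        double = Document.from_text("d", six_word_doc.text + " " + six_word_doc.text)
        assert flesch_score(double) == pytest.approx(flesch_score(six_word_doc))

    def test_longer_words_decrease_score(self):
        short = Document.from_text("s", "The cat sat on the mat.")
        long = Document.from_text("l", "Responsibilities necessitate considerable deliberation always now.")
        assert flesch_score(long) < flesch_score(short)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            flesch_score(Document(id="x", text="", tokens=[], sentences=[]))


class TestHerdanC:
    def test_all_distinct(self):
        assert herdan_c(["a", "b", "c", "d"]) == pytest.approx(1.0, abs=1e-9)

    def test_single_type(self):
        assert herdan_c(["word"] * 10) == pytest.approx(0.0, abs=1e-9)

    def test_formula_value(self):
        tokens = [f"t{i}" for i in range(50)] * 2  # N=100, V=50
        assert herdan_c(tokens) == pytest.approx(
            math.log(50) / math.log(100), abs=1e-9
        )

    def test_undefined_small(self):
        with pytest.raises(ValueError):
            herdan_c(["one"])

    def test_case_insensitive(self):
        assert herdan_c(["The", "the", "cat"]) == pytest.approx(
            math.log(2) / math.log(3)
        )

    @given(
        st.lists(st.sampled_from("abcdefgh"), min_size=2, max_size=200)
    )
    def test_matches_brute_force(self, tokens):
        brute = math.log(len(set(tokens))) / math.log(len(tokens))
        assert herdan_c(tokens) == pytest.approx(brute, abs=1e-12)


class TestPorterStemmer:
    @pytest.mark.parametrize(
        "word,stem",
        [
            ("caresses", "caress"), ("ponies", "poni"), ("cats", "cat"),
            ("feed", "feed"), ("agreed", "agre"), ("plastered", "plaster"),
            ("motoring", "motor"), ("sing", "sing"), ("conflated", "conflat"),
            ("troubled", "troubl"), ("sized", "size"), ("hopping", "hop"),
            ("happy", "happi"), ("relational", "relat"), ("conditional", "condit"),
            ("randomized", "random"), ("assigned", "assign"),
            ("difference", "differ"), ("studies", "studi"),
            ("significantly", "significantli"), ("generalization", "gener"),
        ],
    )
    def test_reference_vectors(self, word, stem):
        assert porter_stem(word) == stem


def _doc_from_tokens(tokens, doc_id="d"):
    text = " ".join(tokens)
    return Document(
        id=doc_id, text=text, tokens=list(tokens), sentences=[(0, len(tokens))]
    )


class TestNGrams:
    def test_bigram_enumeration(self):
        doc = _doc_from_tokens(["a", "b", "a", "b"])
        tab = ngram_table([doc], n=2, top_k=10, stem=False, drop_stop_words=False)
        assert tab.entries == [("a b", 2), ("b a", 1)]

    def test_single_word_corpus(self):
        doc = _doc_from_tokens(["word"])
        tab = ngram_table([doc], n=1, top_k=20, stem=False, drop_stop_words=False)
        assert tab.entries == [("word", 1)]

    def test_top_k_truncation(self, rng):
        tokens = [f"w{i}" for i in range(50)]
        tab = ngram_table(
            [_doc_from_tokens(tokens)], n=1, top_k=20, stem=False,
            drop_stop_words=False,
        )
        assert len(tab.entries) == 20

    def test_counts_non_increasing(self, small_synthetic):
        tab = ngram_table(small_synthetic.docs, n=1, top_k=50)
        counts = [c for _, c in tab.entries]
        assert counts == sorted(counts, reverse=True)

    def test_bigrams_respect_sentence_boundaries(self):
        doc = Document(
            id="d", text="a b. c d.", tokens=["a", "b", "c", "d"],
            sentences=[(0, 2), (2, 4)],
        )
        tab = ngram_table([doc], n=2, top_k=10, stem=False, drop_stop_words=False)
        grams = dict(tab.entries)
        assert "b c" not in grams
        assert grams == {"a b": 1, "c d": 1}

    def test_stop_words_removed_and_stemmed(self):
        doc = _doc_from_tokens(["the", "randomized", "groups"])
        tab = ngram_table([doc], n=1, top_k=10)
        grams = dict(tab.entries)
        assert "the" not in grams
        assert "random" in grams and "group" in grams

    def test_ties_lexicographic(self):
        doc = _doc_from_tokens(["b", "a"])
        tab = ngram_table([doc], n=1, top_k=10, stem=False, drop_stop_words=False)
        assert tab.entries == [("a", 1), ("b", 1)]

    def test_brute_force_sliding_window(self, rng):
        for _ in range(10):
            tokens = list(rng.choice(list("abcd"), size=30))
            doc = _doc_from_tokens(tokens)
            tab = ngram_table([doc], n=2, top_k=1000, stem=False, drop_stop_words=False)
            brute = {}
            for i in range(len(tokens) - 1):
                g = f"{tokens[i]} {tokens[i+1]}"
                brute[g] = brute.get(g, 0) + 1
            assert dict(tab.entries) == brute


class TestFeatureTable:
    def test_shape_and_columns(self, small_synthetic):
        df = feature_table(small_synthetic.docs[:20])
        assert len(df) == 20
        assert list(df.columns)[:2] == ["chars_per_word", "words_per_sentence"]

    def test_panel_has_pos_metrics(self, small_synthetic):
        p = feature_panel(small_synthetic.docs[0])
        assert p.noun_pct + p.verb_pct + p.conj_pct <= 100.0
        assert 0 <= p.herdan_c <= 1
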