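import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ttest_ind_from_stats

from chatmood import lexicon_stats as lx


class TestTokenize:
    @pytest.mark.parametrize("text,tokens", [
        ("I'm SAD!!", ["i'm", "sad"]),
        ("", []),
        ("a  b", ["a", "b"]),
        ("...sad... :( !!", ["sad"]),
        ("don't stop", ["don't", "stop"]),
    ])
    def test_examples(self, text, tokens):
        assert lx.tokenize(text) == tokens


class TestScoreLexicon:
    def test_two_of_three_tokens(self):
        lex = lx.CategoryLexicon("demo", ("sad",))
        assert lx.score_lexicon("sad sad ok", lex) == pytest.approx(200 / 3)

    def test_stem_matches_prefix(self):
        lex = lx.CategoryLexicon("demo", ("depress*",))
        assert lx.score_lexicon("depressed", lex) == 100.0

    def test_literal_matches_whole_token_only(self):
        lex = lx.CategoryLexicon("demo", ("sad",))
        assert lx.score_lexicon("sadness", lex) == 0.0

    def test_empty_lexicon_is_config_error(self):
        with pytest.raises(ValueError):
            lx.CategoryLexicon("demo", ())

    def test_zero_token_text_gives_undefined_score(self):
        lex = lx.CategoryLexicon("demo", ("sad",))
        with pytest.raises(lx.UndefinedScoreError):
            lx.score_lexicon("!!! ...", lex)

    def test_score_invariant_to_order_and_punctuation_tokens(self):
        lex = lx.CategoryLexicon("demo", ("sad", "low"))
        base = lx.score_lexicon("sad day feeling low", lex)
        assert lx.score_lexicon("low feeling day sad", lex) == pytest.approx(base)
        # pure-punctuation "tokens" vanish in tokenization
        assert lx.score_lexicon("sad ?! day ... feeling --- low", lex) == pytest.approx(base)

    def test_score_corpus_excludes_undefined(self):
        lex = lx.CategoryLexicon("demo", ("sad",))
        scores = lx.score_corpus(["sad", "!!!", "ok"], lex)
        assert scores.tolist() == [100.0, 0.0]

    def test_demo_lexicon_set_loads_all_categories(self):
        lexicons = lx.load_demo_lexicons()
        assert len(lexicons) == 24
        assert "emo_neg" in lexicons and "pron_1st" in lexicons


class TestWelchT:
    def test_reconstructs_printed_negative_emotion_contrast(self):
        # group summaries (mean, SD, n) of negative-emotion word percentages
        res = lx.welch_t(29.68, 20.76, 21156, 29.17, 20.40, 21156)
        assert round(res.t, 2) == 2.55

    def test_identical_groups(self):
        res = lx.welch_t(5.0, 2.0, 50, 5.0, 2.0, 50)
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_equal_n_equal_sd_degrees_of_freedom(self):
        res = lx.welch_t(1.0, 3.0, 40, 2.0, 3.0, 40)
        assert res.df == pytest.approx(40 + 40 - 2)

    def test_sign_follows_mean_difference(self):
        assert lx.welch_t(1.0, 1.0, 10, 2.0, 1.0, 10).t < 0
        assert lx.welch_t(2.0, 1.0, 10, 1.0, 1.0, 10).t > 0

    def test_both_sds_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            lx.welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_matches_scipy_from_stats(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 3, size=2)
            n1, n2 = rng.integers(5, 200, size=2)
            res = lx.welch_t(m1, s1, int(n1), m2, s2, int(n2))
            t_ref, p_ref = ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                                equal_var=False)
            assert res.t == pytest.approx(float(t_ref), abs=1e-12)
            assert res.p == pytest.approx(float(p_ref), abs=1e-12)


class TestWelchTFromSamples:
    def test_identical_samples(self):
        assert lx.welch_t_from_samples([1, 2, 3], [1, 2, 3]).t == 0.0

    def test_hand_computed_case(self):
        # A=[0,0,10,10]: mean 5, var 100/3; B constant 5 → t=0, df=3
        res = lx.welch_t_from_samples([0, 0, 10, 10], [5, 5, 5, 5])
        assert res.t == 0.0
        assert res.df == pytest.approx(3.0)

    def test_within_group_permutation_invariance(self):
        a, b = [1.0, 4.0, 2.5, 0.5], [3.0, 3.5, 1.0]
        base = lx.welch_t_from_samples(a, b)
        perm = lx.welch_t_from_samples(a[::-1], b[::-1])
        assert (base.t, base.df, base.p) == (perm.t, perm.df, perm.p)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=30),
           st.lists(st.floats(-50, 50), min_size=3, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_summary_route_equals_sample_route(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            return
        res = lx.welch_t_from_samples(a, b)
        direct = lx.welch_t(a.mean(), a.std(ddof=1), a.size,
                            b.mean(), b.std(ddof=1), b.size)
        assert res.t == pytest.approx(direct.t, abs=1e-12)
        assert res.df == pytest.approx(direct.df, abs=1e-12)


class TestTopNgrams:
    def test_unigram_hand_count(self):
        table = lx.top_ngrams(["sad sad im"], n=1, remove_stopwords=False)
        assert table.entries == [(("sad",), pytest.approx(2 / 3)),
                                 (("im",), pytest.approx(1 / 3))]

    def test_bigrams_need_two_tokens(self):
        assert lx.top_ngrams(["sad"], n=2, remove_stopwords=False).entries == []

    def test_k_larger_than_distinct_returns_all(self):
        table = lx.top_ngrams(["sad lonely sad"], n=1, k=99,
                              remove_stopwords=False)
        assert len(table.entries) == 2

    def test_single_character_tokens_always_removed(self):
        table = lx.top_ngrams(["i m so sad"], n=1, remove_stopwords=False)
        grams = [g for g, _ in table.entries]
        assert ("i",) not in grams and ("m",) not in grams

    def test_stopword_flag(self):
        with_stop = lx.top_ngrams(["you are sad"], n=1, remove_stopwords=False)
        without = lx.top_ngrams(["you are sad"], n=1, remove_stopwords=True)
        assert (("you",), pytest.approx(1 / 3)) in with_stop.entries
        assert [g for g, _ in without.entries] == [("sad",)]

    def test_proportions_sum_to_one_and_nonincreasing(self):
        texts = ["sad lonely sad night", "lonely night again", "sad again"]
        table = lx.top_ngrams(texts, n=2, k=1000, remove_stopwords=False)
        props = [p for _, p in table.entries]
        assert sum(props) == pytest.approx(1.0)
        assert props == sorted(props, reverse=True)

    def test_ties_break_lexicographically(self):
        table = lx.top_ngrams(["zz aa"], n=1, k=2, remove_stopwords=False)
        assert [g for g, _ in table.entries] == [("aa",), ("zz",)]


class TestHourlyProfile:
    def test_point_mass(self, make_record):
        records = [make_record(uid=f"u{i}", hour=20) for i in range(5)]
        prof = lx.hourly_profile(records)["Western"]
        assert prof.freq[20] == 1.0 and prof.peak_hour == 20

    def test_uniform_fixture(self, make_record):
        records = [make_record(uid=f"u{h}_{i}", hour=h)
                   for h in range(24) for i in range(10)]
        prof = lx.hourly_profile(records)["Western"]
        assert np.allclose(prof.freq, 1 / 24)

    def test_frequencies_sum_to_one_per_region(self, make_record):
        records = ([make_record(uid=f"e{i}", country="Malaysia", hour=i % 24)
                    for i in range(30)]
                   + [make_record(uid=f"w{i}", country="Canada", hour=(i * 7) % 24)
                      for i in range(20)])
        profiles = lx.hourly_profile(records)
        assert set(profiles) == {"Eastern", "Western"}
        for prof in profiles.values():
            assert prof.freq.sum() == pytest.approx(1.0)
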