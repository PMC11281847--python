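"""Sparse n-gram retrieval against independent brute-force oracles."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simlink.kb import UnknownCodeError
from simlink.retrieve import (
    Candidate,
    CandidateList,
    HashedCharRetriever,
    SparseNgramRetriever,
    build_sparse_index,
    char_ngrams,
    ensemble_retrieve,
    load_index,
    retrieve_sparse,
    save_index,
    score_pair,
    write_candidates_jsonl,
    read_candidates_jsonl,
)

from conftest import make_kb


# --- character n-grams -----------------------------------------------------

class TestCharNgrams:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("abc", ["abc"]),
            ("fiebre", ["fie", "ieb", "ebr", "bre"]),
            ("", []),
            ("ab", ["ab"]),  # shorter than n: whole folded string
        ],
    )
    def test_windows(self, text, expected):
        assert char_ngrams(text, 3) == expected

    def test_case_folded(self):
        assert char_ngrams("Fiebre", 3) == char_ngrams("fiebre", 3)

    def test_crosses_token_boundaries(self):
        assert "r d" in char_ngrams("dolor de cabeza", 3)

    @settings(derandomize=True, max_examples=50)
    @given(st.text(min_size=0, max_size=30), st.integers(min_value=1, max_value=5))
    def test_window_count(self, text, n):
        grams = char_ngrams(text, n)
        folded = text.casefold()
        if not folded:
            assert grams == []
        elif len(folded) < n:
            assert grams == [folded]
        else:
            assert len(grams) == len(folded) - n + 1
            assert all(len(g) == n for g in grams)


# --- tf-idf weights against a hand oracle ----------------------------------

def brute_force_tfidf(alias_terms):
    """Independent tf-idf computation: raw tf, ln((1+A)/(1+df))+1, L2 norm."""
    A = len(alias_terms)
    df = collections.Counter()
    for term in alias_terms:
        df.update(set(char_ngrams(term)))

    def vec(text):
        tf = collections.Counter(char_ngrams(text))
        raw = {g: c * (np.log((1 + A) / (1 + df[g])) + 1) for g, c in tf.items() if g in df}
        norm = np.sqrt(sum(x * x for x in raw.values()))
        return {g: x / norm for g, x in raw.items()} if norm else {}

    return vec


def brute_force_ranking(kb, query, k=64):
    aliases = sorted({(code, term) for code, term, _ in kb.iter_aliases()})
    vec = brute_force_tfidf([t for _, t in aliases])
    q = vec(query)
    scores = {}
    for code, term in aliases:
        s = sum(w * vec(term).get(g, 0.0) for g, w in q.items())
        if s > 1e-12:
            scores[code] = max(scores.get(code, 0.0), s)
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


class TestSparseIndex:
    def test_rows_are_unit_norm(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        norms = np.sqrt(np.asarray(index.matrix_.power(2).sum(axis=1)).ravel())
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_idf_is_one_for_ubiquitous_gram(self):
        kb = make_kb({"C1": ["abcx"], "C2": ["abcy"], "C3": ["abcz"]})
        index = build_sparse_index(kb)
        gram_idx = index.vectorizer_.vocabulary_["abc"]
        assert index.vectorizer_.idf_[gram_idx] == pytest.approx(1.0)

    def test_weight_matrix_matches_hand_computation(self):
        kb = make_kb({f"C{i}": [t] for i, t in enumerate(
            ["fiebre", "fiebre alta", "tos", "disnea", "cefalea"])})
        index = build_sparse_index(kb)
        vec = brute_force_tfidf(index.alias_terms_)
        for row, term in enumerate(index.alias_terms_):
            expected = vec(term)
            got = index.matrix_[row].toarray().ravel()
            for gram, idx in index.vectorizer_.vocabulary_.items():
                assert got[idx] == pytest.approx(expected.get(gram, 0.0), abs=1e-12)

    def test_empty_kb_raises(self):
        from simlink.kb import KnowledgeBase
        with pytest.raises(ValueError):
            build_sparse_index(KnowledgeBase({}))


class TestRetrieveSparse:
    def test_exact_alias_scores_one_at_rank_one(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        result = retrieve_sparse(index, "cefalea", 5)
        assert result.top.code == "C3"
        assert result.top.score == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_query_returns_empty_list(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        assert len(retrieve_sparse(index, "xyzw", 5)) == 0

    def test_k_below_one_raises(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        with pytest.raises(ValueError):
            retrieve_sparse(index, "fiebre", 0)

    def test_matches_brute_force_on_random_queries(self, synth_small, synth_small_index):
        _, kb, corpus, _ = synth_small
        queries = [m.text for m in list(corpus)[:40]]
        for query in queries:
            expected = brute_force_ranking(kb, query)
            got = [(c.code, c.score) for c in synth_small_index.retrieve(query, 64)]
            assert [c for c, _ in got] == [c for c, _ in expected]
            assert np.allclose([s for _, s in got], [s for _, s in expected], atol=1e-9)

    def test_exact_match_property_over_all_aliases(self, synth_small, synth_small_index):
        _, kb, _, _ = synth_small
        for concept in list(kb)[:25]:
            for term in concept.alias_terms:
                top = synth_small_index.retrieve(term, 3).top
                assert top.code == concept.code
                assert top.score == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_byte_identical_lists(self, synth_small, synth_small_index):
        _, _, corpus, _ = synth_small
        text = list(corpus)[0].text
        a = synth_small_index.retrieve(text, 64)
        b = synth_small_index.retrieve(text, 64)
        assert a == b


class TestScorePair:
    def test_alias_with_own_code_scores_one(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        assert score_pair(index, "pirexia", "C1") == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_pair_scores_zero(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        assert score_pair(index, "xyzw", "C1") == 0.0

    def test_unknown_code_raises(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        with pytest.raises(UnknownCodeError):
            score_pair(index, "fiebre", "C99")

    def test_consistent_with_retrieve(self, synth_small, synth_small_index):
        _, _, corpus, _ = synth_small
        for mention in list(corpus)[:20]:
            for cand in synth_small_index.retrieve(mention.text, 10):
                assert score_pair(synth_small_index, mention.text, cand.code) == \
                    pytest.approx(cand.score, abs=1e-9)


class TestEnsemble:
    def test_single_retriever_identity(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        assert ensemble_retrieve([index], "fiebre", 5) == index.retrieve("fiebre", 5)

    def test_two_identical_retrievers_equal_one(self, tiny_kb):
        index = build_sparse_index(tiny_kb)
        fused = ensemble_retrieve([index, index], "dolor", 5)
        single = index.retrieve("dolor", 5)
        assert fused.codes == single.codes
        assert [c.score for c in fused] == pytest.approx([c.score for c in single])

    def test_stub_only_concept_enters_fused_list(self, tiny_kb):
        index = build_sparse_index(tiny_kb)

        class Stub(SparseNgramRetriever):
            """Dense stand-in that always surfaces C4 with a fixed score."""
            def __init__(self):
                pass
            def retrieve(self, query, k=64):
                return CandidateList(query, (Candidate("C4", 0.9, "dense", "tos"),), k=k)
            def score_pair(self, query, code):
                return 0.9 if code == "C4" else 0.0

        fused = ensemble_retrieve([index, Stub()], "cefalea", 5)
        c4 = {c.code: c for c in fused}["C4"]
        assert c4.score == pytest.approx(0.9)
        assert fused.top.code == "C3"  # exact match still wins

    def test_fusion_never_decreases_scores(self, synth_small, synth_small_index):
        _, kb, corpus, _ = synth_small
        dense = HashedCharRetriever(dim=64).fit(kb)
        for mention in list(corpus)[:15]:
            fused = {c.code: c.score for c in
                     ensemble_retrieve([synth_small_index, dense], mention.text, 64)}
            for retriever in (synth_small_index, dense):
                for cand in retriever.retrieve(mention.text, 64):
                    if cand.code in fused:
                        assert fused[cand.code] >= cand.score - 1e-9


class TestHashedCharRetriever:
    def test_exact_match_scores_one(self, tiny_kb):
        dense = HashedCharRetriever().fit(tiny_kb)
        top = dense.retrieve("disnea", 3).top
        assert top.code == "C2"
        assert top.score == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_across_instances(self, tiny_kb):
        a = HashedCharRetriever().fit(tiny_kb).retrieve("dolor", 4)
        b = HashedCharRetriever().fit(tiny_kb).retrieve("dolor", 4)
        assert a == b


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, synth_small, synth_small_index):
        _, _, corpus, _ = synth_small
        save_index(synth_small_index, tmp_path / "index")
        reloaded = load_index(tmp_path / "index")
        for mention in list(corpus)[:15]:
            a = synth_small_index.retrieve(mention.text, 64)
            b = reloaded.retrieve(mention.text, 64)
            assert a.codes == b.codes
            assert [c.score for c in a] == pytest.approx([c.score for c in b], abs=1e-12)

    def test_candidates_jsonl_round_trip(self, tmp_path, tiny_kb):
        index = build_sparse_index(tiny_kb)
        records = [("m1", index.retrieve("fiebre", 4)), ("m2", index.retrieve("tos", 4))]
        path = tmp_path / "candidates.jsonl"
        write_candidates_jsonl(records, path)
        assert read_candidates_jsonl(path) == records
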