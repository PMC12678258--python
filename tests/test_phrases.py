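"""Phrase scoring and the screening funnel against brute-force oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest

from resilmine.contrastive import HashingEncoder
from resilmine.corpus import TokenSequence
from resilmine.phrases import (
    PhraseCandidate,
    ScreeningConfig,
    extract_ngrams,
    quartile_pool_threshold,
    relevance_score,
    screen,
    sensitivity_analysis,
    specificity_index,
    tfidf_norm,
    token_idf,
)


def _seqs(token_lists):
    return [TokenSequence(doc_id=f"d{i}", tokens=list(t)) for i, t in enumerate(token_lists)]


class TestExtractNgrams:
    def test_single_doc_enumeration(self):
        pool = extract_ngrams(_seqs([["a", "b", "c"]]), max_n=2)
        texts = {p.text for p in pool}
        assert texts == {"a", "b", "c", "a b", "b c"}

    def test_counts_match_brute_force_substring_scan(self, study_seqs, study_corpus):
        pool = extract_ngrams(study_seqs[:30], max_n=3)
        sample = [p for p in pool if p.n_words >= 2][:50]
        for p in sample:
            toks = list(p.tokens)
            n = len(toks)
            total = sum(
                1
                for ts in study_seqs[:30]
                for i in range(len(ts.tokens) - n + 1)
                if ts.tokens[i : i + n] == toks
            )
            docf = sum(
                1
                for ts in study_seqs[:30]
                if any(ts.tokens[i : i + n] == toks for i in range(len(ts.tokens) - n + 1))
            )
            assert (p.total_freq, p.doc_freq) == (total, docf), p.text


class TestTfidf:
    def test_everywhere_phrase_scores_zero(self):
        seqs = _seqs([["x", "y"], ["x", "z"], ["x", "w"]])
        pool = extract_ngrams(seqs, 1)
        scored = {p.text: p.tfidf_norm for p in tfidf_norm(pool, 3)}
        assert scored["x"] == 0.0

    def test_argmax_normalizes_to_one(self):
        seqs = _seqs([["x", "y"], ["x", "z"], ["x", "w"]])
        scored = tfidf_norm(extract_ngrams(seqs, 1), 3)
        assert max(p.tfidf_norm for p in scored) == 1.0

    def test_three_phrase_toy_matches_formula(self):
        pool = [
            PhraseCandidate("a b", 2, 10, 2),
            PhraseCandidate("c d", 2, 6, 3),
            PhraseCandidate("e f", 2, 8, 1),
        ]
        n = 20
        raw = {p.text: p.total_freq * math.log(n / p.doc_freq) for p in pool}
        top = max(raw.values())
        scored = {p.text: p.tfidf_norm for p in tfidf_norm(pool, n)}
        for text, r in raw.items():
            assert scored[text] == pytest.approx(r / top)


class TestRelevanceSpecificity:
    def test_relevance_extremes(self):
        enc = HashingEncoder(dim=16, seed=0)
        emb = enc.encode_tokens(["clinic"])
        assert relevance_score("clinic", enc, emb) == pytest.approx(1.0)
        assert relevance_score("clinic", enc, -emb) == pytest.approx(0.0, abs=1e-12)

    def test_relevance_midcase_composition(self):
        enc = HashingEncoder(dim=16, seed=0)
        centroid = np.ones(16)
        from resilmine.contrastive import cosine_similarity

        expected = (cosine_similarity(enc.encode_tokens(["ward"]), centroid) + 1) / 2
        assert relevance_score("ward", enc, centroid) == pytest.approx(expected)

    def test_specificity_ubiquitous_tokens_zero(self):
        seqs = _seqs([["x", "a"], ["x", "b"], ["x", "c"], ["x", "d"], ["x", "e"]])
        idf = token_idf(seqs)
        assert specificity_index("x x", idf, 5) == 0.0

    def test_specificity_rare_tokens_clip_to_one(self):
        seqs = _seqs([["x", "a"], ["x", "b"], ["x", "c"], ["x", "d"], ["x", "e"]])
        idf = token_idf(seqs)
        # 'a'..'e' each occur in one of five docs: idf = ln 5, the p95 region
        assert specificity_index("a b", idf, 5) == 1.0

    def test_specificity_toy_hand_computation(self):
        seqs = _seqs([["p", "q"], ["p", "r"], ["q", "r"], ["p", "q"], ["s", "t"]])
        idf = token_idf(seqs)
        vals = sorted(idf.values())
        p95 = float(np.quantile(np.array(list(idf.values())), 0.95))
        mean_idf = (idf["p"] + idf["s"]) / 2
        expected = min(1.0, mean_idf / p95)
        assert specificity_index("p s", idf, 5) == pytest.approx(expected)


class TestQuartile:
    def test_linear_interpolation_case(self):
        pool = [PhraseCandidate(f"p{i}", 1, f_, 1) for i, f_ in enumerate([1, 2, 3, 100])]
        assert quartile_pool_threshold(pool) == pytest.approx(27.25)

    def test_constant_frequencies(self):
        pool = [PhraseCandidate(f"p{i}", 1, 4, 2) for i in range(6)]
        assert quartile_pool_threshold(pool) == 4.0

    def test_singleton(self):
        assert quartile_pool_threshold([PhraseCandidate("p", 1, 9, 3)]) == 9.0


def _pool(rows):
    return [
        PhraseCandidate(
            text=t, n_words=len(t.split()), total_freq=tf, doc_freq=df,
            tfidf_norm=x, relevance=r, specificity=s,
        )
        for t, tf, df, x, r, s in rows
    ]


CFG = ScreeningConfig(min_tfidf=None, min_specificity=None)


class TestScreen:
    def test_phase_counts_match_brute_force_filters(self):
        rows = [
            (f"phrase {i:02d}", tf, df, 0.5, rel, 0.6)
            for i, (tf, df, rel) in enumerate(
                [(4, 2, 0.9), (6, 5, 0.9), (12, 10, 0.9), (12, 10, 0.5), (20, 15, 0.8),
                 (10, 10, 0.7), (11, 9, 0.64), (30, 12, 0.66), (5, 3, 0.9), (10, 10, 0.65)]
            )
        ]
        pool = _pool(rows)
        rep = screen(pool, CFG)
        p1 = [r for r in rows if r[1] >= 5]
        p2 = [r for r in p1 if r[1] >= 7 and r[2] >= 10]
        p3 = [r for r in p2 if r[4] >= 0.65]
        assert rep.counts[:3] == [len(p1), len(p2), len(p3)]
        assert set(rep.retained(2)) == {r[0] for r in p3}

    def test_funnel_counts_non_increasing_and_nested(self):
        rows = [
            (f"w{i} v{i}", 5 + i, 3 + i, 0.5, 0.5 + 0.05 * i, 0.6) for i in range(10)
        ]
        rep = screen(_pool(rows), CFG)
        counts = rep.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for k in range(1, 4):
            assert set(rep.retained(k)) <= set(rep.retained(k - 1))

    def test_empty_pool_all_zero(self):
        rep = screen([], CFG)
        assert rep.counts == [0, 0, 0, 0]

    def test_overlong_phrase_dropped_at_phase4(self):
        text = "one two three four five six seven"
        pool = _pool([(text, 20, 15, 0.9, 0.9, 0.9)])
        rep = screen(pool, CFG)
        assert rep.counts == [1, 1, 1, 0]

    def test_generic_single_word_dropped(self):
        pool = _pool([("community", 50, 40, 0.9, 0.9, 0.9)])
        rep = screen(pool, CFG)
        assert rep.retained(2) == ["community"] and rep.retained(3) == []

    def test_blocklist_drops_ambiguous_phrase(self):
        pool = _pool([("good things", 20, 15, 0.9, 0.9, 0.9)])
        cfg = replace(CFG, ambiguity_blocklist=frozenset({"good things"}))
        assert screen(pool, cfg).retained(3) == []

    def test_consensus_gate_applies_when_ratings_supplied(self):
        pool = _pool([("strong phrase", 20, 15, 0.9, 0.9, 0.9),
                      ("weak phrase", 20, 15, 0.9, 0.9, 0.9)])
        ratings = {"strong phrase": 1.0, "weak phrase": 0.5}
        rep = screen(pool, CFG, quality_ratings=ratings)
        assert rep.retained(3) == ["strong phrase"]

    def test_order_independence(self, rng):
        rows = [
            (f"p{i} q{i}", int(tf), int(df), 0.5, float(r), 0.6)
            for i, (tf, df, r) in enumerate(
                zip(rng.integers(1, 30, 40), rng.integers(1, 15, 40), rng.uniform(0, 1, 40))
            )
        ]
        rows = [(t, max(tf, df), df, x, r, s) for t, tf, df, x, r, s in rows]
        pool = _pool(rows)
        rep1 = screen(pool, CFG)
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        rep2 = screen(shuffled, CFG)
        assert rep1.counts == rep2.counts
        assert rep1.retained(-1) == rep2.retained(-1)

    def test_near_duplicate_merge_keeps_higher_relevance(self):
        enc = HashingEncoder(dim=16, seed=0)
        # identical token bags embed identically -> cosine 1 -> merged
        pool = _pool([
            ("alpha beta", 20, 15, 0.9, 0.7, 0.9),
            ("beta alpha", 20, 15, 0.9, 0.9, 0.9),
        ])
        rep = screen(pool, CFG, encoder=enc)
        assert rep.retained(3) == ["beta alpha"]


class TestSensitivity:
    def _scored_pool(self):
        rows = [
            (f"a{i} b{i}", 20, 15, 0.5, rel, 0.6)
            for i, rel in enumerate([0.50, 0.57, 0.62, 0.66, 0.71, 0.76, 0.80, 0.90])
        ]
        return _pool(rows)

    def test_monotone_retention_across_thresholds(self):
        pool = self._scored_pool()
        ref = {p.text for p in pool}
        table = sensitivity_analysis(pool, reference_set=ref, cfg=CFG).to_frame()
        assert list(table.n_retained) == sorted(table.n_retained, reverse=True)

    def test_default_threshold_reproduces_main_funnel(self):
        pool = self._scored_pool()
        rep = screen(pool, CFG)
        table = sensitivity_analysis(pool, reference_set=set(rep.retained(-1)) or {"x"}, cfg=CFG).to_frame()
        at_default = table[np.isclose(table.threshold, CFG.min_relevance)]
        assert int(at_default.n_retained.iloc[0]) == rep.counts[-1]

    def test_vacuous_threshold_keeps_phase2_survivors(self):
        pool = self._scored_pool()
        ref = {p.text for p in pool if (p.relevance or 0) >= 0.65}
        table = sensitivity_analysis(pool, thresholds=[0.0], reference_set=ref, cfg=CFG).to_frame()
        assert int(table.n_retained.iloc[0]) == len(pool)
        assert table.overlap.iloc[0] == 1.0

    def test_overlap_matches_brute_force(self):
        pool = self._scored_pool()
        ref = {"a6 b6", "a7 b7", "nonexistent phrase"}
        table = sensitivity_analysis(pool, thresholds=[0.75], reference_set=ref, cfg=CFG).to_frame()
        retained = {p.text for p in pool if (p.relevance or 0) >= 0.75}
        assert table.overlap.iloc[0] == pytest.approx(len(retained & ref) / len(ref))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis(self._scored_pool(), reference_set=set(), cfg=CFG)
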