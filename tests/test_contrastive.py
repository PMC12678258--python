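"""Contrastive learning: augmentation, InfoNCE, schedule, training, metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resilmine.contrastive import (
    MASK_TOKEN,
    AugmentationSpec,
    HashingEncoder,
    TrainableEncoder,
    TrainingConfig,
    ValidationMetrics,
    augment,
    cosine_similarity,
    info_nce_loss,
    lr_at,
    train,
    validate,
)
from resilmine.corpus import TokenSequence, preprocess_corpus


def brute_force_info_nce(anchor, positive, negatives, tau):
    """Independent softmax oracle over explicit exponentials."""
    sims = [cosine_similarity(anchor, positive)] + [
        cosine_similarity(anchor, n) for n in negatives
    ]
    exps = [math.exp(s / tau) for s in sims]
    return -math.log(exps[0] / sum(exps))


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([2.0, -1.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_diagonal_pair(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])


class TestInfoNCE:
    def test_uniform_similarities_give_log_batch(self, rng):
        # 15 negatives + positive = 16 equal denominator terms
        v = rng.standard_normal(8)
        loss = info_nce_loss(v, v.copy(), [v.copy() for _ in range(15)], tau=0.07)
        assert loss == pytest.approx(math.log(16), abs=1e-10)

    def test_single_negative_closed_form(self):
        # sim(anchor,pos)=1, sim(anchor,neg)=0, tau=1: -ln(e/(e+1))
        anchor = np.array([1.0, 0.0])
        loss = info_nce_loss(anchor, anchor.copy(), [np.array([0.0, 1.0])], tau=1.0)
        assert loss == pytest.approx(-math.log(math.e / (math.e + 1)), abs=1e-12)

    def test_separated_limit_vanishes(self):
        anchor = np.array([1.0, 0.0])
        loss = info_nce_loss(anchor, anchor.copy(), [-anchor], tau=0.07)
        assert loss < 1e-6

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 7))
            vecs = rng.standard_normal((k + 2, 5))
            tau = float(rng.uniform(0.05, 2.0))
            ours = info_nce_loss(vecs[0], vecs[1], list(vecs[2:]), tau)
            assert ours == pytest.approx(
                brute_force_info_nce(vecs[0], vecs[1], list(vecs[2:]), tau), abs=1e-10
            )

    def test_negative_permutation_invariance(self, rng):
        vecs = rng.standard_normal((6, 4))
        negs = list(vecs[2:])
        a = info_nce_loss(vecs[0], vecs[1], negs, 0.07)
        b = info_nce_loss(vecs[0], vecs[1], negs[::-1], 0.07)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            info_nce_loss([1, 0], [1, 0], [[0, 1]], tau=0.0)


def _ts(tokens, sentences=None):
    return TokenSequence(doc_id="d", tokens=list(tokens), sentences=sentences or [])


class TestAugment:
    def test_identity_configuration(self):
        ts = _ts(["alpha", "beta", "gamma"])
        spec = AugmentationSpec(mask_rate=0.0, do_sentence_reorder=False)
        assert augment(ts, spec).tokens == ts.tokens

    def test_mask_count_rule(self):
        ts = _ts([f"t{i}" for i in range(100)])
        out = augment(ts, AugmentationSpec(mask_rate=0.15, do_sentence_reorder=False, seed=3))
        assert out.tokens.count(MASK_TOKEN) == 15
        assert len(out.tokens) == 100

    def test_sentence_reordering_preserves_multiset(self):
        ts = _ts(list("abcdef"), sentences=[(0, 2), (2, 4), (4, 6)])
        out = augment(ts, AugmentationSpec(mask_rate=0.0, do_sentence_reorder=True, seed=1))
        assert sorted(out.tokens) == sorted(ts.tokens)
        assert len(out.sentences) == 3

    def test_seeded_determinism(self):
        ts = _ts([f"t{i}" for i in range(40)], sentences=[(0, 20), (20, 40)])
        spec = AugmentationSpec(seed=7)
        assert augment(ts, spec).tokens == augment(ts, spec).tokens

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment(_ts([]), AugmentationSpec())

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from("abcdefgh"), min_size=1, max_size=60), st.integers(0, 10_000))
    def test_token_count_always_preserved(self, tokens, seed):
        out = augment(_ts(tokens), AugmentationSpec(seed=seed))
        assert len(out.tokens) == len(tokens)


class TestSchedule:
    def test_warmup_endpoint_reaches_peak(self):
        assert lr_at(10, 100, peak_lr=1.0) == pytest.approx(1.0)

    def test_final_step_decays_to_zero(self):
        assert lr_at(100, 100, peak_lr=1.0) == 0.0

    def test_linear_in_both_segments(self):
        assert lr_at(5, 100, 1.0) == pytest.approx(0.5)
        assert lr_at(55, 100, 1.0) == pytest.approx(0.5)


class TestTrain:
    def _small_corpus(self, study_corpus):
        corpus, _ = study_corpus
        return corpus

    def test_loss_decreases_on_planted_corpus(self, study_corpus):
        corpus, _ = study_corpus
        cfg = TrainingConfig(lr=0.05, epochs=3, val_every=50, seed=0)
        _, log = train(corpus, cfg=cfg, aug=AugmentationSpec(seed=0))
        assert log.loss.iloc[-1] < log.loss.iloc[0]

    def test_two_runs_identical_logs(self, study_corpus):
        corpus, _ = study_corpus
        cfg = TrainingConfig(lr=0.05, epochs=1, val_every=10, seed=4)
        enc1, log1 = train(corpus, cfg=cfg, aug=AugmentationSpec(seed=4))
        enc2, log2 = train(corpus, cfg=cfg, aug=AugmentationSpec(seed=4))
        assert log1.equals(log2)
        assert np.array_equal(enc1.W, enc2.W)

    def test_patience_halts_after_constant_mrr(self, study_corpus):
        corpus, _ = study_corpus
        calls = []

        def constant_mrr(encoder, docs, aug, pairs):
            calls.append(1)
            return ValidationMetrics(contrastive_accuracy=0.5, mrr=0.5, coherence=float("nan"))

        cfg = TrainingConfig(lr=0.01, epochs=50, val_every=1, patience=5, seed=0)
        train(corpus, cfg=cfg, aug=AugmentationSpec(seed=0), validate_fn=constant_mrr)
        # first check sets the best; exactly 5 further non-improving checks
        assert len(calls) == 6

    def test_corpus_smaller_than_batch_rejected(self, study_corpus):
        corpus, _ = study_corpus
        small = preprocess_corpus(corpus)[:10]
        with pytest.raises(ValueError):
            train(small, cfg=TrainingConfig(batch_size=16))


class TestValidate:
    def test_perfect_encoder_ranks_first(self, study_seqs):
        docs = study_seqs[:8]

        class Oracle:
            dim = 8

            def encode(self, ts):
                # identical unique vector for a doc and its augmentation
                rng = np.random.default_rng(abs(hash(ts.doc_id)) % 2**31)
                return rng.standard_normal(8)

            def encode_tokens(self, tokens):  # pragma: no cover
                raise NotImplementedError

        m = validate(Oracle(), docs, AugmentationSpec(seed=0))
        assert m.contrastive_accuracy == 1.0 and m.mrr == 1.0

    def test_collapsed_encoder_worst_case_ties(self, study_seqs):
        docs = study_seqs[:6]

        class Collapsed:
            dim = 3

            def encode(self, ts):
                return np.ones(3)

            def encode_tokens(self, tokens):  # pragma: no cover
                raise NotImplementedError

        m = validate(Collapsed(), docs, AugmentationSpec(seed=0))
        # all similarities tie; pessimistic rule puts every positive last
        n = len(docs)
        assert m.mrr == pytest.approx(1.0 / n)
        assert m.contrastive_accuracy == 0.0

    def test_mrr_agrees_with_exhaustive_enumeration(self, study_seqs, rng):
        docs = study_seqs[:7]
        enc = HashingEncoder(dim=16, seed=2)
        aug = AugmentationSpec(seed=5)
        m = validate(enc, docs, aug)
        # brute-force recomputation of pessimistic ranks
        gen = np.random.default_rng(aug.seed)
        anchors = [enc.encode(d) for d in docs]
        pos = [enc.encode(augment(d, aug, rng=gen)) for d in docs]
        rr = []
        top = 0
        for i, a in enumerate(anchors):
            sims = [cosine_similarity(a, p) for p in pos]
            rank = 1 + sum(1 for j, s in enumerate(sims) if j != i and s >= sims[i])
            rr.append(1 / rank)
            top += rank == 1
        assert m.mrr == pytest.approx(np.mean(rr), abs=1e-12)
        assert m.contrastive_accuracy == pytest.approx(top / len(docs), abs=1e-12)

    def test_empty_pair_list_gives_nan_coherence(self, study_seqs):
        m = validate(HashingEncoder(dim=8), study_seqs[:4], AugmentationSpec(seed=0))
        assert math.isnan(m.coherence)

    def test_fewer_than_two_docs_rejected(self, study_seqs):
        with pytest.raises(ValueError):
            validate(HashingEncoder(dim=8), study_seqs[:1], AugmentationSpec())


def test_hashing_encoder_deterministic_across_instances():
    a = HashingEncoder(dim=32, seed=9)
    b = HashingEncoder(dim=32, seed=9)
    tokens = ["clinic", "ward", "clinic"]
    assert np.array_equal(a.encode_tokens(tokens), b.encode_tokens(tokens))
    c = HashingEncoder(dim=32, seed=10)
    assert not np.array_equal(a.encode_tokens(tokens), c.encode_tokens(tokens))


def test_trainable_encoder_same_seed_identical():
    e1 = TrainableEncoder(["a", "b", "c"], dim=8, seed=3)
    e2 = TrainableEncoder(["a", "b", "c"], dim=8, seed=3)
    assert np.array_equal(e1.W, e2.W)
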