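"""Contrastive representation learning for documents and phrases.

The pipeline needs an encoder ``f`` mapping token sequences to fixed-size
vectors such that a document and a lightly perturbed copy of itself land
close together while unrelated documents land apart.  Training uses the
InfoNCE objective with in-batch negatives: for each anchor the augmented
copies of all other batch members are the negatives, so a batch of B
documents yields B-1 negatives per anchor.

Two encoders implement the same contract:

* :class:`HashingEncoder` — a deterministic seeded random-projection
  bag-of-tokens encoder; no training, no external weights, instant.  This is
  the default desk-scale encoder for the rest of the pipeline.
* :class:`TrainableEncoder` — a linear bag-of-tokens encoder (one weight row
  per vocabulary entry) trained by :func:`train` with AdamW, linear
  warmup/decay, gradient clipping, periodic validation and early stopping on
  mean reciprocal rank.

Augmentation follows the standard recipe: random token masking at a fixed
rate, sentence reordering, and lexicon-based synonym replacement.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, TokenSequence, preprocess_corpus

__all__ = [
    "MASK_TOKEN",
    "AugmentationSpec",
    "TrainingConfig",
    "ValidationMetrics",
    "Encoder",
    "HashingEncoder",
    "TrainableEncoder",
    "load_default_synonyms",
    "augment",
    "cosine_similarity",
    "info_nce_loss",
    "lr_at",
    "train",
    "validate",
]

MASK_TOKEN = "[mask]"


def load_default_synonyms() -> dict[str, str]:
    text = resources.files("resilmine.data").joinpath("synonyms.txt").read_text("utf-8")
    lex: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, rep = line.split("\t")
        lex[word] = rep
    return lex


@dataclass
class AugmentationSpec:
    """Positive-pair recipe: mask 15% of tokens, reorder sentences, swap synonyms."""

    mask_rate: float = 0.15
    do_sentence_reorder: bool = True
    synonym_lexicon: dict[str, str] | None = None
    synonym_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_rate < 1.0:
            raise ValueError("mask_rate must lie in [0, 1)")


def augment(ts: TokenSequence, spec: AugmentationSpec, rng: np.random.Generator | None = None) -> TokenSequence:
    """Produce the positive sample for ``ts``.

    Token count is preserved: sentence reordering permutes whole sentences,
    synonym replacement is one-for-one, and masking substitutes the reserved
    mask token in round(mask_rate * n) positions sampled without replacement.
    """
    if ts.is_empty:
        raise ValueError(f"cannot augment empty token sequence {ts.doc_id!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    sentences = ts.sentences if ts.sentences else [(0, len(ts.tokens))]
    order = rng.permutation(len(sentences)) if spec.do_sentence_reorder else np.arange(len(sentences))
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for si in order:
        a, b = sentences[si]
        start = len(tokens)
        tokens.extend(ts.tokens[a:b])
        spans.append((start, len(tokens)))

    if spec.synonym_lexicon:
        for i, t in enumerate(tokens):
            if t in spec.synonym_lexicon and rng.random() < spec.synonym_prob:
                tokens[i] = spec.synonym_lexicon[t]

    n_mask = int(round(spec.mask_rate * len(tokens)))
    if n_mask:
        for i in rng.choice(len(tokens), size=n_mask, replace=False):
            tokens[i] = MASK_TOKEN
    return TokenSequence(doc_id=ts.doc_id, tokens=tokens, sentences=spans)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def info_nce_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negatives: Sequence[np.ndarray],
    tau: float = 0.07,
) -> float:
    """-log softmax probability of the positive among {positive} U negatives.

    Similarities are cosine; the denominator runs over the positive plus all
    negatives, scaled by the temperature ``tau``.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if len(negatives) == 0:
        raise ValueError("at least one negative is required")
    sims = np.array(
        [cosine_similarity(anchor, positive)] + [cosine_similarity(anchor, n) for n in negatives]
    )
    logits = sims / tau
    m = logits.max()
    return float(-(logits[0] - m) + math.log(np.exp(logits - m).sum()))


class Encoder(Protocol):
    """Map a token list to a fixed-dimension real vector, deterministically."""

    dim: int

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray: ...

    def encode(self, ts: TokenSequence) -> np.ndarray: ...


class _EncoderBase:
    dim: int

    def encode(self, ts: TokenSequence) -> np.ndarray:
        return self.encode_tokens(ts.tokens)

    def encode_many(self, seqs: Sequence[TokenSequence]) -> np.ndarray:
        return np.stack([self.encode(ts) for ts in seqs])


class HashingEncoder(_EncoderBase):
    """Seeded random-projection bag-of-tokens encoder.

    Each token is assigned a fixed Gaussian direction derived from a stable
    hash of (seed, token); a document maps to the mean of its token vectors.
    Deterministic across processes, needs no vocabulary or fitting.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if len(tokens) == 0:
            return np.zeros(self.dim)
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


class TrainableEncoder(_EncoderBase):
    """Linear bag-of-tokens encoder: one learned weight row per vocabulary entry.

    A document embeds as the mean of its tokens' weight rows; out-of-vocabulary
    tokens (including the mask token) share a single OOV row.  Initialization
    is seeded Gaussian so two encoders built with the same vocabulary and seed
    are identical.
    """

    def __init__(self, vocabulary: Sequence[str], dim: int = 64, seed: int = 0):
        self.dim = dim
        self.vocab = {t: i for i, t in enumerate(dict.fromkeys(vocabulary))}
        self.oov_index = len(self.vocab)
        rng = np.random.default_rng(seed)
        self.W = rng.standard_normal((len(self.vocab) + 1, dim)) / math.sqrt(dim)

    @classmethod
    def from_corpus(cls, seqs: Sequence[TokenSequence], dim: int = 64, seed: int = 0) -> "TrainableEncoder":
        vocab = sorted({t for ts in seqs for t in ts.tokens})
        return cls(vocab, dim=dim, seed=seed)

    def token_ids(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.vocab.get(t, self.oov_index) for t in tokens], dtype=int)

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        if len(tokens) == 0:
            return np.zeros(self.dim)
        ids = self.token_ids(tokens)
        return self.W[ids].mean(axis=0)

    def clone(self) -> "TrainableEncoder":
        out = copy.copy(self)
        out.W = self.W.copy()
        return out


@dataclass
class TrainingConfig:
    """Optimization schedule for contrastive fine-tuning."""

    temperature: float = 0.07
    batch_size: int = 16
    grad_accum: int = 2
    lr: float = 2e-5
    weight_decay: float = 0.01
    warmup_fraction: float = 0.10
    max_grad_norm: float = 1.0
    epochs: int = 3
    val_fraction: float = 0.15
    val_every: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class ValidationMetrics:
    contrastive_accuracy: float
    mrr: float
    coherence: float  # NaN sentinel when no same-topic pairs supplied


def lr_at(step: int, total_steps: int, peak_lr: float, warmup_fraction: float = 0.10) -> float:
    """Linear warmup to the peak over the first warmup fraction of steps,
    then linear decay to zero at the final step (1-indexed steps)."""
    warmup = max(1, int(round(warmup_fraction * total_steps)))
    if step <= warmup:
        return peak_lr * step / warmup
    if total_steps == warmup:
        return peak_lr
    return peak_lr * (total_steps - step) / (total_steps - warmup)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (A / na) @ (B / nb).T


def _batch_loss_and_grads(
    enc: TrainableEncoder,
    anchor_ids: list[np.ndarray],
    pos_ids: list[np.ndarray],
    tau: float,
) -> tuple[float, np.ndarray]:
    """InfoNCE over a batch with in-batch negatives; analytic gradient in W.

    z_i = mean of W rows for anchor i, p_j likewise for augmented copies;
    logits[i, j] = cos(z_i, p_j) / tau; the diagonal holds the positives.
    """
    W = enc.W
    B = len(anchor_ids)
    Z = np.stack([W[ids].mean(axis=0) for ids in anchor_ids])
    P = np.stack([W[ids].mean(axis=0) for ids in pos_ids])
    nz = np.linalg.norm(Z, axis=1)
    np_ = np.linalg.norm(P, axis=1)
    nz = np.where(nz == 0, 1.0, nz)
    np_ = np.where(np_ == 0, 1.0, np_)
    S = (Z / nz[:, None]) @ (P / np_[:, None]).T
    logits = S / tau
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    prob = expl / expl.sum(axis=1, keepdims=True)
    loss = float(-np.log(np.clip(np.diag(prob), 1e-300, None)).mean())

    dS = (prob - np.eye(B)) / (tau * B)  # dL/dS
    # cosine backward: S_ij = (z_i . p_j) / (|z_i||p_j|)
    gZ = (dS @ (P / np_[:, None])) / nz[:, None] - (dS * S).sum(axis=1, keepdims=True) * Z / (nz**2)[:, None]
    gP = (dS.T @ (Z / nz[:, None])) / np_[:, None] - (dS * S).sum(axis=0)[:, None] * P / (np_**2)[:, None]

    grad = np.zeros_like(W)
    for i, ids in enumerate(anchor_ids):
        np.add.at(grad, ids, gZ[i] / len(ids))
    for j, ids in enumerate(pos_ids):
        np.add.at(grad, ids, gP[j] / len(ids))
    return loss, grad


def train(
    corpus: Corpus | Sequence[TokenSequence],
    encoder: TrainableEncoder | None = None,
    cfg: TrainingConfig | None = None,
    aug: AugmentationSpec | None = None,
    validate_fn: Callable[..., ValidationMetrics] | None = None,
    same_topic_pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[TrainableEncoder, pd.DataFrame]:
    """Contrastive fine-tuning with in-batch negatives.

    Returns the best-MRR checkpoint and a per-step log (step, lr, loss, and
    validation snapshots).  One optimizer step consumes ``batch_size *
    grad_accum`` documents (gradient accumulation); the learning rate follows
    :func:`lr_at`; gradients are clipped to ``max_grad_norm``; AdamW with
    decoupled weight decay performs the update.  Early stopping fires after
    ``patience`` validation checks without MRR improvement.

    ``validate_fn`` is injectable for testing the early-stopping contract.
    """
    cfg = cfg or TrainingConfig()
    aug = aug or AugmentationSpec()
    seqs = preprocess_corpus(corpus) if isinstance(corpus, Corpus) else list(corpus)
    seqs = [s for s in seqs if not s.is_empty]
    if len(seqs) <= cfg.batch_size:
        raise ValueError(
            f"corpus ({len(seqs)} non-empty docs) must exceed batch_size {cfg.batch_size}"
        )
    rng = np.random.default_rng(cfg.seed)

    # validation split: round-half-up of val_fraction * N, seeded shuffle
    n_val = int(math.floor(cfg.val_fraction * len(seqs) + 0.5))
    n_val = max(2, min(n_val, len(seqs) - cfg.batch_size))
    perm = rng.permutation(len(seqs))
    val_seqs = [seqs[i] for i in perm[:n_val]]
    train_seqs = [seqs[i] for i in perm[n_val:]]

    if encoder is None:
        encoder = TrainableEncoder.from_corpus(seqs, seed=cfg.seed)
    if validate_fn is None:
        validate_fn = validate

    micro = cfg.batch_size
    micro_per_step = cfg.grad_accum
    batches_per_epoch = max(1, len(train_seqs) // micro)
    steps_per_epoch = max(1, batches_per_epoch // micro_per_step)
    total_steps = steps_per_epoch * cfg.epochs

    m = np.zeros_like(encoder.W)
    v = np.zeros_like(encoder.W)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    log_rows: list[dict] = []
    best_mrr, best_W = -np.inf, encoder.W.copy()
    checks_since_improvement = 0
    step = 0
    stop = False

    for _epoch in range(cfg.epochs):
        if stop:
            break
        order = rng.permutation(len(train_seqs))
        micro_batches = [
            order[i * micro : (i + 1) * micro] for i in range(batches_per_epoch)
        ]
        for s in range(steps_per_epoch):
            step += 1
            grad = np.zeros_like(encoder.W)
            losses = []
            for b in range(micro_per_step):
                idx = micro_batches[(s * micro_per_step + b) % len(micro_batches)]
                batch = [train_seqs[i] for i in idx]
                anchor_ids = [encoder.token_ids(ts.tokens) for ts in batch]
                pos_ids = [
                    encoder.token_ids(augment(ts, aug, rng=rng).tokens) for ts in batch
                ]
                loss_b, grad_b = _batch_loss_and_grads(
                    encoder, anchor_ids, pos_ids, cfg.temperature
                )
                losses.append(loss_b)
                grad += grad_b / micro_per_step
            gnorm = float(np.linalg.norm(grad))
            if gnorm > cfg.max_grad_norm:
                grad *= cfg.max_grad_norm / gnorm
            lr = lr_at(step, total_steps, cfg.lr, cfg.warmup_fraction)
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**step)
            vhat = v / (1 - beta2**step)
            encoder.W -= lr * (mhat / (np.sqrt(vhat) + eps) + cfg.weight_decay * encoder.W)

            row = {
                "step": step,
                "lr": lr,
                "loss": float(np.mean(losses)),
                "val_accuracy": np.nan,
                "val_mrr": np.nan,
                "val_coherence": np.nan,
            }
            if step % cfg.val_every == 0 or step == total_steps:
                metrics = validate_fn(
                    encoder, val_seqs, replace(aug, seed=aug.seed + 1), same_topic_pairs or []
                )
                row.update(
                    val_accuracy=metrics.contrastive_accuracy,
                    val_mrr=metrics.mrr,
                    val_coherence=metrics.coherence,
                )
                if metrics.mrr > best_mrr:
                    best_mrr = metrics.mrr
                    best_W = encoder.W.copy()
                    checks_since_improvement = 0
                else:
                    checks_since_improvement += 1
                log_rows.append(row)
                if checks_since_improvement >= cfg.patience:
                    stop = True
                    break
                continue
            log_rows.append(row)

    best = encoder.clone()
    best.W = best_W if np.isfinite(best_mrr) else encoder.W.copy()
    return best, pd.DataFrame(log_rows)


def validate(
    encoder: Encoder,
    val_docs: Sequence[TokenSequence],
    aug: AugmentationSpec,
    same_topic_pairs: Sequence[tuple[int, int]] = (),
) -> ValidationMetrics:
    """In-batch ranking metrics on a validation set.

    For each anchor the augmented copies of all validation documents are
    ranked by cosine similarity; ties are broken pessimistically (a tied
    competitor counts as ranked above the positive).  Contrastive accuracy
    is the fraction of anchors whose positive strictly outranks every
    negative; MRR averages 1/rank.  Coherence is the mean cosine of
    ``same_topic_pairs`` (NaN when none are given).
    """
    val_docs = [d for d in val_docs if not d.is_empty]
    if len(val_docs) < 2:
        raise ValueError("validation requires at least 2 non-empty documents")
    rng = np.random.default_rng(aug.seed)
    anchors = np.stack([encoder.encode(ts) for ts in val_docs])
    positives = np.stack(
        [encoder.encode(augment(ts, aug, rng=rng)) for ts in val_docs]
    )
    S = _cosine_matrix(anchors, positives)
    n = len(val_docs)
    ranks = np.empty(n)
    for i in range(n):
        pos = S[i, i]
        others = np.delete(S[i], i)
        ranks[i] = 1 + int(np.sum(others >= pos))  # pessimistic tie rule
    mrr = float(np.mean(1.0 / ranks))
    acc = float(np.mean(ranks == 1))
    if same_topic_pairs:
        coh = float(
            np.mean([cosine_similarity(anchors[i], anchors[j]) for i, j in same_topic_pairs])
        )
    else:
        coh = float("nan")
    return ValidationMetrics(contrastive_accuracy=acc, mrr=mrr, coherence=coh)
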