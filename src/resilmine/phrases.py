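"""Candidate phrase extraction, scoring, and the four-phase screening funnel.

Candidates are all contiguous 1..max_n token n-grams with exact total and
document frequencies.  Each candidate carries four scores:

* ``tfidf_norm`` — total_freq x ln(N/doc_freq), rescaled by the pool maximum
  into [0, 1];
* ``relevance`` — cosine of the phrase embedding to the domain centroid
  (the mean document embedding), affinely mapped to [0, 1];
* ``specificity`` — mean token IDF over the phrase's tokens divided by the
  corpus's 95th-percentile token IDF, clipped to [0, 1]; generic words score
  near zero;
* ``consensus`` — optional manual-reviewer approval fraction.

Screening runs in four phases, each a pure filter over the previous phase's
survivors, so phase counts are non-increasing by construction:

1. candidate pool at frequency >= pool_min_freq,
2. frequency and source-breadth gates (total_freq and doc_freq),
3. semantic relevance (plus optional TF-IDF / specificity / coherence gates),
4. quality filters: overlong phrases dropped, generic single words dropped,
   blocklisted (ambiguous) phrases dropped, near-duplicates merged keeping
   the higher-relevance member, and the reviewer-consensus gate when ratings
   are supplied.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contrastive import Encoder, cosine_similarity
from .corpus import TokenSequence

__all__ = [
    "PhraseCandidate",
    "ScreeningConfig",
    "FunnelReport",
    "SensitivityTable",
    "extract_ngrams",
    "tfidf_norm",
    "token_idf",
    "domain_centroid",
    "relevance_score",
    "specificity_index",
    "score_pool",
    "quartile_pool_threshold",
    "screen",
    "sensitivity_analysis",
]

# Single generic words that never survive quality filtering on their own.
DEFAULT_GENERIC_WORDS = frozenset(
    "community problem impact system approach research study method factor".split()
)


@dataclass
class PhraseCandidate:
    text: str
    n_words: int
    total_freq: int
    doc_freq: int
    tfidf_norm: float | None = None
    relevance: float | None = None
    specificity: float | None = None
    consensus: float | None = None

    def __post_init__(self) -> None:
        if self.doc_freq > self.total_freq:
            raise ValueError(f"{self.text!r}: doc_freq {self.doc_freq} > total_freq {self.total_freq}")
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.text.split())


@dataclass
class ScreeningConfig:
    pool_min_freq: int = 5
    min_total_freq: int = 7
    min_doc_freq: int = 10
    min_relevance: float = 0.65
    min_tfidf: float | None = 0.45
    min_specificity: float | None = 0.50
    min_consensus: float = 2.0 / 3.0
    max_words: int = 6
    generic_word_list: frozenset[str] = DEFAULT_GENERIC_WORDS
    ambiguity_blocklist: frozenset[str] = frozenset()
    merge_similarity: float = 0.9

    def __post_init__(self) -> None:
        if self.pool_min_freq > self.min_total_freq:
            raise ValueError("pool_min_freq must not exceed min_total_freq")


@dataclass
class FunnelReport:
    """Per-phase retained phrase lists; counts are non-increasing."""

    phases: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def counts(self) -> list[int]:
        return [len(kept) for _, kept in self.phases]

    def retained(self, phase: int = -1) -> list[str]:
        return list(self.phases[phase][1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(name, len(kept)) for name, kept in self.phases],
            columns=["phase", "n_retained"],
        )


@dataclass
class SensitivityTable:
    rows: pd.DataFrame  # threshold, n_retained, overlap

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def extract_ngrams(seqs: Sequence[TokenSequence], max_n: int = 4) -> list[PhraseCandidate]:
    """All contiguous 1..max_n-grams with exact total and document frequencies."""
    total: Counter[tuple[str, ...]] = Counter()
    docs: Counter[tuple[str, ...]] = Counter()
    for ts in seqs:
        toks = ts.tokens
        seen: set[tuple[str, ...]] = set()
        for n in range(1, max_n + 1):
            for i in range(len(toks) - n + 1):
                g = tuple(toks[i : i + n])
                total[g] += 1
                seen.add(g)
        docs.update(seen)
    pool = [
        PhraseCandidate(text=" ".join(g), n_words=len(g), total_freq=c, doc_freq=docs[g])
        for g, c in total.items()
    ]
    pool.sort(key=lambda p: p.text)
    return pool


def tfidf_norm(pool: Sequence[PhraseCandidate], n_docs: int) -> list[PhraseCandidate]:
    """Raw score total_freq * ln(N/doc_freq), normalized by the pool maximum."""
    kept = [p for p in pool if p.doc_freq > 0]
    raw = np.array([p.total_freq * math.log(n_docs / p.doc_freq) for p in kept])
    top = raw.max() if len(raw) and raw.max() > 0 else 1.0
    return [replace(p, tfidf_norm=float(r / top)) for p, r in zip(kept, raw)]


def token_idf(seqs: Sequence[TokenSequence]) -> dict[str, float]:
    n = len(seqs)
    df: Counter[str] = Counter()
    for ts in seqs:
        df.update(set(ts.tokens))
    return {t: math.log(n / d) for t, d in df.items()}


def domain_centroid(encoder: Encoder, seqs: Sequence[TokenSequence]) -> np.ndarray:
    vecs = [encoder.encode(ts) for ts in seqs if not ts.is_empty]
    return np.mean(vecs, axis=0)


def relevance_score(phrase: PhraseCandidate | str, encoder: Encoder, centroid: np.ndarray) -> float:
    """(cos(phrase embedding, domain centroid) + 1) / 2, in [0, 1]."""
    tokens = phrase.split() if isinstance(phrase, str) else list(phrase.tokens)
    emb = encoder.encode_tokens(tokens)
    if np.linalg.norm(emb) == 0:
        raise ValueError(f"zero embedding for phrase {phrase!r}")
    return (cosine_similarity(emb, centroid) + 1.0) / 2.0


def specificity_index(
    phrase: PhraseCandidate | str,
    idf: Mapping[str, float],
    n_docs: int,
    p95: float | None = None,
) -> float:
    """Normalized mean token IDF, clipped to [0, 1].

    Unseen tokens take the maximal possible IDF ln(N) (document frequency 1
    would give ln(N/1)).  The normalizer is the 95th-percentile token IDF of
    the corpus vocabulary.
    """
    tokens = phrase.split() if isinstance(phrase, str) else list(phrase.tokens)
    if p95 is None:
        p95 = idf_p95(idf)
    max_idf = math.log(n_docs) if n_docs > 1 else 1.0
    mean_idf = float(np.mean([idf.get(t, max_idf) for t in tokens]))
    if p95 <= 0:
        return 0.0 if mean_idf <= 0 else 1.0
    return float(np.clip(mean_idf / p95, 0.0, 1.0))


def idf_p95(idf: Mapping[str, float]) -> float:
    return float(np.quantile(np.array(list(idf.values())), 0.95))


def score_pool(
    pool: Sequence[PhraseCandidate],
    seqs: Sequence[TokenSequence],
    encoder: Encoder,
    consensus: Mapping[str, float] | None = None,
) -> list[PhraseCandidate]:
    """Populate tfidf_norm, relevance, specificity (and optional consensus)."""
    n_docs = len(seqs)
    scored = tfidf_norm(pool, n_docs)
    idf = token_idf(seqs)
    p95 = idf_p95(idf)
    centroid = domain_centroid(encoder, seqs)
    out = []
    for p in scored:
        out.append(
            replace(
                p,
                relevance=relevance_score(p, encoder, centroid),
                specificity=specificity_index(p, idf, n_docs, p95),
                consensus=None if consensus is None else consensus.get(p.text),
            )
        )
    return out


def quartile_pool_threshold(pool: Sequence[PhraseCandidate]) -> float:
    """Upper quartile (Q3, linear-interpolation quantile) of total frequencies."""
    if not pool:
        raise ValueError("empty pool")
    return float(np.quantile(np.array([p.total_freq for p in pool], dtype=float), 0.75))


def _phase4(
    survivors: list[PhraseCandidate],
    cfg: ScreeningConfig,
    encoder: Encoder | None,
    quality_ratings: Mapping[str, float] | None,
) -> list[PhraseCandidate]:
    kept = [
        p
        for p in survivors
        if p.n_words <= cfg.max_words
        and not (p.n_words == 1 and p.text in cfg.generic_word_list)
        and p.text not in cfg.ambiguity_blocklist
    ]
    if quality_ratings is not None:
        kept = [p for p in kept if quality_ratings.get(p.text, 0.0) >= cfg.min_consensus]
    # near-duplicate merge in canonical order: higher relevance first, then text
    if encoder is not None and len(kept) > 1:
        order = sorted(kept, key=lambda p: (-(p.relevance or 0.0), p.text))
        embs = [encoder.encode_tokens(list(p.tokens)) for p in order]
        merged: list[PhraseCandidate] = []
        merged_embs: list[np.ndarray] = []
        for p, e in zip(order, embs):
            dup = any(
                np.linalg.norm(e) > 0
                and np.linalg.norm(me) > 0
                and cosine_similarity(e, me) >= cfg.merge_similarity
                for me in merged_embs
            )
            if not dup:
                merged.append(p)
                merged_embs.append(e)
        kept = sorted(merged, key=lambda p: p.text)
    return kept


def screen(
    pool: Sequence[PhraseCandidate],
    cfg: ScreeningConfig | None = None,
    quality_ratings: Mapping[str, float] | None = None,
    encoder: Encoder | None = None,
) -> FunnelReport:
    """Run the four-phase funnel; every phase filters the previous survivors.

    The result is independent of the input order: phases operate on
    canonically sorted candidates and the merge step uses a deterministic
    relevance-then-text order.
    """
    cfg = cfg or ScreeningConfig()
    ordered = sorted(pool, key=lambda p: p.text)

    p1 = [p for p in ordered if p.total_freq >= cfg.pool_min_freq]
    p2 = [p for p in p1 if p.total_freq >= cfg.min_total_freq and p.doc_freq >= cfg.min_doc_freq]
    p3 = [
        p
        for p in p2
        if (p.relevance or 0.0) >= cfg.min_relevance
        and (cfg.min_tfidf is None or (p.tfidf_norm or 0.0) >= cfg.min_tfidf)
        and (cfg.min_specificity is None or (p.specificity or 0.0) >= cfg.min_specificity)
    ]
    p4 = _phase4(list(p3), cfg, encoder, quality_ratings)
    return FunnelReport(
        phases=[
            ("phase1_candidate_pool", [p.text for p in p1]),
            ("phase2_frequency_breadth", [p.text for p in p2]),
            ("phase3_semantic_relevance", [p.text for p in p3]),
            ("phase4_quality_filtered", [p.text for p in p4]),
        ]
    )


def sensitivity_analysis(
    pool: Sequence[PhraseCandidate],
    thresholds: Iterable[float] = (0.55, 0.60, 0.65, 0.70, 0.75),
    reference_set: Iterable[str] = (),
    cfg: ScreeningConfig | None = None,
    quality_ratings: Mapping[str, float] | None = None,
    encoder: Encoder | None = None,
) -> SensitivityTable:
    """Re-run Phases 3-4 at each relevance threshold; report retention and
    overlap with the reference set (|retained & reference| / |reference|)."""
    cfg = cfg or ScreeningConfig()
    ref = set(reference_set)
    if not ref:
        raise ValueError("reference_set must be non-empty")
    rows = []
    for thr in thresholds:
        rep = screen(pool, replace(cfg, min_relevance=float(thr)), quality_ratings, encoder)
        retained = set(rep.retained(-1))
        rows.append(
            {
                "threshold": float(thr),
                "n_retained": len(retained),
                "overlap": len(retained & ref) / len(ref),
            }
        )
    return SensitivityTable(rows=pd.DataFrame(rows, columns=["threshold", "n_retained", "overlap"]))
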