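"""Indicator relation matrix: multi-head self-attention under a DAG constraint.

Indicator embeddings are projected per head into query/key/value spaces,
attention weights are row-softmax of QK^T/sqrt(d_k), head outputs are
concatenated, and a bilinear output transform turns each ordered indicator
pair into a directed relation score, giving an n x n matrix C.

Acyclicity of the weighted relation graph is measured by the trace-exponential
penalty

    h(C) = tr(exp(C o C)) - n      (o = Hadamard product)

which is zero exactly when the graph of C o C has no directed cycle.
``enforce_dag`` projects a matrix onto (near-)acyclicity by minimizing a
least-squares departure plus an escalating multiple of h, accepting only
steps that reduce both the composite objective and the penalty itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm

__all__ = [
    "AttentionParams",
    "attention_head",
    "mhsa_relation_matrix",
    "dag_penalty",
    "enforce_dag",
    "symmetrize",
    "is_acyclic",
    "DagEnforcementError",
]


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Seeded matrix with orthonormal columns (or rows when cols > rows)."""
    transpose = cols > rows
    if transpose:
        rows, cols = cols, rows
    a = rng.standard_normal((rows, cols))
    q, r = np.linalg.qr(a)
    sign = np.sign(np.diag(r))
    q *= np.where(sign == 0, 1.0, sign)  # fix QR sign ambiguity for determinism
    return q.T if transpose else q


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections plus the bilinear output transform.

    ``w_src``/``w_dst`` map each indicator's concatenated head vector to
    source and target factors; C = (O w_src)(O w_dst)^T.  This keeps the
    relation matrix equivariant to indicator reordering while remaining a
    linear transform of the concatenated head outputs.
    """

    heads: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (W_Q, W_K, W_V) each d x d_k
    w_src: np.ndarray  # (h*d_k, n_out)
    w_dst: np.ndarray  # (h*d_k, n_out)
    d_k: int = 64
    seed: int = 0
    scale: float = field(default=1.0)

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @classmethod
    def create(
        cls, d: int, n_heads: int = 8, d_k: int = 64, n_out: int | None = None, seed: int = 0
    ) -> "AttentionParams":
        if n_heads < 1:
            raise ValueError("need at least one attention head")
        rng = np.random.default_rng(seed)
        heads = [
            tuple(_orthogonal(rng, d, d_k) for _ in range(3)) for _ in range(n_heads)
        ]
        n_out = n_out or d_k
        w_src = _orthogonal(rng, n_heads * d_k, n_out)
        w_dst = _orthogonal(rng, n_heads * d_k, n_out)
        return cls(heads=heads, w_src=w_src, w_dst=w_dst, d_k=d_k, seed=seed)


def attention_head(
    H: np.ndarray, W_Q: np.ndarray, W_K: np.ndarray, W_V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention for one head.

    Returns (weights, output) with each weight row summing to 1 and
    output = weights @ (H W_V).
    """
    H = np.asarray(H, dtype=float)
    if H.shape[1] != W_Q.shape[0]:
        raise ValueError(
            f"embedding dim {H.shape[1]} does not match projection rows {W_Q.shape[0]}"
        )
    d_k = W_Q.shape[1]
    Q, K, V = H @ W_Q, H @ W_K, H @ W_V
    scores = Q @ K.T / np.sqrt(d_k)
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=1, keepdims=True)
    return weights, weights @ V


def mhsa_relation_matrix(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Concatenate all head outputs and apply the bilinear output transform.

    Deterministic for fixed params; permuting the indicator rows of ``H``
    permutes the rows and columns of C consistently.
    """
    outputs = [attention_head(H, *head)[1] for head in params.heads]
    O = np.concatenate(outputs, axis=1)  # (n, h*d_k)
    return (O @ params.w_src) @ (O @ params.w_dst).T * params.scale


def dag_penalty(C: np.ndarray) -> float:
    """tr(exp(C o C)) - n; nonnegative, and zero iff the graph is acyclic."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("relation matrix must be square")
    n = C.shape[0]
    return float(np.trace(expm(C * C)) - n)


def is_acyclic(C: np.ndarray, threshold: float = 1e-6) -> bool:
    """Discrete check: threshold |entries|, then look for directed cycles."""
    A = (np.abs(np.asarray(C, dtype=float)) > threshold).astype(int)
    np.fill_diagonal(A, A.diagonal())  # self-loops count as cycles
    g = nx.from_numpy_array(A, create_using=nx.DiGraph)
    # self-loops are cycles but nx DAG check already treats them as such
    return nx.is_directed_acyclic_graph(g)


class DagEnforcementError(RuntimeError):
    def __init__(self, penalty: float):
        self.penalty = penalty
        super().__init__(f"failed to reach acyclicity tolerance; final penalty {penalty:.3e}")


def _dag_penalty_grad(C: np.ndarray) -> np.ndarray:
    # d tr(exp(C o C)) / dC = exp(C o C)^T o 2C
    return expm(C * C).T * (2.0 * C)


def enforce_dag(
    C: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 30,
    inner_steps: int = 200,
    lam0: float = 1.0,
    lr: float = 0.1,
    snap_threshold: float = 1e-6,
) -> np.ndarray:
    """Return the nearest (in the least-squares sense of this procedure)
    matrix whose DAG penalty is at most ``tol``.

    Minimizes 0.5 ||X - C||^2 + lam * h(X) by gradient descent with
    backtracking; ``lam`` doubles whenever an inner loop plateaus above the
    tolerance.  Accepted steps never increase h.  Entries whose magnitude
    falls below ``snap_threshold`` are snapped to zero at the end when that
    lowers the penalty further.  Already-acyclic input is returned unchanged.
    Deterministic; raises :class:`DagEnforcementError` if the step budget is
    exhausted above tolerance.
    """
    C = np.asarray(C, dtype=float)
    h0 = dag_penalty(C)
    if h0 <= tol:
        return C.copy()
    X = C.copy()
    h = h0
    lam = lam0
    for _outer in range(max_outer):
        step = lr
        for _inner in range(inner_steps):
            grad = (X - C) + lam * _dag_penalty_grad(X)
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-14:
                break
            f = 0.5 * float(np.sum((X - C) ** 2)) + lam * h
            accepted = False
            for _half in range(40):
                cand = X - step * grad / max(gnorm, 1e-300)
                hc = dag_penalty(cand)
                fc = 0.5 * float(np.sum((cand - C) ** 2)) + lam * hc
                if fc <= f and hc <= h:
                    X, h = cand, hc
                    step = min(step * 1.5, 1.0)
                    accepted = True
                    break
                step *= 0.5
            if not accepted or h <= tol:
                break
        if h <= tol:
            break
        lam *= 2.0
    # snap numerically-dead entries to exact zero when it helps
    snapped = np.where(np.abs(X) < snap_threshold, 0.0, X)
    hs = dag_penalty(snapped)
    if hs <= h:
        X, h = snapped, hs
    # residual cycles of near-zero weight can survive the penalty tolerance;
    # break each by zeroing its smallest entry (this only lowers the penalty,
    # since tr(exp(.)) is monotone in the nonnegative Hadamard square)
    X = _break_residual_cycles(X, snap_threshold)
    h = dag_penalty(X)
    if h > tol:
        raise DagEnforcementError(h)
    return X


def _break_residual_cycles(X: np.ndarray, threshold: float) -> np.ndarray:
    X = X.copy()
    while True:
        A = (np.abs(X) > threshold).astype(int)
        g = nx.from_numpy_array(A, create_using=nx.DiGraph)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return X
        i, j, *_ = min(cycle, key=lambda e: abs(X[e[0], e[1]]))
        X[i, j] = 0.0


def symmetrize(C: np.ndarray) -> np.ndarray:
    """S = (C + C^T) / 2."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("relation matrix must be square")
    return (C + C.T) / 2.0
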