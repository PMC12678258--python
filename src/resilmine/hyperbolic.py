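"""Poincare-ball geometry, stress embedding, and hierarchy-fidelity scoring.

The open unit ball with the hyperbolic metric

    d(x, y) = arcosh(1 + 2 |x - y|^2 / ((1 - |x|^2)(1 - |y|^2)))

hosts the indicator embedding; tree-like structures embed there with far
less distortion than in flat space because ball volume grows exponentially
with radius.  The Hierarchical Fidelity Score (HFS) of an embedding against
a parent->child edge set H is the fraction of edges whose parent sits
strictly closer to the origin than its child.

Embedding is weighted metric stress minimization: points move by projected
gradient descent (with re-clipping into the ball and a backtracking line
search, so the objective never increases over accepted steps), optionally
with a margin term that pushes parents to smaller radii than their children
when the hierarchy is supplied.  A flat-metric twin of the same optimizer
provides the Euclidean baseline for space comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmbeddingSet",
    "poincare_distance",
    "poincare_distance_matrix",
    "clip_to_ball",
    "log_map_origin",
    "hfs",
    "embed_ball",
    "embed_euclidean",
    "distortion_rate",
    "compare_spaces",
]

_EPS = 1e-5


@dataclass
class EmbeddingSet:
    """One point per indicator, tagged with the geometry it lives in."""

    points: np.ndarray  # (n, dim)
    space: str  # "hyperbolic" | "euclidean"
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.space not in ("hyperbolic", "euclidean"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.space == "hyperbolic":
            norms = np.linalg.norm(self.points, axis=1)
            if np.any(norms >= 1.0):
                raise ValueError("hyperbolic points must have norm < 1")

    def distance_matrix(self) -> np.ndarray:
        if self.space == "hyperbolic":
            return poincare_distance_matrix(self.points)
        diff = self.points[:, None, :] - self.points[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def radii(self) -> np.ndarray:
        """Distance of each point from the origin in its own geometry."""
        norms = np.linalg.norm(self.points, axis=1)
        if self.space == "hyperbolic":
            return 2.0 * np.arctanh(np.clip(norms, 0.0, 1.0 - 1e-15))
        return norms


def _check_in_ball(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.linalg.norm(x) >= 1.0:
        raise ValueError(f"point with norm {np.linalg.norm(x):.6f} outside the open unit ball")
    return x


def poincare_distance(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_in_ball(x), _check_in_ball(y)
    num = 2.0 * float(np.sum((x - y) ** 2))
    den = (1.0 - float(np.sum(x**2))) * (1.0 - float(np.sum(y**2)))
    return float(np.arccosh(max(1.0, 1.0 + num / den)))


def poincare_distance_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sq = np.sum(X**2, axis=1)
    if np.any(sq >= 1.0):
        raise ValueError("all points must lie in the open unit ball")
    diff = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    arg = 1.0 + 2.0 * diff / np.outer(1.0 - sq, 1.0 - sq)
    return np.arccosh(np.maximum(arg, 1.0))


def clip_to_ball(x: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Rescale any vector with norm >= 1 - eps onto the sphere of radius 1 - eps."""
    if not 0.0 < eps < 0.1:
        raise ValueError("eps must lie in (0, 0.1)")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        n = np.linalg.norm(x)
        return x * ((1.0 - eps) / n) if n >= 1.0 - eps else x.copy()
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    scale = np.where(norms >= 1.0 - eps, (1.0 - eps) / np.maximum(norms, 1e-300), 1.0)
    return x * scale


def log_map_origin(x: np.ndarray) -> np.ndarray:
    """Tangent-space projection at the origin: v = 2 x / (1 - |x|^2).

    This is the conformal-factor scaling lambda_x * x; see the methods note
    for how it relates to (and differs from) the exact origin log map.
    """
    x = np.asarray(x, dtype=float)
    sq = np.sum(x**2, axis=-1, keepdims=x.ndim > 1)
    if x.ndim == 1:
        sq = float(np.sum(x**2))
        if sq >= 1.0:
            raise ValueError("point outside the open unit ball")
        return (2.0 / (1.0 - sq)) * x
    if np.any(sq >= 1.0):
        raise ValueError("all points must lie in the open unit ball")
    return (2.0 / (1.0 - sq)) * x


def hfs(emb: EmbeddingSet, edges: list[tuple[int, int]]) -> float:
    """Fraction of parent->child edges with the parent strictly nearer the
    origin (the hierarchy root) than the child, in the embedding's geometry."""
    if len(edges) == 0:
        raise ValueError("hierarchy edge set must be non-empty")
    r = emb.radii()
    hits = sum(1 for i, j in edges if r[i] < r[j])
    return hits / len(edges)


def _stress_and_grad_ball(X: np.ndarray, delta: np.ndarray, W: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(X)
    sq = np.sum(X**2, axis=1)
    one = 1.0 - sq
    diff = X[:, None, :] - X[None, :, :]
    A = np.sum(diff**2, axis=-1)
    B = np.outer(one, one)
    u = 1.0 + 2.0 * A / B
    D = np.arccosh(np.maximum(u, 1.0))
    R = D - delta
    np.fill_diagonal(R, 0.0)
    stress = float(np.sum(W * R**2) / 2.0)
    # each unordered pair appears twice in the double sum, hence the factor 2
    dD = 2.0 * W * R
    # dD/du = 1/sqrt(u^2-1); guard the diagonal/coincident pairs
    root = np.sqrt(np.maximum(u**2 - 1.0, 1e-18))
    du = dD / root
    np.fill_diagonal(du, 0.0)
    # u = 1 + 2A/B:  dA/dx_i = 2(x_i - x_j);  dB/dx_i = -2 x_i (1-|x_j|^2)
    coef_diff = 4.0 * du / B  # multiplies (x_i - x_j)
    grad = (coef_diff.sum(axis=1)[:, None] * X) - (coef_diff @ X)
    # term from dB/dx_i: d(2A/B)/dx_i |_B = -2A/B^2 * dB/dx_i = 4A x_i (1-|x_j|^2)/B^2
    coef_b = 4.0 * du * A * (1.0 - sq)[None, :] / B**2
    grad += coef_b.sum(axis=1)[:, None] * X
    return stress, grad


def _stress_and_grad_flat(X: np.ndarray, delta: np.ndarray, W: np.ndarray) -> tuple[float, np.ndarray]:
    diff = X[:, None, :] - X[None, :, :]
    D = np.linalg.norm(diff, axis=-1)
    R = D - delta
    np.fill_diagonal(R, 0.0)
    stress = float(np.sum(W * R**2) / 2.0)
    coef = 2.0 * W * R / np.maximum(D, 1e-18)
    np.fill_diagonal(coef, 0.0)
    grad = coef.sum(axis=1)[:, None] * X - coef @ X
    return stress, grad


def _margin_and_grad(X: np.ndarray, edges: list[tuple[int, int]], margin: float) -> tuple[float, np.ndarray]:
    """Hinge penalty sum relu(|x_parent| - |x_child| + margin)^2."""
    val = 0.0
    grad = np.zeros_like(X)
    norms = np.linalg.norm(X, axis=1)
    for i, j in edges:
        gap = norms[i] - norms[j] + margin
        if gap > 0:
            val += gap**2
            if norms[i] > 1e-12:
                grad[i] += 2.0 * gap * X[i] / norms[i]
            if norms[j] > 1e-12:
                grad[j] -= 2.0 * gap * X[j] / norms[j]
    return val, grad


def _descend(
    X0: np.ndarray,
    objective,
    n_iter: int,
    lr: float,
    project=None,
    precondition=None,
) -> np.ndarray:
    """Gradient descent with backtracking; the objective never increases
    over accepted steps.  ``project`` re-clips iterates into the feasible
    set; ``precondition`` rescales the raw gradient into a descent direction
    (used for the Riemannian metric correction in the ball)."""
    X = X0.copy()
    f, g = objective(X)
    step = lr
    for _ in range(n_iter):
        if not np.isfinite(f):
            raise FloatingPointError("embedding objective diverged")
        d = g if precondition is None else precondition(X, g)
        if np.linalg.norm(d) < 1e-12:
            break
        accepted = False
        for _half in range(30):
            cand = X - step * d
            if project is not None:
                cand = project(cand)
            fc, gc = objective(cand)
            if fc <= f:
                X, f, g = cand, fc, gc
                step = min(step * 1.5, lr * 10)
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return X


def _riemannian_precondition(X: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Scale Euclidean gradients by the inverse squared conformal factor
    (1 - |x|^2)^2 / 4, the natural metric correction in the Poincare ball;
    without it points near the boundary barely move."""
    return g * (((1.0 - np.sum(X**2, axis=1)) ** 2) / 4.0)[:, None]


def embed_ball(
    dissimilarity: np.ndarray,
    H: list[tuple[int, int]] | None = None,
    dim: int = 2,
    seed: int = 0,
    iters: int = 2000,
    lr: float = 0.05,
    margin_weight: float = 1.0,
    margin: float = 0.02,
    weights: np.ndarray | None = None,
) -> EmbeddingSet:
    """Fit ball points whose pairwise hyperbolic distances match the targets.

    Minimizes the weighted metric stress sum_ij w_ij (d(x_i,x_j) - delta_ij)^2
    by projected gradient descent (points re-clipped into the ball after each
    step).  When ``H`` is given, a hinge term with weight ``margin_weight``
    additionally pushes each parent to a strictly smaller radius than its
    children.  Deterministic for fixed inputs and seed.
    """
    delta = np.asarray(dissimilarity, dtype=float)
    if delta.shape[0] != delta.shape[1] or not np.allclose(delta, delta.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = delta.shape[0]
    W = np.ones((n, n)) if weights is None else np.asarray(weights, dtype=float)
    np.fill_diagonal(W, 0.0)
    rng = np.random.default_rng(seed)
    X0 = rng.uniform(-1.0, 1.0, size=(n, dim))
    X0 *= 0.1 * rng.random((n, 1)) / np.maximum(np.linalg.norm(X0, axis=1, keepdims=True), 1e-12)

    use_margin = H is not None and len(H) > 0 and margin_weight > 0

    def objective(X):
        f, g = _stress_and_grad_ball(X, delta, W)
        if use_margin:
            fm, gm = _margin_and_grad(X, H, margin)
            f += margin_weight * fm
            g = g + margin_weight * gm
        return f, g

    X = _descend(
        X0,
        objective,
        iters,
        lr,
        project=lambda Y: clip_to_ball(Y, _EPS),
        precondition=_riemannian_precondition,
    )
    return EmbeddingSet(points=X, space="hyperbolic")


def embed_euclidean(
    dissimilarity: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    iters: int = 2000,
    lr: float = 0.05,
    weights: np.ndarray | None = None,
) -> EmbeddingSet:
    """Flat-metric twin of :func:`embed_ball` (metric least-squares scaling)."""
    delta = np.asarray(dissimilarity, dtype=float)
    if delta.shape[0] != delta.shape[1] or not np.allclose(delta, delta.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    n = delta.shape[0]
    W = np.ones((n, n)) if weights is None else np.asarray(weights, dtype=float)
    np.fill_diagonal(W, 0.0)
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n, dim)) * 0.1
    X = _descend(X0, lambda X: _stress_and_grad_flat(X, delta, W), iters, lr)
    return EmbeddingSet(points=X, space="euclidean")


def distortion_rate(emb: EmbeddingSet, reference: np.ndarray) -> float:
    """Scale-aligned mean relative distortion against reference distances.

    The embedded distance matrix is first rescaled by the least-squares
    scalar s = <d_emb, d_ref> / <d_emb, d_emb>; the statistic is the mean of
    |s*d_emb - d_ref| / d_ref over off-diagonal pairs, so any embedding
    reproducing the reference up to a global scale scores zero.
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.shape[0]
    iu = np.triu_indices(n, k=1)
    if np.any(ref[iu] <= 0):
        raise ValueError("reference dissimilarities must be positive off the diagonal")
    d = emb.distance_matrix()[iu]
    r = ref[iu]
    denom = float(np.dot(d, d))
    s = float(np.dot(d, r)) / denom if denom > 0 else 1.0
    return float(np.mean(np.abs(s * d - r) / r))


def compare_spaces(
    dissimilarity: np.ndarray,
    H: list[tuple[int, int]],
    dim: int = 2,
    seed: int = 0,
    iters: int = 2000,
    lr: float = 0.05,
    margin_weight: float = 1.0,
) -> dict[str, float]:
    """Fit both geometries from the same inputs/seed and report HFS and
    distortion for each."""
    ball = embed_ball(
        dissimilarity, H=H, dim=dim, seed=seed, iters=iters, lr=lr, margin_weight=margin_weight
    )
    flat = embed_euclidean(dissimilarity, dim=dim, seed=seed, iters=iters, lr=lr)
    return {
        "hfs_hyperbolic": hfs(ball, H),
        "hfs_euclidean": hfs(flat, H),
        "distortion_hyperbolic": distortion_rate(ball, dissimilarity),
        "distortion_euclidean": distortion_rate(flat, dissimilarity),
    }
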