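"""Barnes-Hut stochastic neighbor embedding (BH-SNE) of signature vectors.

t-SNE places each fragment in 2-D so that the heavy-tailed Student-t
similarity q_ij of the embedded points matches the Gaussian input
similarity p_ij, by gradient descent on the Kullback-Leibler divergence
KL(P || Q). Input similarities are sparse: each point keeps its
floor(3 * perplexity) exact nearest neighbors, with a per-point kernel
precision beta_i calibrated by binary search so the conditional
distribution has the target perplexity (2^H). The O(n^2) repulsive term
of the gradient is approximated with a quadtree (Barnes-Hut); the
accuracy parameter theta = 0 recovers the exact method.

Runs are bit-reproducible for a fixed seed: initialization is keyed to
(seed, row index), neighbor ties break by row index, and execution is
serial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._bh import _attraction, _repulsion
from .signatures import SignatureMatrix

__all__ = [
    "TsneParams",
    "AffinityMatrix",
    "EmbeddingResult",
    "conditional_affinities",
    "symmetrize",
    "joint_affinities",
    "exact_gradient",
    "bh_gradient",
    "kl_divergence",
    "run_tsne",
]

_EPS = 1e-12  # floor applied inside logarithms only


@dataclass(frozen=True)
class TsneParams:
    """BH-SNE hyperparameters.

    Defaults follow the reference Barnes-Hut t-SNE implementation:
    perplexity 30 (effective neighbor count), theta 0.5 (quadtree
    accuracy; 0 = exact), 1000 iterations with early exaggeration 12 for
    the first 250, learning rate 200, momentum 0.5 switching to 0.8 at
    iteration 250. ``n_threads`` is recorded in run manifests; execution
    is serial so that results are reproducible bit-for-bit.
    """

    perplexity: float = 30.0
    theta: float = 0.5
    n_iter: int = 1000
    early_exaggeration: float = 12.0
    exaggeration_iters: int = 250
    learning_rate: float = 200.0
    momentum_initial: float = 0.5
    momentum_final: float = 0.8
    momentum_switch_iter: int = 250
    seed: int = 0
    n_threads: int = 1

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be > 0")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.n_threads < 1:
            raise ValueError("n_threads must be >= 1")


@dataclass
class AffinityMatrix:
    """Sparse affinities over sequence pairs.

    ``kind`` is "conditional" (rows are p_{j|i}, each summing to 1 over
    the stored neighbors) or "joint" (symmetric p_ij summing to 1 over
    all stored pairs). ``betas`` are the per-point Gaussian precisions
    found by the perplexity search.
    """

    P: sparse.csr_matrix
    betas: np.ndarray
    kind: str

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class EmbeddingResult:
    """2-D coordinates with the KL-divergence trace of the optimization."""

    coords: np.ndarray
    kl_trace: list[tuple[int, float]]
    params: TsneParams
    ids: list[str] | None = None


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", X, X)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D2, 0.0, out=D2)
    np.fill_diagonal(D2, 0.0)
    return D2


def _entropy_bits(beta: float, d2: np.ndarray) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) of p_j ∝ exp(-beta d2_j), and the p vector."""
    shifted = d2 - d2.min()
    e = np.exp(-beta * shifted)
    s = e.sum()
    p = e / s
    h_nats = math.log(s) + beta * float(np.dot(shifted, p))
    return h_nats / math.log(2.0), p


def _search_beta(d2: np.ndarray, log2_perp: float, tol: float = 1e-5,
                 max_iter: int = 200) -> tuple[float, np.ndarray]:
    if d2.max() == 0.0:
        # all stored neighbors coincide with the point: uniform conditionals
        return 1.0, np.full(len(d2), 1.0 / len(d2))
    beta = 1.0
    beta_min = -np.inf
    beta_max = np.inf
    h, p = _entropy_bits(beta, d2)
    for _ in range(max_iter):
        diff = h - log2_perp
        if abs(diff) <= tol:
            break
        if diff > 0:  # entropy too high -> narrow the kernel
            beta_min = beta
            beta = beta * 2.0 if not np.isfinite(beta_max) else 0.5 * (beta + beta_max)
        else:
            beta_max = beta
            beta = beta * 0.5 if not np.isfinite(beta_min) else 0.5 * (beta + beta_min)
        h, p = _entropy_bits(beta, d2)
    return beta, p


def conditional_affinities(X: np.ndarray, perplexity: float) -> AffinityMatrix:
    """Per-point Gaussian conditionals over exact nearest neighbors.

    Each point keeps its floor(3 * perplexity) nearest neighbors by
    Euclidean distance (ties broken by row index), and beta_i is binary-
    searched until |log2(perplexity) - H(p_{.|i})| <= 1e-5.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 points")
    if perplexity > n - 1:
        raise ValueError(
            f"perplexity {perplexity} unreachable with n={n}: the entropy of a "
            f"distribution over at most {n - 1} neighbors is below log2(perplexity)"
        )
    # 3*perplexity neighbors, capped at n-1 (small n falls back to the
    # exact all-neighbors method)
    k = min(int(math.floor(3 * perplexity)), n - 1)
    D2 = _squared_distances(X)
    np.fill_diagonal(D2, np.inf)
    # stable sort keeps equal distances in row-index order
    order = np.argsort(D2, axis=1, kind="stable")[:, :k]

    log2_perp = math.log2(perplexity)
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    vals = np.empty(n * k, dtype=float)
    betas = np.empty(n, dtype=float)
    for i in range(n):
        betas[i], p = _search_beta(D2[i, order[i]], log2_perp)
        vals[i * k : (i + 1) * k] = p
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return AffinityMatrix(P=P, betas=betas, kind="conditional")


def symmetrize(conditional: AffinityMatrix) -> AffinityMatrix:
    """Joint affinities p_ij = (p_{j|i} + p_{i|j}) / (2n); sums to 1."""
    if conditional.kind != "conditional":
        raise ValueError("expected conditional affinities")
    n = conditional.n
    C = conditional.P
    P = (C + C.T) / (2.0 * n)
    return AffinityMatrix(P=P.tocsr(), betas=conditional.betas, kind="joint")


def joint_affinities(X: np.ndarray, perplexity: float) -> AffinityMatrix:
    return symmetrize(conditional_affinities(X, perplexity))


def _as_joint_csr(P) -> sparse.csr_matrix:
    if isinstance(P, AffinityMatrix):
        if P.kind != "joint":
            raise ValueError("gradient requires joint (symmetrized) affinities")
        return P.P
    if sparse.issparse(P):
        return P.tocsr()
    return sparse.csr_matrix(P)


def exact_gradient(P, Y: np.ndarray) -> np.ndarray:
    """O(n^2) reference gradient 4 sum_j (p_ij - q_ij) q#_ij (y_i - y_j).

    q#_ij = 1 / (1 + |y_i - y_j|^2) is the unnormalized Student-t kernel.
    Kept as the dense oracle against which the Barnes-Hut approximation
    is validated.
    """
    Pd = np.asarray(_as_joint_csr(P).todense(), dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    num = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Z = num.sum()
    W = (Pd - num / Z) * num
    return 4.0 * (W.sum(axis=1)[:, None] * Y - W @ Y)


def bh_gradient(P, Y: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """Barnes-Hut gradient: sparse attraction + quadtree-approximated repulsion."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    Pc = _as_joint_csr(P)
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    n = Y.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    F_attr = _attraction(Y, Pc.indptr, Pc.indices, Pc.data)
    F_rep, Zi = _repulsion(Y, theta)
    Z = Zi.sum() - n  # remove each point's self term (q = 1)
    return 4.0 * (F_attr - F_rep / Z)


def kl_divergence(P, Y: np.ndarray) -> float:
    """KL(P || Q) over the stored pairs, with q normalized over all pairs."""
    Pc = _as_joint_csr(P).tocoo()
    Y = np.asarray(Y, dtype=float)
    num = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Z = num.sum()
    q = num[Pc.row, Pc.col] / Z
    p = Pc.data
    mask = p > 0
    p = p[mask]
    q = q[mask]
    return float(np.sum(p * (np.log(np.maximum(p, _EPS)) - np.log(np.maximum(q, _EPS)))))


def _initial_coords(n: int, seed: int) -> np.ndarray:
    """Gaussian(0, 1e-4) initialization keyed to (seed, row index).

    Each row's draw depends only on the seed and its own index, so
    permuting the input rows permutes the initialization identically.
    """
    Y = np.empty((n, 2))
    for i in range(n):
        Y[i] = np.random.default_rng([seed, i]).standard_normal(2)
    return Y * 1e-4


def run_tsne(
    X, params: TsneParams | None = None, init: np.ndarray | None = None
) -> EmbeddingResult:
    """Embed rows of X (array or SignatureMatrix) into 2-D by BH-SNE.

    Gradient descent with per-parameter adaptive gains, the momentum
    schedule, and early exaggeration of P for the first
    ``exaggeration_iters`` iterations. The KL divergence (of the
    un-exaggerated P) is recorded every 50 iterations and at the end.
    Raises if coordinates go non-finite rather than clipping silently.
    ``init`` overrides the seeded Gaussian initialization (n × 2).
    """
    if params is None:
        params = TsneParams()
    ids = None
    if isinstance(X, SignatureMatrix):
        ids = list(X.ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 points to embed")

    P = joint_affinities(X, params.perplexity)
    P_plain = P.P
    P_exag = P_plain * params.early_exaggeration

    if init is not None:
        Y = np.array(init, dtype=float)
        if Y.shape != (n, 2):
            raise ValueError(f"init shape {Y.shape} != ({n}, 2)")
    else:
        Y = _initial_coords(n, params.seed)
    inc = np.zeros_like(Y)
    gains = np.ones_like(Y)
    trace: list[tuple[int, float]] = []

    for it in range(params.n_iter):
        P_run = P_exag if it < params.exaggeration_iters else P_plain
        momentum = (
            params.momentum_initial
            if it < params.momentum_switch_iter
            else params.momentum_final
        )
        grad = bh_gradient(P_run, Y, params.theta)
        same_sign = np.sign(grad) == np.sign(inc)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        np.maximum(gains, 0.01, out=gains)
        inc = momentum * inc - params.learning_rate * gains * grad
        Y = Y + inc
        Y -= Y.mean(axis=0)
        if not np.isfinite(Y).all():
            raise FloatingPointError(
                f"non-finite embedding coordinates at iteration {it + 1}; "
                "try a lower learning rate"
            )
        if (it + 1) % 50 == 0 or it + 1 == params.n_iter:
            trace.append((it + 1, kl_divergence(P_plain, Y)))

    return EmbeddingResult(coords=Y, kl_trace=trace, params=params, ids=ids)
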