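"""Multi-level hypergraph-convolution node embeddings.

The PPI adjacency is first enhanced with an attribute-similarity graph
(common-neighbor counts, row-thresholded to suppress weak false-positive
links): Ã = A + μ·Ŝ. A graph-convolution step on Ã produces the input features
φ(1) = D^{-1/2}·Ã·D^{-1/2}·φ(0)·W₀ with φ(0) = A and W₀ a seeded random
projection to dimension d. At every compression level a two-layer hypergraph
convolution Z = ReLU(M·ReLU(M·φ·θ₁)·θ₂) with propagation operator
M = Dv^{-1/2}·H·W·De^{-1/2}·Hᵀ·Dv^{-1/2} yields supernode embeddings, which
are redistributed to their constituent proteins with degree-proportional
weights and concatenated across levels into the final embedding FD.

No loss function is imposed by default: θ₁, θ₂ are fan-in-scaled seeded random
matrices (untrained graph filtering), which keeps runs reproducible. An
optional training mode fits θ by gradient descent on a logistic reconstruction
of Ã from Z·Zᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .compression import LevelStack
from .hypergraph import Hypergraph
from .ppi_io import PPINetwork

__all__ = [
    "EmbeddingSet",
    "attribute_similarity",
    "enhanced_adjacency",
    "initial_features",
    "hypergraph_convolve",
    "redistribute",
    "concat_embeddings",
    "embed_network",
]


@dataclass
class EmbeddingSet:
    """Per-level supernode embeddings plus the concatenated final matrix."""

    node_ids: tuple[str, ...]
    per_level: list[np.ndarray]       # level ℓ: (n_level, d)
    redistributed: list[np.ndarray]   # level ℓ: (n_original, d)
    final: np.ndarray                 # (n_original, d × level_count)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.final)):
            raise ValueError("non-finite entries in final embedding")
        if self.final.shape[0] != len(self.node_ids):
            raise ValueError("final embedding row count mismatch")


def attribute_similarity(ppi: PPINetwork) -> sp.csr_matrix:
    """Thresholded common-neighbor similarity Ŝ.

    S(i,j) = xᵢᵀxⱼ with xᵢ the i-th adjacency row, i.e. the number of shared
    neighbors. Row i keeps S(i,j) only when it is at least the minimum
    similarity between i and its own neighbors; the result is re-symmetrized
    by elementwise max, and the diagonal is zeroed (self-similarity carries no
    link information).
    """
    A = ppi.adjacency()
    S = (A @ A).tolil()
    S.setdiag(0.0)
    S = S.tocsr()
    S.eliminate_zeros()

    n = ppi.n_nodes
    # row thresholds: min S(i,k) over PPI neighbors k of i
    thr = np.zeros(n)
    A_csr = A.tocsr()
    for i in range(n):
        nbrs = A_csr.indices[A_csr.indptr[i]:A_csr.indptr[i + 1]]
        svals = np.asarray(S[i, nbrs].todense()).ravel() if len(nbrs) else np.array([0.0])
        thr[i] = svals.min()

    S = S.tocoo()
    keep = S.data >= thr[S.row]
    s_row = sp.csr_matrix((S.data[keep], (S.row[keep], S.col[keep])), shape=(n, n))
    return s_row.maximum(s_row.T).tocsr()


def enhanced_adjacency(ppi: PPINetwork, s_hat: sp.spmatrix, mu: float) -> sp.csr_matrix:
    """Ã = A + μ·Ŝ, the similarity-enhanced adjacency."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return (ppi.adjacency() + mu * s_hat.tocsr()).tocsr()


def _sym_norm(mat: sp.spmatrix) -> sp.csr_matrix:
    """D^{-1/2}·mat·D^{-1/2} with D the row-sum degree matrix."""
    deg = np.asarray(mat.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("zero-degree row: cannot normalize")
    d = sp.diags(1.0 / np.sqrt(deg))
    return (d @ mat @ d).tocsr()


def _uniform_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def initial_features(ppi: PPINetwork, a_tilde: sp.spmatrix, d: int,
                     seed: int = 0) -> np.ndarray:
    """First-layer features φ(1) = D^{-1/2}·Ã·D^{-1/2}·φ(0)·W₀.

    φ(0) is the PPI adjacency; W₀ is an n×d fan-in-scaled random projection
    drawn from ``seed``.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    norm = _sym_norm(a_tilde)
    rng = np.random.default_rng(seed)
    w0 = _uniform_init(rng, ppi.n_nodes, d)
    phi0 = ppi.adjacency()
    return np.asarray(norm @ (phi0 @ w0))


def propagation_operator(hg: Hypergraph) -> sp.csr_matrix:
    """M = Dv^{-1/2}·H·W·De^{-1/2}·Hᵀ·Dv^{-1/2}; zero-degree nodes are left
    untouched (their rows/columns stay zero)."""
    H = hg.incidence()
    dv = hg.node_degrees()
    de = hg.hyperedge_degrees()
    dv_inv = np.where(dv > 0, 1.0 / np.sqrt(np.where(dv > 0, dv, 1.0)), 0.0)
    Dvi = sp.diags(dv_inv)
    W = sp.diags(hg.edge_weights())
    Dei = sp.diags(1.0 / np.sqrt(de))
    return (Dvi @ H @ W @ Dei @ H.T @ Dvi).tocsr()


def hypergraph_convolve(level_hg: Hypergraph, features: np.ndarray,
                        params_seed: int = 0,
                        theta: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Two-layer hypergraph convolution Z = ReLU(M·ReLU(M·φ·θ₁)·θ₂).

    θ₁, θ₂ are d×d fan-in-scaled random matrices drawn from ``params_seed``
    unless given explicitly (trained mode).
    """
    if features.shape[0] != level_hg.n_nodes:
        raise ValueError("feature row count does not match level node count")
    M = propagation_operator(level_hg)
    d = features.shape[1]
    if theta is None:
        rng = np.random.default_rng(params_seed)
        theta = (_uniform_init(rng, d, d), _uniform_init(rng, d, d))
    z1 = np.maximum(M @ features @ theta[0], 0.0)
    z2 = np.maximum(M @ z1 @ theta[1], 0.0)
    return np.asarray(z2)


def redistribute(stack: LevelStack, per_level: list[np.ndarray],
                 dv_original: np.ndarray) -> list[np.ndarray]:
    """Hand each supernode's embedding back to its proteins.

    Node v in supernode n receives ω(v)·GZ(n) with
    ω(v) = Dv(v)/Σ_{u∈SN(n)} Dv(u); weights within a supernode sum to one.
    """
    node_ids = stack.levels[0].node_ids
    idx = {v: i for i, v in enumerate(node_ids)}
    out: list[np.ndarray] = []
    for level, gz in enumerate(per_level):
        lineage = stack.lineage[level]
        level_nodes = stack.levels[level].node_ids
        dg = np.zeros((len(node_ids), gz.shape[1]))
        assigned = np.zeros(len(node_ids), dtype=bool)
        for sn_pos, sn in enumerate(level_nodes):
            members = lineage[sn]
            mem_idx = np.array([idx[v] for v in members])
            w = dv_original[mem_idx]
            total = w.sum()
            w = w / total if total > 0 else np.full(len(mem_idx), 1.0 / len(mem_idx))
            dg[mem_idx] = np.outer(w, gz[sn_pos])
            assigned[mem_idx] = True
        if not assigned.all():
            raise ValueError("lineage does not cover all original nodes")
        out.append(dg)
    return out


def concat_embeddings(redistributed: list[np.ndarray]) -> np.ndarray:
    """FD: row v = [DG_level1(v) | DG_level2(v) | …]."""
    if len({m.shape[0] for m in redistributed}) != 1:
        raise ValueError("ragged levels: inconsistent row counts")
    return np.hstack(redistributed)


def _train_theta(M: sp.csr_matrix, features: np.ndarray, target: np.ndarray,
                 seed: int, epochs: int, lr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Fit θ₁, θ₂ by full-batch gradient descent on a logistic reconstruction
    of the (binarized) enhanced adjacency from Z·Zᵀ."""
    d = features.shape[1]
    rng = np.random.default_rng(seed)
    th1, th2 = _uniform_init(rng, d, d), _uniform_init(rng, d, d)
    mf = np.asarray(M @ features)
    n = target.shape[0]
    for _ in range(epochs):
        a1 = mf @ th1
        z1 = np.maximum(a1, 0.0)
        mz1 = np.asarray(M @ z1)
        a2 = mz1 @ th2
        z2 = np.maximum(a2, 0.0)
        logits = z2 @ z2.T
        probs = 1.0 / (1.0 + np.exp(-logits))
        dlogits = (probs - target) / (n * n)
        dz2 = (dlogits + dlogits.T) @ z2
        da2 = dz2 * (a2 > 0)
        dth2 = mz1.T @ da2
        dz1 = np.asarray(M @ (da2 @ th2.T))
        da1 = dz1 * (a1 > 0)
        dth1 = mf.T @ da1
        th1 -= lr * dth1
        th2 -= lr * dth2
    return th1, th2


def reconstruction_loss(z: np.ndarray, target: np.ndarray) -> float:
    """Mean logistic cross-entropy between σ(Z·Zᵀ) and the 0/1 target."""
    logits = z @ z.T
    # stable BCE-with-logits
    loss = np.maximum(logits, 0) - logits * target + np.log1p(np.exp(-np.abs(logits)))
    return float(loss.mean())


def embed_network(ppi: PPINetwork, stack: LevelStack, dim: int = 64,
                  mu: float = 0.5, seed: int = 0, train_mode: str = "off",
                  epochs: int = 30) -> EmbeddingSet:
    """Run the full embedding stage over a compression stack.

    Level-1 features are φ(1); coarser levels use the Dv-weighted average of
    their constituent proteins' φ(1) rows. ``train_mode`` is "off" (seeded
    untrained propagation, default) or "reconstruction".
    """
    if train_mode not in ("off", "reconstruction"):
        raise ValueError(f"unknown train_mode: {train_mode!r}")
    s_hat = attribute_similarity(ppi)
    a_tilde = enhanced_adjacency(ppi, s_hat, mu)
    phi1 = initial_features(ppi, a_tilde, dim, seed=seed)

    original = stack.levels[0]
    dv0 = original.node_degrees()
    idx0 = original.index

    theta = None
    if train_mode == "reconstruction":
        target = (np.asarray(a_tilde.todense()) > 0).astype(float)
        M0 = propagation_operator(original)
        theta = _train_theta(M0, phi1, target, seed=(seed + 1) % (2**31),
                             epochs=epochs)

    per_level: list[np.ndarray] = []
    for level, hg in enumerate(stack.levels):
        if level == 0:
            feats = phi1
        else:
            feats = np.zeros((hg.n_nodes, dim))
            for pos, sn in enumerate(hg.node_ids):
                members = stack.lineage[level][sn]
                mi = np.array([idx0[v] for v in members])
                w = dv0[mi]
                w = w / w.sum() if w.sum() > 0 else np.full(len(mi), 1.0 / len(mi))
                feats[pos] = w @ phi1[mi]
        params_seed = (seed * 0x9E3779B1 + 7919 * (level + 1)) % (2**31)
        per_level.append(hypergraph_convolve(hg, feats, params_seed=params_seed,
                                             theta=theta))

    redist = redistribute(stack, per_level, dv0)
    final = concat_embeddings(redist)
    return EmbeddingSet(node_ids=original.node_ids, per_level=per_level,
                        redistributed=redist, final=final)
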