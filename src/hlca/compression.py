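"""Degree-preserving hypergraph modularity and hierarchical compression.

The hypergraph is converted to a weighted graph. Replacing each hyperedge by a
clique (A_clique = H·W·Hᵀ) biases degrees, so the modularity uses the
normalized form A_hyp = H·W·(De−I)⁻¹·Hᵀ, whose off-diagonal row sums equal the
hypergraph node degrees Dv exactly (degree preservation). Against the
configuration null model P(i,j) = Dv(i)·Dv(j)/ΣDv this gives a Newman-style
modularity Q = (1/2m)·Σ_ij (A_hyp − P)·δ(c_i, c_j), where self-pairs are
excluded from the A_hyp term (self-loops are removed from the weighted graph)
but kept in the null term, and m = ΣDv/2.

Compression alternates seeded local-move modularity optimization with module
aggregation into supernodes, producing a stack of successively smaller
hypergraphs with full lineage back to the original proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hypergraph import Hypergraph, total_node_degree

__all__ = [
    "Partition",
    "LevelStack",
    "clique_adjacency",
    "normalized_adjacency",
    "null_expectation",
    "modularity",
    "optimize_partition",
    "aggregate",
    "compress",
]

GAIN_TOL = 1e-10


@dataclass(frozen=True)
class Partition:
    """Node → community assignment with dense integer labels."""

    assignment: dict[str, int]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def labels(self, node_ids: tuple[str, ...]) -> np.ndarray:
        return np.array([self.assignment[v] for v in node_ids], dtype=int)


@dataclass
class LevelStack:
    """The sequence G1…Ghe of compressed hypergraphs with lineage maps.

    ``lineage[ℓ]`` maps each level-ℓ node to the frozenset of *original*
    protein identifiers it aggregates; at level 0 every node maps to itself.
    """

    levels: list[Hypergraph]
    lineage: list[dict[str, frozenset[str]]]
    q_values: list[float] = field(default_factory=list)

    @property
    def level_count(self) -> int:
        return len(self.levels)


def clique_adjacency(hg: Hypergraph) -> sp.csr_matrix:
    """Raw clique-expansion weights H·W·Hᵀ (diagonal retained)."""
    H = hg.incidence()
    W = sp.diags(hg.edge_weights())
    return (H @ W @ H.T).tocsr()


def normalized_adjacency(hg: Hypergraph) -> sp.csr_matrix:
    """Degree-preserving weighted adjacency H·W·(De−I)⁻¹·Hᵀ.

    For every node i, the off-diagonal row sum equals Dv(i) exactly.
    """
    De = hg.hyperedge_degrees()
    if np.any(De < 2):
        raise ValueError("hyperedge of size 1 encountered; (De - I) not invertible")
    H = hg.incidence()
    scale = sp.diags(hg.edge_weights() / (De - 1.0))
    return (H @ scale @ H.T).tocsr()


def null_expectation(hg: Hypergraph) -> np.ndarray:
    """Configuration-model expectation P(i,j) = Dv(i)·Dv(j)/ΣDv (rank one)."""
    dv = hg.node_degrees()
    return np.outer(dv, dv) / total_node_degree(hg)


def _offdiag(a: sp.csr_matrix) -> sp.csr_matrix:
    a = a.tolil(copy=True)
    a.setdiag(0.0)
    return a.tocsr()


def modularity(hg: Hypergraph, p: Partition) -> float:
    """Q = (1/2m)·Σ_{c_i=c_j} (A_hyp − P)(i,j), self-pairs off the A term.

    m is half the total edge weight of the weighted graph; by degree
    preservation this equals ΣDv/2.
    """
    dv = hg.node_degrees()
    two_m = float(dv.sum())
    if two_m <= 0:
        raise ValueError("degenerate weighted graph (m = 0)")
    labels = p.labels(hg.node_ids)
    A = _offdiag(normalized_adjacency(hg)).tocoo()
    same = labels[A.row] == labels[A.col]
    w_in = float(A.data[same].sum())
    d_comm = np.bincount(labels, weights=dv)
    null = float((d_comm ** 2).sum()) / two_m
    return (w_in - null) / two_m


def optimize_partition(hg: Hypergraph, seed: int = 0) -> Partition:
    """Local-move modularity maximization (one Louvain level).

    Every node starts in its own community; sweeps visit nodes in a seeded
    random order and move a node to the neighboring community with the best
    strictly positive gain (ties toward the lowest label), until a full sweep
    yields no improvement.
    """
    n = hg.n_nodes
    dv = hg.node_degrees()
    two_m = float(dv.sum())
    if two_m <= 0:
        raise ValueError("degenerate weighted graph (m = 0)")
    m = two_m / 2.0
    A = _offdiag(normalized_adjacency(hg))
    comm = np.arange(n)
    comm_deg = dv.copy()
    rng = np.random.default_rng(seed)

    indptr, indices, data = A.indptr, A.indices, A.data
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            c = comm[i]
            w_to: dict[int, float] = {}
            for pos in range(indptr[i], indptr[i + 1]):
                j = indices[pos]
                if j == i:
                    continue
                cj = comm[j]
                w_to[cj] = w_to.get(cj, 0.0) + data[pos]
            comm_deg[c] -= dv[i]
            w_ic = w_to.get(c, 0.0)
            best_c, best_gain = c, 0.0
            for b in sorted(w_to):
                if b == c:
                    continue
                gain = (w_to[b] - w_ic) / m \
                    - dv[i] * (comm_deg[b] - comm_deg[c]) / (2.0 * m * m)
                if gain > best_gain + GAIN_TOL:
                    best_gain, best_c = gain, b
            comm[i] = best_c
            comm_deg[best_c] += dv[i]
            if best_c != c:
                improved = True

    # dense relabel in order of first appearance over node index order
    relabel: dict[int, int] = {}
    for c in comm:
        if c not in relabel:
            relabel[c] = len(relabel)
    return Partition({v: relabel[comm[i]] for i, v in enumerate(hg.node_ids)})


def aggregate(hg: Hypergraph, p: Partition) -> tuple[Hypergraph, dict[str, frozenset[str]]]:
    """Collapse each community into a supernode.

    Each hyperedge maps to the set of supernodes it touches; size-1 images are
    dropped (fully internal hyperedges) and identical images merged. Weights,
    De and Dv are recomputed from the new sets. Returns the new hypergraph and
    a map supernode-id → member node-ids of the *current* level.
    """
    labels = p.labels(hg.node_ids)
    node_of = {c: f"m{c}" for c in sorted(set(labels))}
    groups: dict[str, set[str]] = {node_of[c]: set() for c in node_of}
    for v, c in zip(hg.node_ids, labels):
        groups[node_of[c]].add(v)

    seen: set[frozenset[str]] = set()
    new_edges: list[frozenset[str]] = []
    idx = hg.index
    for e in hg.hyperedges:
        img = frozenset(node_of[labels[idx[v]]] for v in e)
        if len(img) >= 2 and img not in seen:
            seen.add(img)
            new_edges.append(img)

    node_ids = tuple(node_of[c] for c in sorted(set(labels)))
    nidx = {v: i for i, v in enumerate(node_ids)}

    def key(e: frozenset[str]) -> tuple:
        members = tuple(sorted(nidx[v] for v in e))
        return (members[0], len(e), members)

    new_edges.sort(key=key)
    new_hg = Hypergraph(node_ids=node_ids, hyperedges=tuple(new_edges))
    return new_hg, {k: frozenset(v) for k, v in groups.items()}


def compress(hg: Hypergraph, max_levels: int = 5, seed: int = 0) -> LevelStack:
    """Alternate modularity optimization and aggregation into a LevelStack.

    Stops when no move improves Q (partition stays singleton-free progress),
    when aggregation does not shrink the hypergraph, when the aggregated
    hyperedge set becomes empty, or at ``max_levels``.
    """
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    levels = [hg]
    lineage: list[dict[str, frozenset[str]]] = [
        {v: frozenset({v}) for v in hg.node_ids}]
    qs: list[float] = []
    current = hg
    for level in range(1, max_levels):
        child_seed = (seed * 0x9E3779B1 + level) % (2**31)
        p = optimize_partition(current, seed=child_seed)
        qs.append(modularity(current, p))
        if p.n_communities == current.n_nodes:
            break  # no merge found: converged
        new_hg, groups = aggregate(current, p)
        if new_hg.n_hyperedges == 0 or new_hg.n_nodes >= current.n_nodes:
            break
        prev = lineage[-1]
        lineage.append({
            sn: frozenset().union(*(prev[u] for u in members))
            for sn, members in groups.items()
            if sn in new_hg.node_ids
        })
        levels.append(new_hg)
        current = new_hg
    return LevelStack(levels=levels, lineage=lineage, q_values=qs)
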