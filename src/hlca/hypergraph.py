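"""Star-expansion hypergraph of a PPI network.

Each protein's closed neighborhood {v} ∪ N(v) becomes a hyperedge; identical
neighborhood sets are merged. Hyperedge weights are ω(e) = 1/|e| so that large
hyperedges do not dominate, and the weighted node degree is
Dv(v) = Σ_e ω(e)·H(v,e). A useful exact identity follows: every hyperedge
contributes ω(e)·De(e) = 1 to the total node degree, so Σ_v Dv(v) = |E|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .ppi_io import PPINetwork

__all__ = ["Hypergraph", "build_hypergraph", "total_node_degree"]


@dataclass(frozen=True)
class Hypergraph:
    """Nodes, deduplicated hyperedges, and derived incidence structure."""

    node_ids: tuple[str, ...]
    hyperedges: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if any(len(e) < 2 for e in self.hyperedges):
            raise ValueError("every hyperedge must have size >= 2")
        if len(set(self.hyperedges)) != len(self.hyperedges):
            raise ValueError("hyperedges must be deduplicated")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.node_ids)}

    def incidence(self) -> sp.csr_matrix:
        """0/1 matrix H, one row per node, one column per hyperedge."""
        idx = self.index
        rows, cols = [], []
        for k, e in enumerate(self.hyperedges):
            for v in e:
                rows.append(idx[v])
                cols.append(k)
        return sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                             shape=(self.n_nodes, self.n_hyperedges))

    def hyperedge_degrees(self) -> np.ndarray:
        """De(e) = |e|, the number of nodes in each hyperedge."""
        return np.array([len(e) for e in self.hyperedges], dtype=float)

    def edge_weights(self) -> np.ndarray:
        """ω(e) = 1/|e|."""
        return 1.0 / self.hyperedge_degrees()

    def node_degrees(self) -> np.ndarray:
        """Dv(v) = Σ_e ω(e)·H(v,e), the weighted hypergraph node degree."""
        H = self.incidence()
        return np.asarray(H @ self.edge_weights()).ravel()


def build_hypergraph(ppi: PPINetwork) -> Hypergraph:
    """Star-expand a PPI network: one hyperedge per closed neighborhood.

    Identical candidate sets are merged. Hyperedge order is deterministic:
    sorted by (minimum member index, size, member index tuple).
    """
    nb = ppi.neighbors()
    idx = ppi.index
    seen: set[frozenset[str]] = set()
    edges: list[frozenset[str]] = []
    for v in ppi.node_ids:
        e = frozenset(nb[v] | {v})
        if e not in seen:
            seen.add(e)
            edges.append(e)

    def key(e: frozenset[str]) -> tuple:
        members = tuple(sorted(idx[v] for v in e))
        return (members[0], len(e), members)

    edges.sort(key=key)
    return Hypergraph(node_ids=ppi.node_ids, hyperedges=tuple(edges))


def total_node_degree(hg: Hypergraph) -> float:
    """Σ_v Dv(v); equals the number of hyperedges exactly."""
    total = float(hg.node_degrees().sum())
    if total <= 0:
        raise ValueError("total node degree must be positive")
    return total
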