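"""Synthetic PPI networks with planted complexes.

Emulates the structure the method assumes — dense protein complexes
(near-cliques with edge dropout, optionally sharing a node) over a sparse
Erdős–Rényi background — so every stage and the end-to-end pipeline are
testable without external datasets. Deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ppi_io import ComplexSet, PPINetwork

__all__ = ["SyntheticSpec", "generate", "DEFAULT_SPEC"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_nodes: int = 120
    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 8)
    p_within: float = 0.9
    p_background: float = 0.05
    overlap_fraction: float = 0.0
    seed: int = 17

    def validate(self) -> None:
        if not 0 <= self.p_background < self.p_within <= 1:
            raise ValueError("need 0 <= p_background < p_within <= 1")
        if self.size_range[0] < 3:
            raise ValueError("minimum complex size is 3")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("invalid size range")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")


DEFAULT_SPEC = SyntheticSpec()


def _sample_complex_edges(members: list[str], p: float,
                          rng: np.random.Generator) -> set[tuple[str, str]]:
    """Near-clique edges with retention p; resampled until the induced density
    stays within 3σ below p (σ from the binomial edge count)."""
    k = len(members)
    pairs = [(members[a], members[b]) if members[a] < members[b]
             else (members[b], members[a])
             for a in range(k) for b in range(a + 1, k)]
    n_pairs = len(pairs)
    sigma = math.sqrt(p * (1 - p) / n_pairs)
    floor = p - 3 * sigma
    while True:
        mask = rng.random(n_pairs) < p
        if mask.sum() / n_pairs >= floor:
            return {pairs[i] for i in range(n_pairs) if mask[i]}


def generate(spec: SyntheticSpec = DEFAULT_SPEC) -> tuple[PPINetwork, ComplexSet]:
    """Plant complexes and add background edges; returns (network, truth).

    Complexes are node-disjoint except that a fraction ``overlap_fraction`` of
    them share one node with the previous complex. Background edges are drawn
    uniformly over node pairs not inside any planted complex. Nodes left with
    no edges at all do not appear in the network (edge-list semantics).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = rng.integers(spec.size_range[0], spec.size_range[1] + 1,
                         size=spec.n_complexes)
    n_shared = int(round(spec.overlap_fraction * max(spec.n_complexes - 1, 0)))
    if sizes.sum() - n_shared > spec.n_nodes:
        raise ValueError("complexes exceed available nodes")

    node_ids = [f"p{i:04d}" for i in range(spec.n_nodes)]
    free = list(node_ids)
    complexes: list[list[str]] = []
    for ci, k in enumerate(sizes):
        members: list[str] = []
        if complexes and ci <= n_shared:  # first n_shared complexes after the
            members.append(complexes[-1][0])  # seed share one node each
        take = int(k) - len(members)
        picked = rng.choice(len(free), size=take, replace=False)
        members += [free[i] for i in sorted(picked)]
        for i in sorted(picked, reverse=True):
            free.pop(i)
        complexes.append(members)

    edges: set[tuple[str, str]] = set()
    for members in complexes:
        edges |= _sample_complex_edges(members, spec.p_within, rng)

    inside: set[tuple[str, str]] = set()
    for members in complexes:
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                u, v = members[a], members[b]
                inside.add((u, v) if u < v else (v, u))

    n = spec.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            pair = (node_ids[i], node_ids[j])
            if pair in inside:
                continue
            if rng.random() < spec.p_background:
                edges.add(pair)

    ppi = PPINetwork.from_edges(sorted(edges))
    truth = ComplexSet(complexes=[frozenset(m) for m in complexes])
    return ppi, truth
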