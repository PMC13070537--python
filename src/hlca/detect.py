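"""Core-attachment complex detection on the cosine-weighted PPI network.

Edges of the original PPI network are weighted by the cosine similarity of the
final node embeddings. Maximal cliques (size ≥ 3) of the topology form the
candidate cores, ranked by the sum of their pairwise cosine weights. A greedy
disjoint seed-selection strips overlaps, seeds are grown by neighbors that
strictly increase the (unweighted) cluster density 2E/(N(N−1)), cores below
the ``dens`` threshold are discarded, and unassigned proteins attach to
adjacent cores when the enlarged core keeps edge density ≥ ε while its maximum
Jaccard overlap against the other cores stays ≤ θ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .compression import compress
from .embedding import embed_network
from .hypergraph import build_hypergraph
from .ppi_io import ComplexSet, PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedPPINetwork",
    "CoreCluster",
    "build_weighted_network",
    "enumerate_cliques",
    "select_seed_cores",
    "grow_core",
    "filter_cores",
    "hyperedge_density",
    "hyperedge_overlap",
    "attach",
    "run_hlca",
]

MIN_COMPLEX_SIZE = 3


@dataclass(frozen=True)
class WeightedPPINetwork:
    """The source topology with cosine edge weights in [-1, 1]."""

    ppi: PPINetwork
    weights: dict[tuple[str, str], float]

    def weight(self, u: str, v: str) -> float:
        return self.weights[(u, v) if u < v else (v, u)]


@dataclass(frozen=True)
class CoreCluster:
    members: frozenset[str]
    density: float
    stage: str = "candidate"  # candidate | seed | core | complex


def build_weighted_network(ppi: PPINetwork, fd: np.ndarray) -> WeightedPPINetwork:
    """Weight every PPI edge by the cosine of the two embedding rows."""
    idx = ppi.index
    norms = np.linalg.norm(fd, axis=1)
    zero_rows = norms == 0
    if zero_rows.any():
        logger.warning("%d zero-norm embedding rows: their edge weights are 0",
                       int(zero_rows.sum()))
    weights: dict[tuple[str, str], float] = {}
    for u, v in ppi.edges:
        i, j = idx[u], idx[v]
        if zero_rows[i] or zero_rows[j]:
            w = 0.0
        else:
            w = float(fd[i] @ fd[j] / (norms[i] * norms[j]))
            w = max(-1.0, min(1.0, w))
        weights[(u, v) if u < v else (v, u)] = w
    return WeightedPPINetwork(ppi=ppi, weights=weights)


def _cosine_density(members: frozenset[str], gw: WeightedPPINetwork) -> float:
    """Sum of pairwise cosine weights over edges inside the set (ranking
    score; not size-normalized). Non-edge pairs contribute nothing."""
    total = 0.0
    mem = sorted(members)
    for a in range(len(mem)):
        for b in range(a + 1, len(mem)):
            key = (mem[a], mem[b])
            if key in gw.weights:
                total += gw.weights[key]
    return total


def enumerate_cliques(gw: WeightedPPINetwork, min_size: int = 3) -> list[CoreCluster]:
    """All maximal cliques of the topology with at least ``min_size`` nodes,
    as candidate cores ranked by summed cosine weight.

    Output order is deterministic: density descending, then lexicographic
    members.
    """
    g = nx.Graph()
    g.add_edges_from(gw.ppi.edges)
    out = []
    for clique in nx.find_cliques(g):
        if len(clique) >= min_size:
            members = frozenset(clique)
            out.append(CoreCluster(members=members,
                                   density=_cosine_density(members, gw),
                                   stage="candidate"))
    out.sort(key=lambda c: (-c.density, tuple(sorted(c.members))))
    return out


def select_seed_cores(candidates: list[CoreCluster],
                      gw: WeightedPPINetwork) -> list[CoreCluster]:
    """Greedy disjoint seed selection.

    Repeatedly promote the densest candidate to a seed, strip its members from
    every remaining candidate, drop candidates falling below 3 members,
    recompute densities on the stripped sets and re-sort. Seeds are pairwise
    disjoint by construction.
    """
    pool = [(c.members, c.density) for c in candidates]
    seeds: list[CoreCluster] = []
    while pool:
        pool.sort(key=lambda t: (-t[1], tuple(sorted(t[0]))))
        top_members, top_density = pool.pop(0)
        seeds.append(CoreCluster(members=top_members, density=top_density,
                                 stage="seed"))
        nxt = []
        for members, _ in pool:
            stripped = members - top_members
            if len(stripped) >= MIN_COMPLEX_SIZE:
                nxt.append((stripped, _cosine_density(stripped, gw)))
        pool = nxt
    return seeds


def cluster_density(members: frozenset[str], ppi: PPINetwork) -> float:
    """Unweighted density 2E/(N(N−1)) of the induced subgraph; 0 when N < 2."""
    n = len(members)
    if n < 2:
        return 0.0
    mem = sorted(members)
    e = sum(1 for a in range(n) for b in range(a + 1, n)
            if ppi.has_edge(mem[a], mem[b]))
    return 2.0 * e / (n * (n - 1))


def grow_core(seed: CoreCluster, ppi: PPINetwork) -> CoreCluster:
    """Admit first-order neighbors that strictly increase cluster density.

    Neighbors are ranked by (edges into the cluster descending, identifier
    ascending) — each edge into the cluster closes that many triangles with
    cluster edges. The loop restarts after every admission and stops when no
    neighbor is admissible.
    """
    nb = ppi.neighbors()
    members = set(seed.members)
    dens = cluster_density(frozenset(members), ppi)
    while True:
        frontier = set().union(*(nb[v] for v in members)) - members
        ranked = sorted(frontier,
                        key=lambda v: (-len(nb[v] & members), v))
        admitted = False
        for v in ranked:
            cand = frozenset(members | {v})
            d = cluster_density(cand, ppi)
            if d > dens:
                members.add(v)
                dens = d
                admitted = True
                break
        if not admitted:
            break
    return CoreCluster(members=frozenset(members), density=dens, stage="core")


def filter_cores(grown: list[CoreCluster], dens: float) -> list[CoreCluster]:
    """Keep cores whose unweighted cluster density is at least ``dens``."""
    if not 0 <= dens <= 1:
        raise ValueError("dens must lie in [0, 1]")
    return [c for c in grown if c.density >= dens]


def hyperedge_density(node_set: frozenset[str] | set[str], ppi: PPINetwork) -> float:
    """Edge density of the induced subgraph, 2·Σγ(e)/(k(k−1)); γ(e)=1 iff the
    pair is a PPI edge."""
    if len(node_set) < 2:
        raise ValueError("hyperedge density needs at least 2 nodes")
    return cluster_density(frozenset(node_set), ppi)


def hyperedge_overlap(node_set: frozenset[str] | set[str],
                      others: list[frozenset[str]]) -> float:
    """Maximum Jaccard overlap of the set against the other cores; 0 when
    there are no other cores."""
    s = frozenset(node_set)
    best = 0.0
    for o in others:
        j = len(s & o) / len(s | o)
        best = max(best, j)
    return best


def attach(cores: list[CoreCluster], ppi: PPINetwork, epsilon: float,
           theta: float) -> ComplexSet:
    """Gradual attachment of unassigned proteins to adjacent cores.

    Candidates are the proteins in no core at the start. Attachment is greedy
    and sequential — at every step the admissible (candidate, core) pair with
    the highest enlarged-core edge density joins, and the core is updated —
    so the density test is evaluated against the core as already expanded,
    which keeps the final complex itself at density ≥ ε. A pair is admissible
    when the candidate has at least one PPI edge into the core, the enlarged
    core keeps edge density ≥ ε, and its maximum Jaccard overlap against the
    other (current) cores stays ≤ θ. A candidate may join several cores under
    the overlap cap. Final complexes are deduplicated and size-filtered (≥ 3).
    """
    if not (0 <= epsilon <= 1 and 0 <= theta <= 1):
        raise ValueError("epsilon and theta must lie in [0, 1]")
    nb = ppi.neighbors()
    core_sets: list[set[str]] = [set(c.members) for c in cores]
    in_core = set().union(*core_sets) if core_sets else set()
    candidates = [v for v in ppi.node_ids if v not in in_core]

    def edges_within(s: set[str]) -> int:
        return sum(len(nb[v] & s) for v in s) // 2

    n_edges = [edges_within(cs) for cs in core_sets]
    while True:
        best: tuple | None = None  # (-density, node, core index, k)
        for v in candidates:
            for i, cs in enumerate(core_sets):
                if v in cs:
                    continue
                k = len(nb[v] & cs)
                if k == 0:
                    continue
                n = len(cs)
                d = 2.0 * (n_edges[i] + k) / ((n + 1) * n)
                if d < epsilon:
                    continue
                others = [frozenset(core_sets[j])
                          for j in range(len(core_sets)) if j != i]
                if hyperedge_overlap(cs | {v}, others) > theta:
                    continue
                cand = (-d, v, i, k)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, v, i, k = best
        core_sets[i].add(v)
        n_edges[i] += k

    complexes: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for cs in core_sets:
        final = frozenset(cs)
        if len(final) >= MIN_COMPLEX_SIZE and final not in seen:
            seen.add(final)
            complexes.append(final)
    if not complexes:
        logger.info("no complexes emitted (no maximal clique of size >= 3 "
                    "or all cores filtered)")
    return ComplexSet(complexes=complexes)


def run_hlca(ppi: PPINetwork, config=None, **overrides) -> tuple[ComplexSet, dict]:
    """Run the full pipeline; returns predicted complexes plus a run report.

    ``config`` is a :class:`hlca.config.RunConfig` (defaults used when None);
    keyword overrides win over the config.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()

    hg = build_hypergraph(ppi)
    stack = compress(hg, max_levels=cfg.max_levels, seed=cfg.seed)
    emb = embed_network(ppi, stack, dim=cfg.dim, mu=cfg.mu, seed=cfg.seed,
                        train_mode=cfg.train_mode, epochs=cfg.epochs)
    gw = build_weighted_network(ppi, emb.final)
    candidates = enumerate_cliques(gw)
    seeds = select_seed_cores(candidates, gw)
    grown = [grow_core(s, ppi) for s in seeds]
    cores = filter_cores(grown, cfg.dens)
    result = attach(cores, ppi, cfg.epsilon, cfg.theta)

    report = {
        "n_nodes": ppi.n_nodes,
        "n_edges": ppi.n_edges,
        "n_hyperedges": hg.n_hyperedges,
        "level_count": stack.level_count,
        "q_per_level": stack.q_values,
        "n_candidate_cliques": len(candidates),
        "n_seed_cores": len(seeds),
        "n_valid_cores": len(cores),
        "n_complexes": len(result),
        "parameters": cfg.to_dict(),
    }
    return result, report
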