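"""Reading, cleaning and writing PPI networks and protein-complex catalogues.

A PPI network arrives as a plain-text edge list (two identifier columns per
line); complex catalogues (CYC2008/MIPS style) are one complex per line,
whitespace-separated members. Cleaning removes self-interactions and
duplicate interactions; node order is first appearance, which fixes the
indexing of every downstream matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "ComplexSet",
    "read_ppi_edge_list",
    "read_complexes",
    "write_complexes",
]


class ParseError(ValueError):
    """A malformed line in an input file."""


@dataclass(frozen=True)
class PPINetwork:
    """A cleaned, undirected protein-protein interaction network.

    ``node_ids`` is ordered (first appearance in the source); ``edges`` holds
    unordered identifier pairs as sorted tuples, with no self-loops and no
    duplicates.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[str, str]]) -> "PPINetwork":
        """Build a network from raw (u, v) pairs, dropping self-loops and
        duplicates. Node order is first appearance in the pair stream."""
        node_ids: list[str] = []
        seen: set[str] = set()
        edges: set[tuple[str, str]] = set()
        n_self = n_dup = 0
        for u, v in pairs:
            u, v = u.strip(), v.strip()
            if u == v:
                n_self += 1
                continue
            e = (u, v) if u < v else (v, u)
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    node_ids.append(x)
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self or n_dup:
            logger.info("dropped %d self-interactions, %d duplicate interactions",
                        n_self, n_dup)
        if not edges:
            raise ValueError("empty network after cleaning")
        return cls(node_ids=tuple(node_ids), edges=frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.node_ids)}

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix indexed consistently with node_ids."""
        idx = self.index
        rows, cols = [], []
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(self.n_nodes, self.n_nodes))

    def neighbors(self) -> dict[str, set[str]]:
        nb: dict[str, set[str]] = {v: set() for v in self.node_ids}
        for u, v in self.edges:
            nb[u].add(v)
            nb[v].add(u)
        return nb

    def has_edge(self, u: str, v: str) -> bool:
        return ((u, v) if u < v else (v, u)) in self.edges


@dataclass
class ComplexSet:
    """A collection of protein complexes (node-identifier sets)."""

    complexes: list[frozenset[str]]
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty sets")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return sorted(map(sorted, self.complexes)) == sorted(map(sorted, other.complexes))


def read_ppi_edge_list(path: str | Path, delimiter: str | None = None,
                       sif: bool = False) -> PPINetwork:
    """Read an edge list; clean self-loops/duplicates; first-appearance order.

    Lines starting with ``#`` are skipped. With ``sif=True`` the file is read
    as the SIF dialect (``a interacts b``): columns 1 and 3 are used instead
    of 1 and 2.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter) if delimiter else line.split()
            need = 3 if sif else 2
            if len(tokens) < need:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {need} columns, got {len(tokens)}")
            u, v = (tokens[0], tokens[2]) if sif else (tokens[0], tokens[1])
            pairs.append((u, v))
    if not pairs:
        raise ValueError(f"{path}: empty network")
    return PPINetwork.from_edges(pairs)


def read_complexes(path: str | Path) -> ComplexSet:
    """Read a catalogue, one complex per line, whitespace-separated members.

    Duplicate members within a line are collapsed (set semantics).
    """
    complexes: list[frozenset[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            complexes.append(frozenset(line.split()))
    if not complexes:
        raise ValueError(f"{path}: empty catalogue")
    return ComplexSet(complexes=complexes)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members sorted for reproducible diffs."""
    if len(cs) == 0:
        raise ValueError("refusing to write an empty ComplexSet")
    with open(path, "w") as fh:
        for c in cs.complexes:
            fh.write(" ".join(sorted(c)) + "\n")
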