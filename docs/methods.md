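# Methods

## Model and assumptions

The package treats protein complexes as dense, possibly overlapping subgraphs
of an undirected, unweighted PPI network. Three modeling commitments follow
the core-attachment view of complex organization (a stable dense core plus
loosely attached peripheral proteins):

- **Hypergraph lift.** Every protein's closed neighborhood {v} ∪ N(v) is a
  hyperedge; identical neighborhoods are merged (full set equality, not just
  pairwise). Hyperedge weights ω(e) = 1/|e| damp large neighborhoods, so a
  hub's star contributes no more total degree than a small complex's. Each
  hyperedge contributes exactly ω(e)·De(e) = 1 to the total node degree,
  giving the exact identity Σ_v Dv(v) = |E| used as a structural test.
- **Degree-preserving clique expansion.** A_hyp = H·W·(De − I)⁻¹·Hᵀ is used
  instead of the raw expansion H·W·Hᵀ so that each node's weighted-graph
  degree equals its hypergraph degree exactly (off-diagonal row sums = Dv).
  Modularity is Newman-style on this loopless weighted graph: self-pairs are
  excluded from the adjacency term (self-loops are removed from the expansion)
  but retained in the configuration-null term P(i,j) = Dv(i)Dv(j)/ΣDv, and
  m = ΣDv/2 — equal, by the degree-preservation identity, to half the
  off-diagonal sum of A_hyp.
- **Multi-scale embeddings.** Two-layer hypergraph convolution at every
  compression level, redistributed to proteins with Dv-proportional weights
  and concatenated, mixes fine-grained local structure with coarse community
  structure before the clustering stage re-weights edges by cosine
  similarity.

## Parameters

| name | default | meaning |
|---|---|---|
| `dens` | 0.8 | minimum unweighted density 2E/(N(N−1)) for a grown core to survive; robust in [0.7, 0.9] |
| `epsilon` | 0.7 | minimum edge density of an enlarged core during attachment; robust in [0.6, 0.8] |
| `theta` | 0.5 | maximum Jaccard overlap of an enlarged core against other cores; robust in [0.4, 0.6] |
| `mu` | 0.5 | weight of the thresholded common-neighbor similarity in Ã = A + μ·Ŝ |
| `dim` | 64 | embedding width per level (final width = dim × levels) |
| `max_levels` | 5 | cap on compression depth; real depth is data-determined (2–4 typical) |
| `delta` | 0.25 | OS match threshold for evaluation; 0.2 is the other conventional choice |
| `seed` | 0 | drives every random draw (sweep order, projections, θ init) |
| `train_mode` | "off" | "reconstruction" fits θ to a logistic reconstruction of Ã |

All thresholds are dimensionless fractions in [0, 1].

## Open design choices

- **Untrained convolution by default.** No training objective is imposed on
  the convolution parameters: θ₁, θ₂ are fan-in-scaled uniform random matrices
  drawn from the run seed, a graph-filtering / random-projection reading that
  is fully reproducible. The optional `reconstruction` mode fits θ once on the
  finest level by full-batch gradient descent (hand-rolled numpy backprop,
  fixed epoch budget, learning rate 0.05) minimizing logistic cross-entropy
  between σ(Z·Zᵀ) and the binarized Ã, then reuses the fitted θ at coarser
  levels. Neither mode is claimed optimal; the default is chosen for
  determinism and speed.
- **Gradual, self-limiting attachment.** Attachment is greedy and sequential:
  at each step the admissible (candidate, core) pair with the highest
  enlarged-core density joins and the core is updated before the next test.
  Evaluating candidates against a frozen core instead would admit every
  protein with a single edge into a sufficiently dense core (for a 7-node
  core with 19 internal edges, (19+1)/28 ≈ 0.714 passes ε = 0.7
  independently), producing complexes whose final density is far below ε —
  contradicting the very purpose of the density gate. The sequential rule
  keeps every emitted complex at density ≥ ε. The candidate pool is fixed
  when attachment starts (proteins in no core); a candidate may join several
  cores subject to the θ cap; ties break by density, then node id, then core
  order.
- **Similarity thresholding.** The common-neighbor matrix S = A·A is kept at
  (i, j) only when S(i,j) ≥ min{S(i,k) : k ∈ N(i)}. The row-wise rule is
  asymmetric, so Ŝ is re-symmetrized by elementwise max; the diagonal
  (a node's own degree) is zeroed first, since self-similarity would only add
  self-loops to Ã.
- **Level-ℓ input features.** Coarser levels take, for each supernode, the
  Dv-weighted average of its constituent proteins' first-layer features —
  consistent with the weights used to redistribute embeddings back down.
- **Seed-core greediness.** After each densest candidate is promoted, the
  survivors' densities are recomputed on their stripped member sets and the
  pool re-sorted (densest-first at every step), rather than keeping the
  initial order.
- **Neighbor ranking during core growth.** Candidates are ranked by the
  number of edges into the current cluster (descending, then identifier),
  since each such edge closes a triangle with a cluster edge; admission
  requires a strict density increase, so a clique is never extended by a node
  that merely keeps density at 1.0.

## Numerical choices

- Local moves accept a gain only above 1e-10 (float-noise guard); node visit
  order is reshuffled once per sweep from the run seed; ties go to the lowest
  community label. Move candidates are restricted to communities of
  weighted-graph neighbors.
- Compression stops when no move improves Q, when aggregation stops shrinking
  the hypergraph, when all hyperedges collapse inside one supernode (empty
  aggregated edge set), or at `max_levels`.
- Degree preservation holds to 1e-12 relative and is asserted in tests; the
  modularity implementation is checked against an O(n²) double-loop oracle.
- Zero-degree supernodes (communities whose hyperedges were all internal) get
  zero rows in the propagation operator rather than a division error; a
  zero-norm embedding row yields cosine weight 0 with a logged warning.
- Cosine weights are clamped to [−1, 1]; negative weights are kept — the
  clique ranking score may then be negative, which only affects ordering.
- Hyperedge and clique orderings are fully deterministic (sorted by member
  indices / density with lexicographic tie-breaks), so identical inputs and
  seeds give bit-identical outputs.
- Degenerate inputs raise explicit errors: empty network after cleaning,
  single-token edge lines (with line number), hyperedges of size 1 in the
  normalized expansion, m = 0 weighted graphs, empty complex catalogues.

## Synthetic benchmark

`hlca.synthetic.generate` plants `n_complexes` near-cliques (sizes drawn
uniformly from `size_range`, edge retention `p_within`, resampled if a
complex's density falls more than 3σ below `p_within`) over an Erdős–Rényi
background at `p_background` on the remaining pairs; complexes are
node-disjoint unless `overlap_fraction` makes consecutive complexes share one
node. Defaults: 120 nodes, 10 complexes of 4–8 proteins, p_within = 0.9,
p_background = 0.05, seed 17.

What it emulates: dense modules in a sparse background — the regime the
method assumes. What it does not: scale-free degree heterogeneity,
experiment-specific false-positive structure, protein identity or annotation
signal, and heavily nested complex overlap. Passing the recovery test
therefore demonstrates correctness of the machinery on the assumed regime,
not expected accuracy on real interactome data. On these defaults the
pipeline recovers all or nearly all planted complexes (recall 0.9–1.0); the
residual imprecision is pure-background triangles, which are maximal cliques
of density 1.0 and indistinguishable from genuine small cores by any rule the
algorithm defines. Because the untrained embeddings leave candidate-clique
densities nearly tied, the greedy seed-stripping order — and with it the
recovery metrics — varies with the run seed (F-measure roughly 0.72–0.87
across seeds on the default benchmark); a single run is reproducible
bit-for-bit, but the metric itself is a seed-conditional quantity.

## Known limitations

- Maximal-clique enumeration (networkx's Bron–Kerbosch with pivoting) is
  output-polynomial on sparse PPI networks but exponential in the worst case.
- The attachment stage is O(candidates × cores) per admission; fine at PPI
  scale, not tuned for networks beyond ~10⁵ edges.
- The published rank tables bundled for the rank-statistics suite include one
  row (CYC2008 F1+ACC) whose ranks sum to 103.8 instead of a(a+1)/2 = 105; it
  is kept verbatim and flagged by a warning rather than corrected.
- Reference complexes smaller than 3 are kept during evaluation (predicted
  complexes are always ≥ 3); the match threshold δ is a convention, not a
  fitted value.
- No GO/annotation integration and no identifier mapping between naming
  systems; edge lists are taken as authoritative.
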