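"""Inspect how the multi-level embeddings re-weight PPI edges.

Builds the hypergraph of a synthetic network, compresses it, computes the
concatenated multi-level embeddings and compares the resulting cosine edge
weights inside planted complexes against background edges — informative
embeddings should weight within-complex edges higher.
"""

import numpy as np

from hlca.compression import compress
from hlca.detect import build_weighted_network
from hlca.embedding import embed_network
from hlca.hypergraph import build_hypergraph
from hlca.synthetic import SyntheticSpec, generate

ppi, truth = generate(SyntheticSpec())
hg = build_hypergraph(ppi)
stack = compress(hg, max_levels=5, seed=0)
emb = embed_network(ppi, stack, dim=64, mu=0.5, seed=0)
print(f"{hg.n_hyperedges} hyperedges, {stack.level_count} levels, "
      f"final embedding: {emb.final.shape[0]} x {emb.final.shape[1]}")

gw = build_weighted_network(ppi, emb.final)
inside = set()
for c in truth:
    mem = sorted(c)
    inside |= {(mem[i], mem[j]) for i in range(len(mem))
               for j in range(i + 1, len(mem))}
w_in = [w for e, w in gw.weights.items() if e in inside]
w_bg = [w for e, w in gw.weights.items() if e not in inside]
print(f"mean cosine weight within complexes: {np.mean(w_in):.3f} "
      f"({len(w_in)} edges)")
print(f"mean cosine weight on background:    {np.mean(w_bg):.3f} "
      f"({len(w_bg)} edges)")
# A higher within-complex mean shows the embedding separates the planted
# dense groups from the random background before any clustering happens.
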