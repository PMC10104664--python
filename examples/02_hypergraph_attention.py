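"""Build the residue-group / fragment hypergraph for one peptide and run the
two-level attention network over it.

Hypernodes are overlapping residue pairs; hyperedges are longer overlapping
fragments.  Attention aggregates nodes into edge representations and edges
back into node representations; the coefficients are normalized within each
edge (alpha) and each node's incident edges (beta).
"""

import numpy as np

from pephat import (HypergraphConfig, extract_hypergraph, incidence_matrix,
                    HyperGMAParams, hypergma_forward)

sequence = "ACDEFGHIKL"          # 10 residues
hg = extract_hypergraph(sequence, HypergraphConfig(fragment_len=4,
                                                   fragment_stride=2))
print(f"sequence: {sequence}")
print(f"hypernodes ({hg.n_nodes}): {[n.token for n in hg.nodes]}")
print(f"hyperedge spans ({hg.n_edges}): {[e.span for e in hg.edges]}")
print(f"incidence column sums: {incidence_matrix(hg).sum(axis=0)}")

params = HyperGMAParams.create(np.random.default_rng(0), n_layers=2,
                               n_heads=4, node_dim=64, edge_dim=64)
states, attention = hypergma_forward(hg, params)
print(f"node states: {states.shape}")
alpha0 = attention.alpha[attention.edge_of_pair == 0, 0]
print(f"head-0 attention over members of edge 0: {np.round(alpha0, 3)} "
      f"(sums to {alpha0.sum():.6f})")

# Each width-4 fragment contains three width-2 groups; the alpha row over an
# edge's members is a probability distribution (it sums to 1).
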