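"""Two-level hypergraph attention: closed-form coefficient cases,
normalization, equivariance, locality, and residue scattering."""

import numpy as np
import pytest

from pephat import autodiff as ad
from pephat.autodiff import Tensor
from pephat.hypergma import (AttentionRecord, HyperGMAParams,
                             edge_to_node_attention, hypergma_forward,
                             node_to_edge_attention, scatter_to_residues)
from pephat.hypergraph import (Hypergraph, HypergraphConfig, Hyperedge,
                               Hypernode, extract_hypergraph)
from pephat.seqio import CANONICAL_AA


def seq(n: int) -> str:
    return (CANONICAL_AA * ((n // 20) + 1))[:n]


def scalar_layer(W=1.0, a=1.0, Wd=1.0, Wf=1.0, af=(1.0, 0.0)):
    """1-head, 1-dim layer with hand-set scalar parameters."""
    return {
        "W_m": [Tensor([[W]], requires_grad=True)],
        "a_m": [Tensor([a], requires_grad=True)],
        "W_d": Tensor([[Wd]], requires_grad=True),
        "W_fragment": Tensor([[Wf]], requires_grad=True),
        "a_fragment": Tensor(list(af), requires_grad=True),
    }


def two_edge_one_node_graph() -> Hypergraph:
    node = Hypernode(0, (0, 1), "A")
    edges = [Hyperedge(0, (0, 1), (0,)), Hyperedge(1, (0, 1), (0,))]
    return Hypergraph(nodes=[node], edges=edges,
                      node_to_edges={0: (0, 1)},
                      residue_to_nodes={0: (0,)})


def test_alpha_singleton_and_symmetric_cases():
    h = extract_hypergraph(seq(8), HypergraphConfig(8, 4, 2, 1))  # one edge
    rng = np.random.default_rng(0)
    params = HyperGMAParams.create(rng, n_layers=1, n_heads=3,
                                   node_dim=4, edge_dim=4)
    # identical node states -> uniform attention within the edge
    states = Tensor(np.tile(rng.standard_normal(4), (h.n_nodes, 1)))
    _, alpha = node_to_edge_attention(states, h, params.layers[0])
    assert np.allclose(alpha, 1.0 / h.n_nodes)

    # singleton edge -> coefficient exactly 1
    g1 = Hypergraph(nodes=[Hypernode(0, (0, 2), "AC")],
                    edges=[Hyperedge(0, (0, 2), (0,))],
                    node_to_edges={0: (0,)},
                    residue_to_nodes={0: (0,), 1: (0,)})
    _, alpha1 = node_to_edge_attention(Tensor(rng.standard_normal((1, 4))),
                                       g1, params.layers[0])
    assert np.array_equal(alpha1, np.ones((1, 3)))


def test_alpha_closed_form_log2_scores():
    """Members with pre-softmax scores ln 2 and 0 get alpha = 2/3, 1/3."""
    g = Hypergraph(
        nodes=[Hypernode(0, (0, 1), "A"), Hypernode(1, (1, 2), "C")],
        edges=[Hyperedge(0, (0, 2), (0, 1))],
        node_to_edges={0: (0,), 1: (0,)},
        residue_to_nodes={0: (0,), 1: (1,)},
    )
    layer = scalar_layer()
    h_states = Tensor([[np.log(2.0)], [0.0]])
    _, alpha = node_to_edge_attention(h_states, g, layer)
    assert np.allclose(alpha[:, 0], [2 / 3, 1 / 3], atol=1e-12)


def test_beta_singleton_symmetric_and_closed_form():
    rng = np.random.default_rng(1)
    # node in exactly one edge -> beta = 1
    h = extract_hypergraph(seq(8), HypergraphConfig(8, 4, 2, 1))
    params = HyperGMAParams.create(rng, n_layers=1, n_heads=2,
                                   node_dim=4, edge_dim=4)
    f = Tensor(rng.standard_normal((1, 4)))
    states = Tensor(rng.standard_normal((h.n_nodes, 4)))
    _, beta = edge_to_node_attention(states, f, h, params.layers[0])
    assert np.allclose(beta, 1.0)

    # two incident edges with identical representations -> 0.5 / 0.5
    g = two_edge_one_node_graph()
    layer = scalar_layer()
    f2 = Tensor([[0.7], [0.7]])
    _, beta2 = edge_to_node_attention(Tensor([[0.3]]), f2, g, layer)
    assert np.allclose(beta2, [0.5, 0.5])

    # scalar parameters chosen so pre-softmax scores are (1, 0)
    f3 = Tensor([[1.0], [0.0]])
    out, beta3 = edge_to_node_attention(Tensor([[0.0]]), f3, g, layer)
    e = np.e
    assert np.allclose(beta3, [e / (e + 1), 1 / (e + 1)], atol=1e-12)
    # independent scalar recomputation of the aggregated node state
    expected = e / (e + 1) * 1.0 + 1 / (e + 1) * 0.0
    assert np.allclose(out.data, expected)


def test_forward_zero_layers_returns_token_embeddings():
    h = extract_hypergraph(seq(10), HypergraphConfig())
    params = HyperGMAParams.create(np.random.default_rng(2), n_layers=0,
                                   n_heads=2, node_dim=8, edge_dim=8)
    out, record = hypergma_forward(h, params)
    expected = params.group_embedding.data[params.token_ids(h)]
    np.testing.assert_array_equal(out.data, expected)
    assert record is None


def test_forward_zero_parameters_uniform_attention_zero_output():
    h = extract_hypergraph(seq(12), HypergraphConfig())
    params = HyperGMAParams.create(np.random.default_rng(3), n_layers=2,
                                   n_heads=2, node_dim=6, edge_dim=6)
    for p in params.parameters():
        p.data[:] = 0.0
    out, record = hypergma_forward(h, params)
    assert np.allclose(out.data, 0.0)
    # uniform alpha within each edge, uniform beta within each node
    for j in range(h.n_edges):
        mask = record.edge_of_pair == j
        assert np.allclose(record.alpha[mask], 1.0 / mask.sum())
    for k in range(h.n_nodes):
        mask = record.node_of_pair == k
        assert np.allclose(record.beta[mask], 1.0 / mask.sum())


def test_attention_rows_normalize_over_random_draws():
    rng = np.random.default_rng(4)
    for trial in range(20):
        n = int(rng.integers(6, 40))
        cfg = HypergraphConfig(fragment_len=int(rng.integers(3, 9)),
                               fragment_stride=int(rng.integers(1, 3)),
                               group_len=2, group_stride=1)
        h = extract_hypergraph(seq(n), cfg)
        params = HyperGMAParams.create(rng, n_layers=1, n_heads=3,
                                       node_dim=5, edge_dim=5)
        states = Tensor(rng.standard_normal((h.n_nodes, 5)) * 3)
        f, alpha = node_to_edge_attention(states, h, params.layers[0])
        edge_pairs, node_pairs = h.membership_pairs()
        for j in range(h.n_edges):
            sums = alpha[edge_pairs == j].sum(axis=0)
            assert np.allclose(sums, 1.0, atol=1e-6)
        _, beta = edge_to_node_attention(states, f, h, params.layers[0])
        for k in range(h.n_nodes):
            assert np.isclose(beta[node_pairs == k].sum(), 1.0, atol=1e-6)
        assert np.isfinite(f.data).all()


def test_single_edge_forward_composes_sub_operations():
    """One edge, one layer: every node output is sigma(1.0 * W_fragment f)."""
    h = extract_hypergraph(seq(6), HypergraphConfig(6, 3, 2, 1))
    assert h.n_edges == 1
    rng = np.random.default_rng(5)
    params = HyperGMAParams.create(rng, n_layers=1, n_heads=2,
                                   node_dim=4, edge_dim=4)
    layer = params.layers[0]
    h0 = params.group_embedding[params.token_ids(h)]
    f, _ = node_to_edge_attention(h0, h, layer)
    out, _ = hypergma_forward(h, params)
    # beta over a single incident edge is 1, so h_i = LeakyReLU(W_fragment f)
    expected = np.where((f.data @ layer["W_fragment"].data) > 0,
                        f.data @ layer["W_fragment"].data,
                        0.01 * (f.data @ layer["W_fragment"].data))
    for k in range(h.n_nodes):
        assert np.allclose(out.data[k], expected[0], atol=1e-12)


def test_permutation_equivariance():
    s = seq(14)
    h = extract_hypergraph(s, HypergraphConfig())
    rng = np.random.default_rng(6)
    params = HyperGMAParams.create(rng, n_layers=2, n_heads=2,
                                   node_dim=6, edge_dim=6)
    out, _ = hypergma_forward(h, params)

    perm = rng.permutation(h.n_nodes)
    inv = np.argsort(perm)
    nodes = [Hypernode(int(inv[n.index]), n.span, n.token) for n in h.nodes]
    nodes.sort(key=lambda n: n.index)
    edges = [Hyperedge(e.index, e.span,
                       tuple(sorted(int(inv[k]) for k in e.members)))
             for e in h.edges]
    node_to_edges = {int(inv[k]): v for k, v in h.node_to_edges.items()}
    residue_to_nodes = {p: tuple(sorted(int(inv[k]) for k in v))
                        for p, v in h.residue_to_nodes.items()}
    hp = Hypergraph(nodes=nodes, edges=edges, node_to_edges=node_to_edges,
                    residue_to_nodes=residue_to_nodes)
    out_p, _ = hypergma_forward(hp, params)
    np.testing.assert_allclose(out_p.data[inv[np.arange(h.n_nodes)]],
                               out.data, atol=1e-12)


def test_one_layer_locality():
    """Perturbing a node's token embedding only changes outputs of nodes
    sharing an edge with it (1-layer network)."""
    s = seq(20)   # all 2-mer tokens distinct
    h = extract_hypergraph(s, HypergraphConfig(8, 4, 2, 1))
    rng = np.random.default_rng(7)
    params = HyperGMAParams.create(rng, n_layers=1, n_heads=2,
                                   node_dim=6, edge_dim=6)
    base, _ = hypergma_forward(h, params)

    target_node = 0
    token_id = params.token_ids(h)[target_node]
    params.group_embedding.data[token_id] += 1.0
    pert, _ = hypergma_forward(h, params)

    neighborhood = set()
    for j in h.node_to_edges[target_node]:
        neighborhood.update(h.edges[j].members)
    changed = {k for k in range(h.n_nodes)
               if not np.allclose(base.data[k], pert.data[k], atol=1e-12)}
    assert changed
    assert changed <= neighborhood


def test_scatter_to_residues_counts_and_identity():
    rng = np.random.default_rng(8)
    # group_len 1, stride 1: residue features equal node states row-for-row
    h1 = extract_hypergraph(seq(7), HypergraphConfig(4, 2, 1, 1))
    states = Tensor(rng.standard_normal((h1.n_nodes, 3)))
    out = scatter_to_residues(states, h1, 7)
    np.testing.assert_allclose(out.data, states.data)

    # default length-10 graph: interior residues average 2 nodes, ends 1
    h2 = extract_hypergraph(seq(10), HypergraphConfig(4, 2, 2, 1))
    counts = {p: len(v) for p, v in h2.residue_to_nodes.items()}
    assert counts[0] == counts[9] == 1
    assert all(counts[p] == 2 for p in range(1, 9))
    states2 = Tensor(rng.standard_normal((h2.n_nodes, 2)))
    out2 = scatter_to_residues(states2, h2, 10)
    # residue 1 covered by nodes [0,2) and [1,3): mean of states 0 and 1
    np.testing.assert_allclose(out2.data[1],
                               (states2.data[0] + states2.data[1]) / 2)


def test_outputs_finite_under_large_inputs():
    h = extract_hypergraph(seq(15), HypergraphConfig())
    params = HyperGMAParams.create(np.random.default_rng(9), n_layers=2,
                                   n_heads=4, node_dim=8, edge_dim=8)
    params.group_embedding.data *= 100.0      # stress the softmax
    out, record = hypergma_forward(h, params)
    assert np.isfinite(out.data).all()
    assert np.isfinite(record.alpha).all() and np.isfinite(record.beta).all()
    assert record.alpha.min() >= 0 and record.alpha.max() <= 1
    assert record.beta.min() >= 0 and record.beta.max() <= 1
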