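"""HyperGMA: two-level hypergraph multi-head attention.

Each layer alternates two attention passes over the residue-group /
fragment hypergraph:

1. node -> edge (residue-group level, multi-head): per head m, every member
   node k of edge j is scored by ``a_m . LeakyReLU(W_m h_k)``; the scores are
   softmax-normalized over the edge's members into coefficients alpha_jk, and
   the edge representation is ``LeakyReLU(sum_k alpha_jk W_m h_k)``.  Head
   outputs are concatenated and compressed to edge_dim by a bias-free linear
   map W_d.
2. edge -> node (fragment level): for node i and each incident edge j,
   ``V_ij = LeakyReLU([W_fragment f_j || W_residue h_i])`` is scored by the
   attention vector a_fragment; softmax over incident edges gives beta_ij and
   the new node state is ``LeakyReLU(sum_j beta_ij W_fragment f_j)``.
   W_residue is the head-concatenation of the W_m right-multiplied by W_d.

Node states are initialized from a learned embedding of the residue-group
token (400 tokens for pairs over the 20 amino acids, plus one shared
wildcard row).  Attention coefficients of the last layer are returned for
interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .hypergraph import Hypergraph, HypergraphError
from .seqio import ResidueAlphabet
from .hypergraph import build_group_vocabulary

LEAKY_SLOPE = 0.01


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class HyperGMAParams:
    """All trainable tensors of the network, plus the token vocabulary."""

    n_layers: int = 2
    n_heads: int = 4
    node_dim: int = 64
    edge_dim: int = 64
    group_len: int = 2
    group_embedding: Tensor = None          # (n_tokens + 1, node_dim)
    layers: list[dict] = field(default_factory=list)
    token_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def create(cls, rng: np.random.Generator, n_layers: int = 2, n_heads: int = 4,
               node_dim: int = 64, edge_dim: int = 64, group_len: int = 2,
               alphabet: ResidueAlphabet | None = None) -> "HyperGMAParams":
        vocab = build_group_vocabulary(alphabet, group_len)
        token_index = {tok: i for i, tok in enumerate(vocab)}
        emb = Tensor(0.1 * rng.standard_normal((len(vocab) + 1, node_dim)),
                     requires_grad=True)
        layers = []
        for _ in range(n_layers):
            layer = {
                "W_m": [Tensor(_glorot(rng, node_dim, node_dim), requires_grad=True)
                        for _ in range(n_heads)],
                "a_m": [Tensor(_glorot(rng, node_dim, 1)[:, 0], requires_grad=True)
                        for _ in range(n_heads)],
                "W_d": Tensor(_glorot(rng, n_heads * node_dim, edge_dim),
                              requires_grad=True),
                "W_fragment": Tensor(_glorot(rng, edge_dim, node_dim),
                                     requires_grad=True),
                "a_fragment": Tensor(
                    _glorot(rng, node_dim + edge_dim, 1)[:, 0], requires_grad=True),
            }
            layers.append(layer)
        return cls(n_layers=n_layers, n_heads=n_heads, node_dim=node_dim,
                   edge_dim=edge_dim, group_len=group_len, group_embedding=emb,
                   layers=layers, token_index=token_index)

    def parameters(self) -> list[Tensor]:
        out = [self.group_embedding]
        for layer in self.layers:
            out.extend(layer["W_m"])
            out.extend(layer["a_m"])
            out.extend([layer["W_d"], layer["W_fragment"], layer["a_fragment"]])
        return out

    def token_ids(self, hypergraph: Hypergraph) -> np.ndarray:
        unk = len(self.token_index)
        return np.array([self.token_index.get(n.token, unk)
                         for n in hypergraph.nodes], dtype=np.int64)


@dataclass
class AttentionRecord:
    """Last-layer attention coefficients with their incidence pairs."""

    alpha: np.ndarray          # (n_pairs, n_heads): node->edge, per head
    beta: np.ndarray           # (n_pairs,): edge->node
    edge_of_pair: np.ndarray   # (n_pairs,)
    node_of_pair: np.ndarray   # (n_pairs,)


def node_to_edge_attention(h_prev: Tensor, hypergraph: Hypergraph,
                           layer: dict) -> tuple[Tensor, np.ndarray]:
    """Aggregate member-node states into edge states (multi-head).

    Returns the (n_edges, edge_dim) edge states and the alpha coefficients
    as an (n_pairs, n_heads) array aligned with membership_pairs().
    """
    if h_prev.shape[0] != hypergraph.n_nodes:
        raise HypergraphError("node-state row count does not match hypergraph")
    e_idx, n_idx = hypergraph.membership_pairs()
    if len(e_idx) == 0:
        raise HypergraphError("hypergraph has no incidence pairs")
    head_outputs = []
    alphas = []
    for W_m, a_m in zip(layer["W_m"], layer["a_m"]):
        Wh = h_prev @ W_m                              # (n_nodes, node_dim)
        u = ad.leaky_relu(Wh, LEAKY_SLOPE)
        scores = (u @ a_m.reshape(-1, 1)).reshape(-1)  # (n_nodes,)
        pair_scores = scores[n_idx]
        alpha = ad.segment_softmax(pair_scores, e_idx, hypergraph.n_edges)
        weighted = alpha.reshape(-1, 1) * Wh[n_idx]
        f_head = ad.leaky_relu(
            ad.segment_sum(weighted, e_idx, hypergraph.n_edges), LEAKY_SLOPE)
        head_outputs.append(f_head)
        alphas.append(alpha.data)
    f = ad.concat(head_outputs, axis=1) @ layer["W_d"]
    return f, np.stack(alphas, axis=1)


def edge_to_node_attention(h_prev: Tensor, f: Tensor, hypergraph: Hypergraph,
                           layer: dict) -> tuple[Tensor, np.ndarray]:
    """Aggregate incident-edge states back into node states.

    Returns the (n_nodes, node_dim) node states and beta coefficients
    aligned with membership_pairs().
    """
    if f.shape[0] != hypergraph.n_edges:
        raise HypergraphError("edge-state row count does not match hypergraph")
    e_idx, n_idx = hypergraph.membership_pairs()
    W_residue = ad.concat(layer["W_m"], axis=1) @ layer["W_d"]
    Wf = f @ layer["W_fragment"]                       # (n_edges, node_dim)
    Wh = h_prev @ W_residue                            # (n_nodes, edge_dim)
    V = ad.leaky_relu(ad.concat([Wf[e_idx], Wh[n_idx]], axis=1), LEAKY_SLOPE)
    scores = (V @ layer["a_fragment"].reshape(-1, 1)).reshape(-1)
    beta = ad.segment_softmax(scores, n_idx, hypergraph.n_nodes)
    weighted = beta.reshape(-1, 1) * Wf[e_idx]
    h = ad.leaky_relu(
        ad.segment_sum(weighted, n_idx, hypergraph.n_nodes), LEAKY_SLOPE)
    return h, beta.data


def hypergma_forward(hypergraph: Hypergraph, params: HyperGMAParams
                     ) -> tuple[Tensor, AttentionRecord | None]:
    """Run all layers; return final node states and last-layer attention."""
    h = params.group_embedding[params.token_ids(hypergraph)]
    record = None
    e_idx, n_idx = hypergraph.membership_pairs()
    for layer in params.layers:
        f, alpha = node_to_edge_attention(h, hypergraph, layer)
        h, beta = edge_to_node_attention(h, f, hypergraph, layer)
        record = AttentionRecord(alpha=alpha, beta=beta,
                                 edge_of_pair=e_idx, node_of_pair=n_idx)
    return h, record


def scatter_to_residues(node_states: Tensor, hypergraph: Hypergraph,
                        seq_len: int) -> Tensor:
    """Per-residue features: mean of the states of all nodes covering it."""
    node_of_pair, res_of_pair, counts = [], [], np.zeros(seq_len)
    for p in range(seq_len):
        covering = hypergraph.residue_to_nodes.get(p, ())
        if not covering:
            raise HypergraphError(f"residue {p} not covered by any node")
        for k in covering:
            res_of_pair.append(p)
            node_of_pair.append(k)
        counts[p] = len(covering)
    node_of_pair = np.asarray(node_of_pair, dtype=np.int64)
    res_of_pair = np.asarray(res_of_pair, dtype=np.int64)
    total = ad.segment_sum(node_states[node_of_pair], res_of_pair, seq_len)
    return total * Tensor((1.0 / counts).reshape(-1, 1))
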