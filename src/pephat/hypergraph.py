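"""Sliding-window hypergraph over a peptide sequence.

Short residue groups (default width 2, stride 1) are the hypernodes; longer
fragments (default width 8, stride 4) are the hyperedges.  A node belongs to
an edge iff its residue span is fully contained in the edge span.  Fragments
overlap by construction ("cross residues"), so consecutive edges share nodes
and information can flow along the chain.

Spans are 0-based half-open intervals over residue positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import ResidueAlphabet


class HypergraphError(ValueError):
    pass


@dataclass(frozen=True)
class HypergraphConfig:
    fragment_len: int = 8
    fragment_stride: int = 4
    group_len: int = 2
    group_stride: int = 1

    def __post_init__(self):
        if min(self.fragment_len, self.fragment_stride,
               self.group_len, self.group_stride) < 1:
            raise HypergraphError("window lengths and strides must be >= 1")
        if self.group_len > self.fragment_len:
            raise HypergraphError("group_len must not exceed fragment_len")
        if self.fragment_stride > self.fragment_len:
            raise HypergraphError(
                "fragment_stride must not exceed fragment_len "
                "(fragments must cover every residue)"
            )
        if self.group_stride > self.group_len:
            raise HypergraphError(
                "group_stride must be <= group_len so groups cover all residues"
            )
        if self.group_stride > self.fragment_len - self.group_len + 1:
            raise HypergraphError(
                "group_stride must be <= fragment_len - group_len + 1 "
                "so every fragment contains at least one residue group"
            )

    @property
    def guarantees_node_coverage(self) -> bool:
        """True iff every group window is contained in some fragment for any
        sequence length (fragment overlap of at least group_len - 1)."""
        return self.fragment_stride <= self.fragment_len - self.group_len + 1


@dataclass(frozen=True)
class Hypernode:
    index: int
    span: tuple[int, int]
    token: str


@dataclass(frozen=True)
class Hyperedge:
    index: int
    span: tuple[int, int]
    members: tuple[int, ...]


@dataclass
class Hypergraph:
    nodes: list[Hypernode]
    edges: list[Hyperedge]
    node_to_edges: dict[int, tuple[int, ...]] = field(default_factory=dict)
    residue_to_nodes: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def membership_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(edge_index, node_index) arrays over all incidence pairs."""
        e_idx, n_idx = [], []
        for e in self.edges:
            for k in e.members:
                e_idx.append(e.index)
                n_idx.append(k)
        return np.asarray(e_idx, dtype=np.int64), np.asarray(n_idx, dtype=np.int64)


def build_group_vocabulary(alphabet: ResidueAlphabet | None = None,
                           group_len: int = 2) -> list[str]:
    """All |alphabet|^group_len residue-group tokens in lexicographic order."""
    if group_len < 1:
        raise HypergraphError("group_len must be >= 1")
    alphabet = alphabet or ResidueAlphabet()
    return ["".join(p) for p in
            itertools.product(sorted(alphabet.symbols), repeat=group_len)]


def _windows(n: int, width: int, stride: int) -> list[tuple[int, int]]:
    """Full-stride windows plus an end-anchored tail guaranteeing coverage."""
    spans = [(s, s + width) for s in range(0, n - width + 1, stride)]
    if not spans:
        return [(0, n)]           # sequence shorter than the window
    if spans[-1][1] < n:
        spans.append((max(0, n - width), n))
    return spans


def extract_hypergraph(sequence: str, config: HypergraphConfig | None = None
                       ) -> Hypergraph:
    """Build the residue-group / fragment hypergraph for one sequence."""
    config = config or HypergraphConfig()
    n = len(sequence)
    if n < config.group_len:
        raise HypergraphError(
            f"sequence of length {n} shorter than group_len {config.group_len}"
        )
    node_spans = _windows(n, config.group_len, config.group_stride)
    edge_spans = _windows(n, config.fragment_len, config.fragment_stride)

    nodes = [Hypernode(k, span, sequence[span[0]:span[1]])
             for k, span in enumerate(node_spans)]
    edges = []
    node_to_edges: dict[int, list[int]] = {k: [] for k in range(len(nodes))}
    for j, espan in enumerate(edge_spans):
        members = tuple(k for k, nspan in enumerate(node_spans)
                        if espan[0] <= nspan[0] and nspan[1] <= espan[1])
        if not members:
            raise HypergraphError(f"fragment {espan} contains no residue group")
        edges.append(Hyperedge(j, espan, members))
        for k in members:
            node_to_edges[k].append(j)

    residue_to_nodes: dict[int, list[int]] = {p: [] for p in range(n)}
    for k, (lo, hi) in enumerate(node_spans):
        for p in range(lo, hi):
            residue_to_nodes[p].append(k)

    for k, incident in node_to_edges.items():
        if not incident:
            raise HypergraphError(f"node {k} belongs to no hyperedge")
    for p, covering in residue_to_nodes.items():
        if not covering:
            raise HypergraphError(f"residue {p} is covered by no node")

    return Hypergraph(
        nodes=nodes,
        edges=edges,
        node_to_edges={k: tuple(v) for k, v in node_to_edges.items()},
        residue_to_nodes={p: tuple(v) for p, v in residue_to_nodes.items()},
    )


def incidence_matrix(h: Hypergraph) -> np.ndarray:
    """Binary |nodes| x |edges| incidence matrix."""
    mat = np.zeros((h.n_nodes, h.n_edges), dtype=np.int8)
    for e in h.edges:
        for k in e.members:
            mat[k, e.index] = 1
    return mat
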