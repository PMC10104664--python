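"""End-to-end model: hypergraph attention + embedding fusion + Bi-LSTM-CRF.

For one peptide the forward pass is

    hypergraph -> HyperGMA node states -> scatter to residues   (channel A)
    residue embedding provider                                  (channel B)
    fuse(A, B) by projected element-wise multiplication
    Bi-LSTM -> CRF potentials (emission + fused transitions)

Training minimizes the CRF negative log-likelihood; prediction decodes with
Viterbi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .crf import CRFParams, Potentials, compute_potentials, viterbi_decode
from .encoder import (BiLSTMParams, EmbeddingProvider, FusionParams,
                      bilstm_encode, embed_sequence, fuse_channels)
from .hypergma import HyperGMAParams, hypergma_forward, scatter_to_residues
from .hypergraph import HypergraphConfig, extract_hypergraph
from .seqio import EmbeddingTable, PeptideRecord, ResidueAlphabet, SSAlphabet


@dataclass
class ModelConfig:
    ss_mode: str = "three_state"
    hypergraph: HypergraphConfig = field(default_factory=HypergraphConfig)
    n_layers: int = 2
    n_heads: int = 4
    node_dim: int = 64
    edge_dim: int = 64
    embedding_kind: str = "one_hot"        # one_hot | learned_lookup | precomputed_table
    embedding_dim: int = 20
    fusion_dim: int = 64
    hidden_dim: int = 64
    lambda_local: float = 0.5

    def to_dict(self) -> dict:
        return {
            "ss_mode": self.ss_mode,
            "hypergraph": {
                "fragment_len": self.hypergraph.fragment_len,
                "fragment_stride": self.hypergraph.fragment_stride,
                "group_len": self.hypergraph.group_len,
                "group_stride": self.hypergraph.group_stride,
            },
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "node_dim": self.node_dim,
            "edge_dim": self.edge_dim,
            "embedding_kind": self.embedding_kind,
            "embedding_dim": self.embedding_dim,
            "fusion_dim": self.fusion_dim,
            "hidden_dim": self.hidden_dim,
            "lambda_local": self.lambda_local,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        hg = d.pop("hypergraph", {})
        return cls(hypergraph=HypergraphConfig(**hg), **d)


class StructurePredictor:
    """The full predictor; owns all trainable parameters."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 embedding_table: EmbeddingTable | None = None):
        self.config = config
        self.ss = SSAlphabet(config.ss_mode)
        self.alphabet = ResidueAlphabet()
        rng = np.random.default_rng(seed)
        self.hypergma = HyperGMAParams.create(
            rng, n_layers=config.n_layers, n_heads=config.n_heads,
            node_dim=config.node_dim, edge_dim=config.edge_dim,
            group_len=config.hypergraph.group_len, alphabet=self.alphabet)
        self.provider = EmbeddingProvider.create(
            config.embedding_kind, dim=config.embedding_dim,
            table=embedding_table, rng=rng)
        self.fusion = FusionParams.create(
            rng, dim1=self.provider.dim, dim2=config.node_dim,
            common_dim=config.fusion_dim)
        self.bilstm = BiLSTMParams.create(
            rng, input_dim=config.fusion_dim, hidden_dim=config.hidden_dim)
        self.crf = CRFParams.create(
            rng, width=2 * config.hidden_dim, n_states=self.ss.n_states,
            lambda_local=config.lambda_local)

    def parameters(self) -> list[Tensor]:
        return (self.hypergma.parameters() + self.provider.parameters()
                + self.fusion.parameters() + self.bilstm.parameters()
                + self.crf.parameters())

    def forward(self, record: PeptideRecord) -> Potentials:
        hg = extract_hypergraph(record.sequence, self.config.hypergraph)
        node_states, _ = hypergma_forward(hg, self.hypergma)
        graph_feat = scatter_to_residues(node_states, hg, len(record.sequence))
        residue_embed = embed_sequence(record, self.provider)
        fused = fuse_channels(residue_embed, graph_feat, self.fusion)
        encoded = bilstm_encode(fused, self.bilstm)
        return compute_potentials(encoded, self.crf)

    def loss(self, record, labels: np.ndarray) -> Tensor:
        from .crf import crf_loss

        return crf_loss(self.forward(record), labels)

    def predict_labels(self, record: PeptideRecord) -> str:
        with ad.no_grad():
            potentials = self.forward(record)
        path, _ = viterbi_decode(potentials)
        return self.ss.decode(path)

    # -- checkpoint (de)serialization ---------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} tensors, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)
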