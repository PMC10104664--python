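"""Per-residue embedding channel, channel fusion, and the Bi-LSTM encoder.

The knowledge-transfer channel is a pluggable per-residue embedding
provider.  Precomputed embedding tables (e.g. exported from a pretrained
protein language model) are accepted via :class:`~pephat.seqio.EmbeddingTable`;
a one-hot encoding and a learned lookup table make everything runnable
offline.

The two feature channels — per-residue embeddings and the hypergraph
features scattered to residues — are each linearly projected to a common
width and fused by element-wise multiplication, then passed through a
single-layer bidirectional LSTM whose output feeds the CRF head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .seqio import CANONICAL_AA, EmbeddingTable, PeptideRecord


class EncoderError(ValueError):
    pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


@dataclass
class EmbeddingProvider:
    """One of: one-hot (dim 20), learned lookup, or a precomputed table."""

    kind: str = "one_hot"                 # one_hot | learned_lookup | precomputed_table
    dim: int = 20
    table: EmbeddingTable | None = None   # precomputed mode
    lookup: Tensor | None = None          # learned mode, (21, dim); row 20 = wildcard

    @classmethod
    def create(cls, kind: str, dim: int = 20,
               table: EmbeddingTable | None = None,
               rng: np.random.Generator | None = None) -> "EmbeddingProvider":
        if kind == "one_hot":
            return cls(kind=kind, dim=20)
        if kind == "learned_lookup":
            rng = rng or np.random.default_rng(0)
            lookup = Tensor(0.1 * rng.standard_normal((21, dim)), requires_grad=True)
            return cls(kind=kind, dim=dim, lookup=lookup)
        if kind == "precomputed_table":
            if table is None or table.dim is None:
                raise EncoderError("precomputed_table mode requires a table")
            return cls(kind=kind, dim=table.dim, table=table)
        raise EncoderError(f"unknown embedding provider kind {kind!r}")

    def parameters(self) -> list[Tensor]:
        return [self.lookup] if self.lookup is not None else []


def _residue_ids(sequence: str) -> np.ndarray:
    index = {a: i for i, a in enumerate(CANONICAL_AA)}
    return np.array([index.get(ch, 20) for ch in sequence], dtype=np.int64)


def embed_sequence(record: PeptideRecord, provider: EmbeddingProvider) -> Tensor:
    """One row of features per residue; wildcard residues get a zero row
    (one-hot) or a dedicated learned row (lookup)."""
    ids = _residue_ids(record.sequence)
    if provider.kind == "one_hot":
        mat = np.zeros((len(ids), 20))
        known = ids < 20
        mat[np.nonzero(known)[0], ids[known]] = 1.0
        return Tensor(mat)
    if provider.kind == "learned_lookup":
        return provider.lookup[ids]
    if record.id not in provider.table.entries:
        raise EncoderError(f"no precomputed embedding for record {record.id!r}")
    mat = provider.table.entries[record.id]
    if mat.shape[0] != len(record.sequence):
        raise EncoderError(
            f"embedding rows ({mat.shape[0]}) != sequence length "
            f"({len(record.sequence)}) for {record.id!r}"
        )
    return Tensor(mat)


@dataclass
class FusionParams:
    """Linear projections of both channels to a common width, with biases."""

    common_dim: int
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, dim1: int, dim2: int,
               common_dim: int = 64) -> "FusionParams":
        return cls(
            common_dim=common_dim,
            W1=Tensor(_glorot(rng, dim1, common_dim), requires_grad=True),
            b1=Tensor(np.zeros(common_dim), requires_grad=True),
            W2=Tensor(_glorot(rng, dim2, common_dim), requires_grad=True),
            b2=Tensor(np.zeros(common_dim), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def fuse_channels(residue_embed: Tensor, graph_residue_feat: Tensor,
                  params: FusionParams) -> Tensor:
    """Project both channels to common_dim and multiply entrywise."""
    if residue_embed.shape[0] != graph_residue_feat.shape[0]:
        raise EncoderError(
            f"channel row counts differ: {residue_embed.shape[0]} vs "
            f"{graph_residue_feat.shape[0]}"
        )
    c1 = residue_embed @ params.W1 + params.b1
    c2 = graph_residue_feat @ params.W2 + params.b2
    return c1 * c2


@dataclass
class BiLSTMParams:
    """Single-layer bidirectional LSTM; output width is 2 * hidden_dim.

    Each direction uses one combined input+recurrent weight matrix of shape
    (input_dim + hidden_dim, 4 * hidden_dim) with gate order i, f, g, o and a
    forget-gate bias initialized to 1.
    """

    input_dim: int
    hidden_dim: int
    W_fwd: Tensor
    b_fwd: Tensor
    W_bwd: Tensor
    b_bwd: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, input_dim: int,
               hidden_dim: int = 64) -> "BiLSTMParams":
        def make():
            W = Tensor(_glorot(rng, input_dim + hidden_dim, 4 * hidden_dim),
                       requires_grad=True)
            b = np.zeros(4 * hidden_dim)
            b[hidden_dim:2 * hidden_dim] = 1.0     # forget gate bias
            return W, Tensor(b, requires_grad=True)

        W_fwd, b_fwd = make()
        W_bwd, b_bwd = make()
        return cls(input_dim=input_dim, hidden_dim=hidden_dim,
                   W_fwd=W_fwd, b_fwd=b_fwd, W_bwd=W_bwd, b_bwd=b_bwd)

    def parameters(self) -> list[Tensor]:
        return [self.W_fwd, self.b_fwd, self.W_bwd, self.b_bwd]


def _lstm_pass(xs: Tensor, W: Tensor, b: Tensor, hidden_dim: int,
               reverse: bool) -> list[Tensor]:
    n = xs.shape[0]
    h = Tensor(np.zeros((1, hidden_dim)))
    c = Tensor(np.zeros((1, hidden_dim)))
    order = range(n - 1, -1, -1) if reverse else range(n)
    outputs: dict[int, Tensor] = {}
    H = hidden_dim
    for t in order:
        x = xs[t:t + 1]
        z = ad.concat([x, h], axis=1) @ W + b
        i = ad.sigmoid(z[:, 0:H])
        f = ad.sigmoid(z[:, H:2 * H])
        g = ad.tanh(z[:, 2 * H:3 * H])
        o = ad.sigmoid(z[:, 3 * H:4 * H])
        c = f * c + i * g
        h = o * ad.tanh(c)
        outputs[t] = h
    return [outputs[t] for t in range(n)]


def bilstm_encode(fused: Tensor, params: BiLSTMParams) -> Tensor:
    """Concatenate a forward and a backward LSTM pass, length preserved."""
    if fused.shape[1] != params.input_dim:
        raise EncoderError(
            f"input width {fused.shape[1]} != expected {params.input_dim}"
        )
    fwd = _lstm_pass(fused, params.W_fwd, params.b_fwd, params.hidden_dim, False)
    bwd = _lstm_pass(fused, params.W_bwd, params.b_bwd, params.hidden_dim, True)
    rows = [ad.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
    return ad.concat(rows, axis=0)
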