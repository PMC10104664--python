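"""Sequence, label and embedding I/O.

Peptide sequences and per-residue secondary-structure label strings travel as
FASTA / FASTA-like files (one state character per residue, community ``.ss``
convention).  Precomputed per-residue embeddings are read from TSV
(``id  position  v0..v{d-1}``) or an HDF5 container keyed by record id.

All coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "X"

THREE_STATE = "HEC"
EIGHT_STATE = "HGIEBTSC"

#: DSSP-style reduction: helices H,G,I -> H; strands E,B -> E; the rest -> C.
EIGHT_TO_THREE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}


class UnknownPolicy(str, Enum):
    REJECT = "reject"
    MAP_TO_WILDCARD = "map_to_wildcard"


class SeqIOError(ValueError):
    """Raised for malformed or inconsistent sequence/label/embedding input."""


@dataclass(frozen=True)
class ResidueAlphabet:
    """The 20 canonical one-letter amino-acid codes with a fixed ordering."""

    symbols: str = CANONICAL_AA
    unknown_policy: UnknownPolicy = UnknownPolicy.REJECT

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise SeqIOError("residue alphabet contains duplicate symbols")
        if len(self.symbols) != 20:
            raise SeqIOError("residue alphabet must contain exactly 20 symbols")

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def clean(self, sequence: str, record_id: str = "?") -> str:
        """Validate `sequence`, applying the unknown-residue policy."""
        seq = "".join(sequence.split()).upper()
        out = []
        for pos, ch in enumerate(seq):
            if ch in self.index:
                out.append(ch)
            elif self.unknown_policy is UnknownPolicy.MAP_TO_WILDCARD:
                out.append(WILDCARD)
            else:
                raise SeqIOError(
                    f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
                )
        return "".join(out)


@dataclass(frozen=True)
class SSAlphabet:
    """Secondary-structure state alphabet, 3-state (H/E/C) or 8-state DSSP."""

    mode: str = "three_state"

    def __post_init__(self):
        if self.mode not in ("three_state", "eight_state"):
            raise SeqIOError(f"unknown secondary-structure mode {self.mode!r}")

    @property
    def symbols(self) -> str:
        return THREE_STATE if self.mode == "three_state" else EIGHT_STATE

    @property
    def n_states(self) -> int:
        return len(self.symbols)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def validate(self, labels: str, record_id: str = "?") -> str:
        for pos, ch in enumerate(labels):
            if ch not in self.index:
                raise SeqIOError(
                    f"record {record_id!r}: invalid state {ch!r} at position {pos}"
                )
        return labels

    def encode(self, labels: str) -> np.ndarray:
        idx = self.index
        return np.array([idx[c] for c in labels], dtype=np.int64)

    def decode(self, states: np.ndarray) -> str:
        return "".join(self.symbols[int(s)] for s in states)


@dataclass(frozen=True)
class PeptideRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise SeqIOError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class LabeledRecord:
    id: str
    sequence: str
    labels: str

    def __post_init__(self):
        if len(self.labels) != len(self.sequence):
            raise SeqIOError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"label length {len(self.labels)}"
            )


@dataclass
class EmbeddingTable:
    """Per-record matrices of per-residue feature vectors, uniform width."""

    entries: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dim(self) -> int | None:
        for m in self.entries.values():
            return int(m.shape[1])
        return None

    def __post_init__(self):
        dim = self.dim
        for rid, m in self.entries.items():
            if m.ndim != 2 or m.shape[1] != dim:
                raise SeqIOError(
                    f"embedding for {rid!r} has width {m.shape}, expected (*, {dim})"
                )


# ---------------------------------------------------------------------------
# FASTA

def _check_fasta_preamble(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SeqIOError(
                    f"{path}: line {lineno} precedes the first FASTA header"
                )
            return


def read_fasta(path: str | Path,
               alphabet: ResidueAlphabet | None = None) -> list[PeptideRecord]:
    """Read peptide records, in file order, joining wrapped sequence lines."""
    alphabet = alphabet or ResidueAlphabet()
    _check_fasta_preamble(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SeqIOError(f"{path}: FASTA record with empty header")
        seq = alphabet.clean(str(rec.seq), record_id=rec.id)
        records.append(PeptideRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(path: str | Path, records: list) -> None:
    """Write PeptideRecord or (id, string) pairs as FASTA (UTF-8)."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, (PeptideRecord, LabeledRecord)):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def write_labels(path: str | Path, records: list[LabeledRecord]) -> None:
    """Write label strings as a FASTA-like file (header + state string)."""
    write_fasta(path, [(r.id, r.labels) for r in records])


def _read_label_fasta(path: str | Path, ss: SSAlphabet) -> dict[str, str]:
    _check_fasta_preamble(path)
    labels: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in labels:
            raise SeqIOError(f"{path}: duplicate label record id {rec.id!r}")
        labels[rec.id] = ss.validate(str(rec.seq).upper(), record_id=rec.id)
    return labels


def read_labeled_dataset(seq_path: str | Path, label_path: str | Path,
                         ss: SSAlphabet | None = None,
                         alphabet: ResidueAlphabet | None = None,
                         ) -> list[LabeledRecord]:
    """Pair a sequence FASTA with a label FASTA by record id.

    Ids present in only one of the two files, and sequence/label length
    mismatches, are errors naming the offending record.
    """
    ss = ss or SSAlphabet()
    seqs = read_fasta(seq_path, alphabet)
    labels = _read_label_fasta(label_path, ss)
    seq_ids = {r.id for r in seqs}
    if len(seq_ids) != len(seqs):
        raise SeqIOError(f"{seq_path}: duplicate sequence record ids")
    missing = seq_ids.symmetric_difference(labels)
    if missing:
        raise SeqIOError(
            "ids present in only one file: " + ", ".join(sorted(missing))
        )
    return [LabeledRecord(r.id, r.sequence, labels[r.id]) for r in seqs]


def reduce_8_to_3(labels: str, eight: SSAlphabet | None = None) -> str:
    """Collapse 8-state DSSP labels to 3-state: H,G,I->H; E,B->E; T,S,C->C."""
    eight = eight or SSAlphabet("eight_state")
    eight.validate(labels)
    return "".join(EIGHT_TO_THREE[c] for c in labels)


# ---------------------------------------------------------------------------
# Embedding tables

def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read per-residue embeddings from TSV or an HDF5 keyed container."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_embeddings_h5(path)
    return _read_embeddings_tsv(path)


def _read_embeddings_tsv(path: Path) -> EmbeddingTable:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise SeqIOError(f"{path}: ragged or malformed TSV ({err})") from err
    if df.empty:
        return EmbeddingTable({})
    if df.shape[1] < 3:
        raise SeqIOError(f"{path}: expected columns id, position, vector...")
    if df.iloc[:, 2:].isna().any().any():
        raise SeqIOError(f"{path}: ragged rows (missing vector components)")
    entries: dict[str, np.ndarray] = {}
    for rid, group in df.groupby(0, sort=False):
        pos = group.iloc[:, 1].to_numpy(dtype=np.int64)
        if len(np.unique(pos)) != len(pos):
            raise SeqIOError(f"{path}: duplicate (id, position) for id {rid!r}")
        if set(pos) != set(range(len(pos))):
            raise SeqIOError(f"{path}: positions for {rid!r} are not 0..n-1")
        mat = group.iloc[:, 2:].to_numpy(dtype=np.float64)
        entries[str(rid)] = mat[np.argsort(pos)]
    return EmbeddingTable(entries)


def _read_embeddings_h5(path: Path) -> EmbeddingTable:
    import h5py

    entries: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for rid in fh:
            entries[str(rid)] = np.asarray(fh[rid], dtype=np.float64)
    return EmbeddingTable(entries)


def write_embeddings(path: str | Path, table: EmbeddingTable) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            for rid, mat in table.entries.items():
                fh.create_dataset(rid, data=mat)
        return
    with io.StringIO() as buf:
        for rid, mat in table.entries.items():
            for pos, row in enumerate(mat):
                vec = "\t".join(repr(float(v)) for v in row)
                buf.write(f"{rid}\t{pos}\t{vec}\n")
        Path(path).write_text(buf.getvalue(), encoding="utf-8")
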