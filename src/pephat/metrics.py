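"""Residue-level and segment-level evaluation of secondary-structure
predictions: per-state accuracy, overall accuracy, per-state F1, macro-F1,
and the SOV segment-overlap measure (1999 definition).

SOV credits each overlapping pair (s1, s2) of same-state reference and
predicted segments with ((minov + delta) / maxov) * len(s1), where

    delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2),

minov is the length of the actual overlap and maxov the extent of the
union.  The normalizer N counts len(s1) once per overlap partner, plus
len(s1) for reference segments with no partner.  Scores are reported as
percentages; dataset-level scores pool numerators and normalizers over
sequences before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import SSAlphabet


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    state: str
    span: tuple[int, int]

    def __len__(self) -> int:
        return self.span[1] - self.span[0]


def segmentize(labels: str) -> list[Segment]:
    """Maximal same-state runs, in order; concatenation rebuilds the input."""
    if not labels:
        raise MetricsError("cannot segmentize an empty label string")
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(state=labels[start], span=(start, i)))
            start = i
    return segments


@dataclass
class ConfusionCounts:
    """Pooled per-position tallies: reference counts, correct counts, and
    predicted-as-state counts."""

    states: str
    true_counts: dict[str, int] = field(default_factory=dict)       # A_i
    correct_counts: dict[str, int] = field(default_factory=dict)    # A_ii
    predicted_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.true_counts.values())

    @property
    def total_correct(self) -> int:
        return sum(self.correct_counts.values())

    def add(self, other: "ConfusionCounts") -> None:
        for s in self.states:
            self.true_counts[s] += other.true_counts[s]
            self.correct_counts[s] += other.correct_counts[s]
            self.predicted_counts[s] += other.predicted_counts[s]


def confusion(ref: str, pred: str, ss: SSAlphabet | None = None) -> ConfusionCounts:
    ss = ss or SSAlphabet()
    if len(ref) != len(pred):
        raise MetricsError(f"length mismatch: {len(ref)} vs {len(pred)}")
    counts = ConfusionCounts(
        states=ss.symbols,
        true_counts={s: 0 for s in ss.symbols},
        correct_counts={s: 0 for s in ss.symbols},
        predicted_counts={s: 0 for s in ss.symbols},
    )
    for r, p in zip(ref, pred):
        if r not in counts.true_counts or p not in counts.predicted_counts:
            raise MetricsError(f"state outside alphabet: {r!r}/{p!r}")
        counts.true_counts[r] += 1
        counts.predicted_counts[p] += 1
        if r == p:
            counts.correct_counts[r] += 1
    return counts


def accuracy_report(counts: ConfusionCounts) -> tuple[dict[str, float], float]:
    """(per-state accuracy, overall accuracy), as percentages.

    Overall accuracy is the pooled ratio 100 * sum A_ii / sum A_i, which is
    algebraically identical to the state-proportion-weighted mean of the
    per-state accuracies.
    """
    if counts.total == 0:
        raise MetricsError("empty confusion counts")
    per_state = {
        s: 100.0 * counts.correct_counts[s] / counts.true_counts[s]
        for s in counts.states if counts.true_counts[s] > 0
    }
    overall = 100.0 * counts.total_correct / counts.total
    return per_state, overall


def f1_report(counts: ConfusionCounts) -> tuple[dict[str, float], float]:
    """(per-state F1, macro-F1) as percentages; macro-F1 averages over the
    states present in the reference."""
    per_state: dict[str, float] = {}
    present = [s for s in counts.states if counts.true_counts[s] > 0]
    for s in counts.states:
        tp = counts.correct_counts[s]
        n_pred = counts.predicted_counts[s]
        n_true = counts.true_counts[s]
        if n_pred == 0 and n_true == 0:
            continue
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_true if n_true else 0.0
        f1 = (200.0 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        per_state[s] = f1
    macro = float(np.mean([per_state[s] for s in present])) if present else 0.0
    return per_state, macro


def _sov_terms(ref: str, pred: str, states: Iterable[str]) -> tuple[float, float]:
    """(numerator, normalizer) of the SOV sum for one sequence pair."""
    ref_segments = segmentize(ref)
    pred_segments = segmentize(pred)
    numerator = 0.0
    normalizer = 0.0
    for state in states:
        s1_list = [s for s in ref_segments if s.state == state]
        s2_list = [s for s in pred_segments if s.state == state]
        for s1 in s1_list:
            b1, e1 = s1.span
            partners = [s2 for s2 in s2_list
                        if min(e1, s2.span[1]) - max(b1, s2.span[0]) > 0]
            if not partners:
                normalizer += len(s1)
                continue
            for s2 in partners:
                b2, e2 = s2.span
                minov = min(e1, e2) - max(b1, b2)
                maxov = max(e1, e2) - min(b1, b2)
                delta = min(maxov - minov, minov, len(s1) // 2, len(s2) // 2)
                numerator += (minov + delta) / maxov * len(s1)
                normalizer += len(s1)
    return numerator, normalizer


def sov(ref: str, pred: str, ss: SSAlphabet | None = None) -> float:
    """SOV'99 score for one pair, as a percentage in [0, 100]."""
    ss = ss or SSAlphabet()
    if len(ref) != len(pred):
        raise MetricsError(f"length mismatch: {len(ref)} vs {len(pred)}")
    num, norm = _sov_terms(ref, pred, ss.symbols)
    return 100.0 * num / norm if norm > 0 else 0.0


@dataclass
class MetricsReport:
    acc_per_state: dict[str, float]
    acc: float
    f1_per_state: dict[str, float]
    macro_f1: float
    sov: float

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "acc_per_state": dict(self.acc_per_state),
            "f1_per_state": dict(self.f1_per_state),
            "macro_f1": self.macro_f1,
            "sov": self.sov,
        }

    def to_tsv(self) -> str:
        lines = ["metric\tstate\tvalue"]
        for s, v in self.acc_per_state.items():
            lines.append(f"acc\t{s}\t{v:.4f}")
        lines.append(f"acc\tall\t{self.acc:.4f}")
        for s, v in self.f1_per_state.items():
            lines.append(f"f1\t{s}\t{v:.4f}")
        lines.append(f"macro_f1\tall\t{self.macro_f1:.4f}")
        lines.append(f"sov\tall\t{self.sov:.4f}")
        return "\n".join(lines) + "\n"


def evaluate_dataset(pairs: Sequence[tuple[str, str]],
                     ss: SSAlphabet | None = None) -> MetricsReport:
    """Pool confusion counts over residues and SOV terms over sequences."""
    ss = ss or SSAlphabet()
    if not pairs:
        raise MetricsError("no sequence pairs to evaluate")
    pooled: ConfusionCounts | None = None
    sov_num = 0.0
    sov_norm = 0.0
    for ref, pred in pairs:
        counts = confusion(ref, pred, ss)
        if pooled is None:
            pooled = counts
        else:
            pooled.add(counts)
        num, norm = _sov_terms(ref, pred, ss.symbols)
        sov_num += num
        sov_norm += norm
    acc_per_state, acc = accuracy_report(pooled)
    f1_per_state, macro = f1_report(pooled)
    return MetricsReport(
        acc_per_state=acc_per_state,
        acc=acc,
        f1_per_state=f1_per_state,
        macro_f1=macro,
        sov=100.0 * sov_num / sov_norm if sov_norm > 0 else 0.0,
    )
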