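"""Linear-chain CRF with fused global/local transition matrices.

Scores of a label path y for a length-n sequence:

    S(y) = sum_i emission[i, y_i] + start[y_1]
         + sum_{i>=1} transition[i-1, y_{i-1}, y_i] + end[y_n]

The emission row for position i is a linear map of the encoder output at i.
The transition slice for the step i-1 -> i fuses a global L x L score matrix
with a per-position local matrix predicted from the encoder output at the
left endpoint i-1:

    transition[i-1] = (1 - lambda_local) * global + lambda_local * local(i-1)

Training minimizes -log P(y_true | x) = log Z(x) - S(y_true) with the
forward recursion computed entirely in log space; prediction maximizes S by
Viterbi dynamic programming with deterministic lowest-index tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class CRFError(ValueError):
    pass


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


@dataclass
class CRFParams:
    n_states: int
    global_transition: Tensor          # (L, L), [prev, next]
    start_scores: Tensor               # (L,)
    end_scores: Tensor                 # (L,)
    W_emission: Tensor                 # (width, L)
    b_emission: Tensor                 # (L,)
    W_local: Tensor                    # (width, L*L)
    b_local: Tensor                    # (L*L,)
    lambda_local: float = 0.5

    @classmethod
    def create(cls, rng: np.random.Generator, width: int, n_states: int,
               lambda_local: float = 0.5) -> "CRFParams":
        if not 0.0 <= lambda_local <= 1.0:
            raise CRFError("lambda_local must lie in [0, 1]")
        L = n_states
        return cls(
            n_states=L,
            global_transition=Tensor(0.01 * rng.standard_normal((L, L)),
                                     requires_grad=True),
            start_scores=Tensor(np.zeros(L), requires_grad=True),
            end_scores=Tensor(np.zeros(L), requires_grad=True),
            W_emission=Tensor(_glorot(rng, width, L), requires_grad=True),
            b_emission=Tensor(np.zeros(L), requires_grad=True),
            W_local=Tensor(_glorot(rng, width, L * L), requires_grad=True),
            b_local=Tensor(np.zeros(L * L), requires_grad=True),
            lambda_local=lambda_local,
        )

    def parameters(self) -> list[Tensor]:
        return [self.global_transition, self.start_scores, self.end_scores,
                self.W_emission, self.b_emission, self.W_local, self.b_local]


@dataclass
class Potentials:
    """Per-sequence CRF potentials (autodiff tensors)."""

    emission: Tensor       # (n, L)
    transition: Tensor     # (n-1, L, L); empty tensor for n = 1
    start_scores: Tensor   # (L,)
    end_scores: Tensor     # (L,)

    @property
    def n(self) -> int:
        return self.emission.shape[0]

    @property
    def n_states(self) -> int:
        return self.emission.shape[1]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.emission.data, self.transition.data,
                self.start_scores.data, self.end_scores.data)


@dataclass
class ViterbiTables:
    delta: np.ndarray      # (n, L) best-path scores
    psi: np.ndarray        # (n, L) argmax back-pointers (row 0 unused)


@dataclass
class PathScore:
    value: float


def compute_potentials(encoded: Tensor | np.ndarray, params: CRFParams) -> Potentials:
    """Emission rows plus per-step fused global/local transition slices."""
    encoded = ad.as_tensor(encoded)
    n = encoded.shape[0]
    L = params.n_states
    if encoded.shape[1] != params.W_emission.shape[0]:
        raise CRFError(
            f"encoder width {encoded.shape[1]} != CRF input width "
            f"{params.W_emission.shape[0]}"
        )
    emission = encoded @ params.W_emission + params.b_emission
    if n > 1:
        # local matrix for the step i-1 -> i comes from the left endpoint
        local = (encoded[:-1] @ params.W_local + params.b_local).reshape(n - 1, L, L)
        lam = params.lambda_local
        transition = local * lam + params.global_transition.reshape(1, L, L) * (1 - lam)
    else:
        transition = Tensor(np.zeros((0, L, L)))
    return Potentials(emission=emission, transition=transition,
                      start_scores=params.start_scores,
                      end_scores=params.end_scores)


def path_score(potentials: Potentials, labels) -> PathScore | Tensor:
    """Score of one label path.  Returns a Tensor so it can carry gradients;
    use float() or .value via score_value() for a plain number."""
    labels = np.asarray(labels, dtype=np.int64)
    n, L = potentials.n, potentials.n_states
    if len(labels) != n:
        raise CRFError(f"label length {len(labels)} != sequence length {n}")
    if labels.min() < 0 or labels.max() >= L:
        raise CRFError("label indices out of range")
    score = potentials.start_scores[labels[0]] + potentials.emission[0, labels[0]]
    if n > 1:
        pos = np.arange(n - 1)
        score = score + potentials.emission[1:][pos, labels[1:]].sum()
        score = score + potentials.transition[pos, labels[:-1], labels[1:]].sum()
    score = score + potentials.end_scores[labels[-1]]
    return score


def score_value(potentials: Potentials, labels) -> PathScore:
    return PathScore(value=float(path_score(potentials, labels)))


def log_partition(potentials: Potentials) -> Tensor:
    """log sum over all L^n paths of exp(path score), via the forward
    recursion in log space."""
    n, L = potentials.n, potentials.n_states
    alpha = potentials.start_scores + potentials.emission[0]     # (L,)
    for i in range(1, n):
        prev = alpha.reshape(L, 1)
        step = prev + potentials.transition[i - 1] + potentials.emission[i].reshape(1, L)
        alpha = ad.logsumexp(step, axis=0)
    return ad.logsumexp(alpha + potentials.end_scores, axis=0)


def crf_loss(potentials: Potentials, labels) -> Tensor:
    """Negative log-likelihood of the true path: log Z - S(y_true) >= 0."""
    return log_partition(potentials) - path_score(potentials, labels)


def viterbi_decode(potentials: Potentials) -> tuple[np.ndarray, ViterbiTables]:
    """Maximum-scoring label path; ties broken toward the lowest state index."""
    emission, transition, start, end = potentials.as_arrays()
    n, L = emission.shape
    delta = np.zeros((n, L))
    psi = np.zeros((n, L), dtype=np.int64)
    delta[0] = start + emission[0]
    for i in range(1, n):
        cand = delta[i - 1][:, None] + transition[i - 1]      # (prev, next)
        psi[i] = np.argmax(cand, axis=0)                       # first max = lowest idx
        delta[i] = cand[psi[i], np.arange(L)] + emission[i]
    final = delta[-1] + end
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(final))
    for i in range(n - 2, -1, -1):
        path[i] = psi[i + 1][path[i + 1]]
    return path, ViterbiTables(delta=delta, psi=psi)


def transition_feature_count(ss) -> int:
    """Number of state-pair transition features: L^2 (9 for 3-state, 64 for
    8-state)."""
    return int(ss.n_states) ** 2
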