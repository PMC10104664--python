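"""CRF head: potentials, path scores, exact inference against brute-force
enumeration, and Viterbi decoding."""

import itertools

import numpy as np
import pytest

from pephat.autodiff import Tensor
from pephat.crf import (CRFError, CRFParams, Potentials, compute_potentials,
                        crf_loss, log_partition, path_score,
                        transition_feature_count, viterbi_decode)
from pephat.seqio import SSAlphabet


def make_potentials(rng, n, L, scale=1.0):
    return Potentials(
        emission=Tensor(scale * rng.standard_normal((n, L))),
        transition=Tensor(scale * rng.standard_normal((max(0, n - 1), L, L))),
        start_scores=Tensor(scale * rng.standard_normal(L)),
        end_scores=Tensor(scale * rng.standard_normal(L)),
    )


def brute_force_scores(p: Potentials) -> dict[tuple, float]:
    """Independent enumeration oracle: score of every label path."""
    emission, transition, start, end = p.as_arrays()
    n, L = emission.shape
    out = {}
    for path in itertools.product(range(L), repeat=n):
        s = start[path[0]] + end[path[-1]]
        for i, y in enumerate(path):
            s += emission[i, y]
        for i in range(1, n):
            s += transition[i - 1, path[i - 1], path[i]]
        out[path] = float(s)
    return out


# -- potentials ---------------------------------------------------------------

def test_compute_potentials_lambda_zero_reduces_to_global():
    rng = np.random.default_rng(0)
    params = CRFParams.create(rng, width=6, n_states=3, lambda_local=0.0)
    encoded = Tensor(rng.standard_normal((5, 6)))
    pot = compute_potentials(encoded, params)
    for i in range(4):
        np.testing.assert_allclose(pot.transition.data[i],
                                   params.global_transition.data)


def test_compute_potentials_lambda_one_zero_local():
    rng = np.random.default_rng(1)
    params = CRFParams.create(rng, width=6, n_states=3, lambda_local=1.0)
    params.W_local.data[:] = 0.0
    params.b_local.data[:] = 0.0
    pot = compute_potentials(Tensor(rng.standard_normal((4, 6))), params)
    assert np.all(pot.transition.data == 0.0)


def test_compute_potentials_single_position():
    rng = np.random.default_rng(2)
    params = CRFParams.create(rng, width=6, n_states=3)
    pot = compute_potentials(Tensor(rng.standard_normal((1, 6))), params)
    assert pot.emission.data.shape == (1, 3)
    assert pot.transition.data.shape == (0, 3, 3)


def test_local_transition_uses_left_endpoint():
    """The slice for step i-1 -> i is a function of encoder row i-1."""
    rng = np.random.default_rng(3)
    params = CRFParams.create(rng, width=4, n_states=3, lambda_local=1.0)
    enc = rng.standard_normal((5, 4))
    pot = compute_potentials(Tensor(enc), params)
    enc2 = enc.copy()
    enc2[-1] += 10.0          # perturbing the last row changes no transition
    pot2 = compute_potentials(Tensor(enc2), params)
    np.testing.assert_array_equal(pot.transition.data, pot2.transition.data)


def test_width_mismatch_rejected():
    params = CRFParams.create(np.random.default_rng(4), width=6, n_states=3)
    with pytest.raises(CRFError):
        compute_potentials(Tensor(np.zeros((3, 5))), params)


# -- path score ---------------------------------------------------------------

def test_path_score_zero_potentials():
    p = make_potentials(np.random.default_rng(5), 4, 3, scale=0.0)
    for path in itertools.product(range(3), repeat=4):
        assert float(path_score(p, list(path))) == 0.0


def test_path_score_single_position():
    rng = np.random.default_rng(6)
    p = make_potentials(rng, 1, 3)
    for y in range(3):
        expected = (p.emission.data[0, y] + p.start_scores.data[y]
                    + p.end_scores.data[y])
        assert np.isclose(float(path_score(p, [y])), expected)


def test_path_score_term_by_term_oracle():
    rng = np.random.default_rng(7)
    p = make_potentials(rng, 4, 3)
    labels = [2, 0, 1, 1]
    # independent position-by-position accumulation
    s = p.start_scores.data[2] + p.end_scores.data[1]
    for i, y in enumerate(labels):
        s += p.emission.data[i, y]
    for i in range(1, 4):
        s += p.transition.data[i - 1, labels[i - 1], labels[i]]
    assert np.isclose(float(path_score(p, labels)), s)


def test_path_score_invalid_labels():
    p = make_potentials(np.random.default_rng(8), 3, 3)
    with pytest.raises(CRFError):
        path_score(p, [0, 1])
    with pytest.raises(CRFError):
        path_score(p, [0, 1, 3])


# -- partition function -------------------------------------------------------

def test_log_partition_uniform_closed_form():
    for n in (1, 2, 4, 6):
        p = make_potentials(np.random.default_rng(9), n, 3, scale=0.0)
        assert np.isclose(float(log_partition(p)), n * np.log(3), atol=1e-12)


def test_log_partition_matches_enumeration():
    rng = np.random.default_rng(10)
    for _ in range(30):
        n = int(rng.integers(1, 7))
        p = make_potentials(rng, n, 3, scale=2.0)
        scores = np.array(list(brute_force_scores(p).values()))
        expected = np.logaddexp.reduce(scores)
        assert np.isclose(float(log_partition(p)), expected, atol=1e-6)


def test_path_probabilities_normalize():
    rng = np.random.default_rng(11)
    p = make_potentials(rng, 5, 3)
    logZ = float(log_partition(p))
    total = sum(np.exp(s - logZ) for s in brute_force_scores(p).values())
    assert np.isclose(total, 1.0, atol=1e-6)


def test_log_partition_emission_shift_equivariance():
    rng = np.random.default_rng(12)
    p = make_potentials(rng, 5, 3)
    base = float(log_partition(p))
    c = 1.37
    p.emission.data[2] += c      # constant added to one position's column
    assert np.isclose(float(log_partition(p)), base + c, atol=1e-9)


# -- loss ---------------------------------------------------------------------

def test_loss_uniform_case_and_nonnegativity():
    rng = np.random.default_rng(13)
    p = make_potentials(rng, 4, 3, scale=0.0)
    assert np.isclose(float(crf_loss(p, [0, 1, 2, 0])), 4 * np.log(3))
    for _ in range(20):
        n = int(rng.integers(1, 7))
        q = make_potentials(rng, n, 3)
        labels = rng.integers(0, 3, size=n)
        assert float(crf_loss(q, labels)) >= -1e-12


def test_loss_single_state_space_is_zero():
    p = make_potentials(np.random.default_rng(14), 5, 1)
    assert np.isclose(float(crf_loss(p, [0] * 5)), 0.0, atol=1e-12)


def test_loss_saturates_on_peaked_emissions():
    rng = np.random.default_rng(15)
    n, L = 5, 3
    labels = rng.integers(0, L, size=n)
    p = make_potentials(rng, n, L, scale=0.0)
    p.emission.data[np.arange(n), labels] = 100.0
    assert float(crf_loss(p, labels)) < 1e-6


# -- Viterbi ------------------------------------------------------------------

def test_viterbi_single_position_and_ties():
    p = make_potentials(np.random.default_rng(16), 1, 3, scale=0.0)
    path, _ = viterbi_decode(p)
    assert list(path) == [0]          # tie broken to lowest index
    p.emission.data[0, 2] = 5.0
    path, _ = viterbi_decode(p)
    assert list(path) == [2]


def test_viterbi_all_zero_scores_gives_all_zero_path():
    p = make_potentials(np.random.default_rng(17), 6, 3, scale=0.0)
    path, tables = viterbi_decode(p)
    assert np.all(path == 0)
    assert np.all(tables.delta == 0.0)


def test_viterbi_matches_enumeration_and_dominates_random_paths():
    rng = np.random.default_rng(18)
    for _ in range(200):
        n = int(rng.integers(1, 7))
        p = make_potentials(rng, n, 3, scale=1.5)
        scores = brute_force_scores(p)
        best = max(scores.values())
        path, _ = viterbi_decode(p)
        assert np.isclose(float(path_score(p, path)), best, atol=1e-9)
        # dominance over random alternatives
        for _ in range(5):
            alt = tuple(rng.integers(0, 3, size=n))
            assert scores[alt] <= float(path_score(p, path)) + 1e-9


def test_transition_feature_counts():
    assert transition_feature_count(SSAlphabet("three_state")) == 9
    assert transition_feature_count(SSAlphabet("eight_state")) == 64
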