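"""Likelihood correctness against exhaustive latent-state enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from feroxmr.encounters import CaptureHistoryMatrix, MalformedDataError
from feroxmr.model import (
    ConfigError,
    HistoryClasses,
    ModelConfig,
    ParameterVector,
    dataset_loglik,
    dataset_loglik_batched,
    entry_schedule,
    individual_marginal_loglik,
    sample_latent_states,
)

probs = st.floats(min_value=0.05, max_value=0.95)


def hmm_enumeration_loglik(y, theta, T):
    """Brute-force oracle: sum over all 3-state occupancy sequences.

    States: 0 = not yet entered, 1 = alive, 2 = dead; entry uses the
    conditional (removal) probabilities, an independent path through the
    same joint law as the marginalised likelihood.
    """
    gamma = entry_schedule(theta.rho1, T).gamma
    total = 1.0 - theta.psi if sum(y) == 0 else 0.0
    for states in itertools.product((0, 1, 2), repeat=T):
        pr = theta.psi
        pr *= gamma[0] if states[0] == 1 else (1.0 - gamma[0] if states[0] == 0 else 0.0)
        for t in range(1, T):
            prev, cur = states[t - 1], states[t]
            if prev == 0:
                pr *= gamma[t] if cur == 1 else (1.0 - gamma[t] if cur == 0 else 0.0)
            elif prev == 1:
                pr *= theta.S if cur == 1 else (1.0 - theta.S if cur == 2 else 0.0)
            else:
                pr *= 1.0 if cur == 2 else 0.0
        for t in range(T):
            if states[t] == 1:
                pr *= theta.p if y[t] else 1.0 - theta.p
            elif y[t]:
                pr = 0.0
        total += pr
    return math.log(total)


class TestEntrySchedule:
    def test_two_occasion_example(self):
        es = entry_schedule(0.5, 2)
        assert np.allclose(es.b, [0.5, 0.5])
        assert np.allclose(es.gamma, [0.5, 1.0])

    def test_rannoch_scale_example(self):
        es = entry_schedule(0.26, 16)
        assert np.allclose(es.b[1:], 0.74 / 15)
        assert math.isclose(es.b.sum(), 1.0, abs_tol=1e-12)

    @given(rho1=probs, T=st.integers(2, 20))
    @settings(max_examples=50, deadline=None)
    def test_gamma_inverts_to_b(self, rho1, T):
        es = entry_schedule(rho1, T)
        # reconstruct b from the removal recursion
        not_entered = 1.0
        b_back = []
        for g in es.gamma:
            b_back.append(not_entered * g)
            not_entered *= 1.0 - g
        assert np.allclose(b_back, es.b, atol=1e-9)
        assert ((es.gamma >= 0) & (es.gamma <= 1)).all()

    def test_too_few_occasions(self):
        with pytest.raises(ConfigError):
            entry_schedule(0.5, 1)


class TestMarginalLoglik:
    @pytest.mark.parametrize(
        "theta",
        [
            ParameterVector(0.6, 0.7, 0.3, 0.4),
            ParameterVector(0.42, 0.74, 0.08, 0.26),
            ParameterVector(0.9, 0.2, 0.85, 0.1),
        ],
    )
    @pytest.mark.parametrize("T", [3, 4])
    def test_matches_enumeration_on_all_histories(self, theta, T):
        config = ModelConfig(T=T, M=2)
        for y in itertools.product((0, 1), repeat=T):
            got = individual_marginal_loglik(np.array(y), theta, config)
            want = hmm_enumeration_loglik(y, theta, T)
            assert got == pytest.approx(want, rel=1e-10)

    @given(psi=probs, S=probs, p=probs, rho1=probs)
    @settings(max_examples=25, deadline=None)
    def test_enumeration_agreement_random_parameters(self, psi, S, p, rho1):
        theta = ParameterVector(psi, S, p, rho1)
        config = ModelConfig(T=3, M=2)
        for y in itertools.product((0, 1), repeat=3):
            got = individual_marginal_loglik(np.array(y), theta, config)
            assert got == pytest.approx(hmm_enumeration_loglik(y, theta, 3), rel=1e-10)

    def test_excluded_individual_never_seen(self):
        theta = ParameterVector(1e-12, 0.5, 0.5, 0.5)
        config = ModelConfig(T=3, M=1)
        ll = individual_marginal_loglik(np.zeros(3, dtype=int), theta, config)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_malformed_history(self):
        theta = ParameterVector(0.5, 0.5, 0.5, 0.5)
        config = ModelConfig(T=3, M=1)
        with pytest.raises(MalformedDataError):
            individual_marginal_loglik(np.array([0, 2, 0]), theta, config)


class TestDatasetLoglik:
    def test_sum_of_individual_terms(self, rannoch_matrix, rannoch_config):
        theta = ParameterVector(0.42, 0.74, 0.08, 0.26)
        zero = np.zeros(16, dtype=int)
        want = sum(
            individual_marginal_loglik(row, theta, rannoch_config)
            for row in rannoch_matrix.y
        ) + (rannoch_config.M - rannoch_matrix.n_individuals) * individual_marginal_loglik(
            zero, theta, rannoch_config
        )
        got = dataset_loglik(rannoch_matrix, theta, rannoch_config)
        assert got == pytest.approx(want, rel=1e-12)

    def test_row_order_invariance(self, rannoch_matrix, rannoch_config):
        theta = ParameterVector(0.3, 0.6, 0.1, 0.3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rannoch_matrix.n_individuals)
        shuffled = CaptureHistoryMatrix(rannoch_matrix.y[perm], rannoch_matrix.years)
        assert dataset_loglik(shuffled, theta, rannoch_config) == pytest.approx(
            dataset_loglik(rannoch_matrix, theta, rannoch_config), rel=1e-12
        )

    def test_augmentation_too_small(self, rannoch_matrix):
        with pytest.raises(ConfigError):
            dataset_loglik(
                rannoch_matrix,
                ParameterVector(0.5, 0.5, 0.5, 0.5),
                ModelConfig(T=16, M=10),
            )

    def test_perfect_detection_certain_data(self):
        # M = n, everyone seen every year: probability 1 in the limit
        m = CaptureHistoryMatrix(np.ones((2, 3), dtype=int), (1, 2, 3))
        theta = ParameterVector(1 - 1e-12, 1 - 1e-12, 1 - 1e-12, 1 - 1e-12)
        ll = dataset_loglik(m, theta, ModelConfig(T=3, M=2))
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_psi_to_zero_impossible_with_observations(self, rannoch_matrix, rannoch_config):
        theta = np.array([1e-300, 0.7, 0.1, 0.3])
        classes = HistoryClasses.from_matrix(rannoch_matrix, rannoch_config)
        # 69 observed fish each contribute log(psi): the likelihood collapses
        assert dataset_loglik_batched(theta, classes) < -4e4

    def test_closed_population_limit(self):
        # S -> 1 and entry mass concentrated at the first occasion reduce the
        # model to the closed-population M0 likelihood psi p^k q^(T-k)
        T = 4
        y = np.array([[1, 0, 1, 0], [0, 1, 1, 1]])
        m = CaptureHistoryMatrix(y, (1, 2, 3, 4))
        psi, p = 0.8, 0.3
        theta = ParameterVector(psi, 1 - 1e-13, p, 1 - 1e-13)
        want = sum(
            math.log(psi * p**k * (1 - p) ** (T - k)) for k in y.sum(axis=1)
        )
        got = dataset_loglik(m, theta, ModelConfig(T=T, M=2))
        assert got == pytest.approx(want, rel=1e-6)


class TestLatentStateSampling:
    def test_detections_force_inclusion_and_alive(self, rannoch_matrix, rannoch_config):
        theta = ParameterVector(0.4, 0.7, 0.1, 0.3)
        latent = sample_latent_states(rannoch_matrix, theta, rannoch_config, rng_seed=1)
        n = rannoch_matrix.n_individuals
        assert (latent.w[:n] == 1).all()
        assert (latent.z[:n][rannoch_matrix.y == 1] == 1).all()
        # alive runs are contiguous
        for row in latent.z:
            det = np.flatnonzero(row)
            if det.size:
                assert (row[det[0] : det[-1] + 1] == 1).all()

    def test_perfect_detection_brackets_exactly(self):
        m = CaptureHistoryMatrix(np.array([[0, 1, 1, 0]]), (1, 2, 3, 4))
        theta = ParameterVector(0.5, 0.5, 1 - 1e-12, 0.5)
        config = ModelConfig(T=4, M=1)
        latent = sample_latent_states(m, theta, config, rng_seed=3)
        assert latent.z[0].tolist() == [0, 1, 1, 0]

    def test_entry_frequencies_match_enumerated_conditional(self):
        # toy history [0, 1, 0]: entry can be occasion 1 or 2
        T = 3
        y = np.array([[0, 1, 0]])
        m = CaptureHistoryMatrix(y, (1, 2, 3))
        theta = ParameterVector(0.5, 0.6, 0.4, 0.35)
        config = ModelConfig(T=T, M=1)
        b = entry_schedule(theta.rho1, T).b
        q = 1 - theta.p
        # enumerate Pr(e, d | y) over e <= 1, d >= 1
        weights = {}
        for e in range(2):
            for d in range(1, T):
                m_d = (1 - theta.S) if d < T - 1 else 1.0
                run = d - e + 1
                weights[(e, d)] = b[e] * theta.S ** (d - e) * m_d * theta.p * q ** (run - 1)
        Z = sum(weights.values())
        p_entry0 = sum(v for (e, _), v in weights.items() if e == 0) / Z
        rng = np.random.default_rng(11)
        draws = 30_000
        hits = 0
        for _ in range(draws):
            latent = sample_latent_states(m, theta, config, rng_seed=rng)
            hits += latent.z[0, 0] == 1
        freq = hits / draws
        se = math.sqrt(p_entry0 * (1 - p_entry0) / draws)
        assert abs(freq - p_entry0) < 3 * se


class TestJointLatentEnumeration:
    def test_dataset_loglik_equals_joint_enumeration(self):
        """Marginalised dataset likelihood equals the full latent-state sum
        over both individuals of a T=3, M=2 instance."""
        T = 3
        m = CaptureHistoryMatrix(np.array([[0, 1, 0]]), (1, 2, 3))  # n=1, one pseudo
        theta = ParameterVector(0.55, 0.65, 0.35, 0.45)
        config = ModelConfig(T=T, M=2)
        want = hmm_enumeration_loglik((0, 1, 0), theta, T) + hmm_enumeration_loglik(
            (0, 0, 0), theta, T
        )
        got = dataset_loglik(m, theta, config)
        assert got == pytest.approx(want, rel=1e-10)
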