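"""Coupled-Markov kernel and coupling-coefficient estimation.

The independent-aggregate kernel is checked against a brute-force
enumeration over explicit channel configurations, and the likelihood
against hand-computed path products.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavcoupling.core import ValidationError
from cavcoupling.idealize import idealize_record
from cavcoupling.markov import (
    build_transition_matrix,
    estimate_kappa,
    loglik_sequence,
    stationary_distribution,
    transition_counts,
)
from cavcoupling.synthetic import GatingParams, simulate_coupled_record


def brute_force_indep_kernel(n: int, p_co: float, p_oc: float) -> np.ndarray:
    """Aggregate kernel by explicit enumeration of 2^n channel configurations.

    Channels are exchangeable, so any start configuration with k open
    channels gives row k.
    """
    T = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        start = (1,) * k + (0,) * (n - k)
        for nxt in itertools.product((0, 1), repeat=n):
            p = 1.0
            for s, x in zip(start, nxt):
                if s == 1:
                    p *= (1.0 - p_oc) if x == 1 else p_oc
                else:
                    p *= p_co if x == 1 else (1.0 - p_co)
            T[k, sum(nxt)] += p
    return T


def coupled_kernel_direct(n: int, p_co: float, p_oc: float) -> np.ndarray:
    """All-or-none kernel from its defining formula."""
    T = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        p_up = (k / n) * (1.0 - p_oc) + (1.0 - k / n) * p_co
        T[k, n] = p_up
        T[k, 0] += 1.0 - p_up
    return T


class TestBuildTransitionMatrix:
    def test_single_channel_two_state(self):
        k = build_transition_matrix(1, 0.2, 0.4, 0.0)
        expected = np.array([[0.8, 0.2], [0.4, 0.6]])
        np.testing.assert_allclose(k.T, expected)

    def test_single_channel_ignores_kappa(self):
        a = build_transition_matrix(1, 0.2, 0.4, 0.0)
        b = build_transition_matrix(1, 0.2, 0.4, 0.9)
        np.testing.assert_allclose(a.T, b.T)

    @pytest.mark.parametrize("n", [2, 3, 4])
    @pytest.mark.parametrize("p_co,p_oc", [(0.1, 0.3), (0.02, 0.9), (0.5, 0.5)])
    def test_independent_kernel_matches_enumeration(self, n, p_co, p_oc):
        k = build_transition_matrix(n, p_co, p_oc, 0.0)
        np.testing.assert_allclose(
            k.T, brute_force_indep_kernel(n, p_co, p_oc), atol=1e-12
        )

    def test_fully_coupled_all_or_none_structure(self):
        n, p_co, p_oc = 6, 0.05, 0.2
        k = build_transition_matrix(n, p_co, p_oc, 1.0)
        assert k.T[0, n] == pytest.approx(p_co)
        assert k.T[n, 0] == pytest.approx(p_oc)
        # intermediate states exit to {0, n} with probability 1
        for s in range(1, n):
            assert k.T[s, 0] + k.T[s, n] == pytest.approx(1.0)
            assert np.all(k.T[s, 1:n] == 0.0)

    def test_mixture_is_linear_in_kappa(self):
        n, p_co, p_oc = 4, 0.1, 0.2
        T0 = build_transition_matrix(n, p_co, p_oc, 0.0).T
        T1 = build_transition_matrix(n, p_co, p_oc, 1.0).T
        Th = build_transition_matrix(n, p_co, p_oc, 0.37).T
        np.testing.assert_allclose(Th, 0.63 * T0 + 0.37 * T1, atol=1e-14)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            build_transition_matrix(0, 0.1, 0.1, 0.0)
        with pytest.raises(ValidationError):
            build_transition_matrix(4, 1.5, 0.1, 0.0)
        with pytest.raises(ValidationError):
            build_transition_matrix(4, 0.1, 0.1, float("nan"))

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(1, 8),
        p_co=st.floats(0.0, 1.0),
        p_oc=st.floats(0.0, 1.0),
        kappa=st.floats(0.0, 1.0),
    )
    def test_rows_stochastic_for_any_parameters(self, n, p_co, p_oc, kappa):
        k = build_transition_matrix(n, p_co, p_oc, kappa)
        assert np.all(k.T >= 0)
        np.testing.assert_allclose(k.T.sum(axis=1), 1.0, atol=1e-12)


class TestStationaryDistribution:
    def test_independent_stationary_is_binomial(self):
        # the probability that all n independent channels are simultaneously
        # open is Po^n — the coincidence argument for n = 5, Po = 0.3
        p_co, p_oc = 0.003, 0.007
        po = p_co / (p_co + p_oc)
        k = build_transition_matrix(5, p_co, p_oc, 0.0)
        pi = stationary_distribution(k)
        from scipy.stats import binom

        np.testing.assert_allclose(pi, binom.pmf(np.arange(6), 5, po), atol=1e-10)
        assert pi[5] == pytest.approx(0.3**5, rel=1e-9)


class TestLoglikSequence:
    def test_constant_closed_sequence_closed_form(self):
        n, p_co, p_oc = 3, 0.1, 0.2
        k = build_transition_matrix(n, p_co, p_oc, 0.0)
        levels = np.zeros(50, dtype=int)
        expected = 49 * n * np.log(1.0 - p_co)
        assert loglik_sequence(levels, k) == pytest.approx(expected)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0])
    def test_matches_hand_path_product(self, kappa):
        n, p_co, p_oc = 3, 0.15, 0.25
        k = build_transition_matrix(n, p_co, p_oc, kappa)
        T_mix = (1 - kappa) * brute_force_indep_kernel(n, p_co, p_oc)
        if kappa > 0:
            T_mix = T_mix + kappa * coupled_kernel_direct(n, p_co, p_oc)
        seq = np.array([0, 1, 3, 3, 0, 2])
        probs = [T_mix[a, b] for a, b in zip(seq[:-1], seq[1:])]
        if any(p == 0 for p in probs):
            assert loglik_sequence(seq, k) == -np.inf
        else:
            assert loglik_sequence(seq, k) == pytest.approx(np.sum(np.log(probs)))

    def test_all_or_none_sequence_prefers_coupled_kernel(self):
        n = 4
        seq = np.array([0, n, 0, n, 0, n, 0])
        k0 = build_transition_matrix(n, 0.3, 0.3, 0.0)
        k1 = build_transition_matrix(n, 0.3, 0.3, 1.0)
        assert loglik_sequence(seq, k1) > loglik_sequence(seq, k0)

    def test_impossible_transition_is_minus_inf(self):
        k = build_transition_matrix(4, 0.1, 0.1, 1.0)
        # 0 -> 2 has zero probability under the all-or-none kernel
        assert loglik_sequence(np.array([0, 2, 0]), k) == -np.inf

    def test_out_of_range_level_rejected(self):
        k = build_transition_matrix(2, 0.1, 0.1, 0.0)
        with pytest.raises(ValidationError):
            loglik_sequence(np.array([0, 3, 0]), k)

    def test_transition_counts_reconstruct_loglik(self, rng):
        n = 4
        k = build_transition_matrix(n, 0.2, 0.3, 0.5)
        seq = rng.integers(0, n + 1, size=200)
        C = transition_counts(seq, n)
        assert C.sum() == seq.size - 1
        ll = loglik_sequence(seq, k)
        if np.isfinite(ll):
            mask = C > 0
            assert ll == pytest.approx(float(np.sum(C[mask] * np.log(k.T[mask]))))


class TestEstimateKappa:
    def test_all_switching_together_is_fully_coupled(self):
        seq = np.tile(np.array([0] * 10 + [6] * 10), 30)
        res = estimate_kappa(seq, n=6)
        assert res.kappa_hat >= 0.9
        assert res.cooperative

    def test_constant_sequence_flagged_degenerate(self):
        res = estimate_kappa(np.zeros(100, dtype=int), n=4)
        assert res.degenerate
        assert np.isnan(res.kappa_hat)
        assert not res.cooperative

    def test_estimate_within_unit_cube(self):
        seq = np.tile(np.array([0, 1, 0, 2, 1, 0, 8, 8, 0, 3]), 20)
        res = estimate_kappa(seq, n=8)
        assert 0.0 <= res.kappa_hat <= 1.0
        assert 0.0 <= res.p_co_hat <= 1.0
        assert 0.0 <= res.p_oc_hat <= 1.0

    def test_independent_records_classified_non_cooperative(self):
        hats = []
        for seed in range(1, 7):
            params = GatingParams(kappa=0.0, duration=1.0, seed=seed)
            rec, _ = simulate_coupled_record(params)
            levels = idealize_record(rec, baseline=0.0, n_max=8, hysteresis=0.75)
            res = estimate_kappa(levels, n=8)
            hats.append(res.kappa_hat)
        assert np.mean(hats) <= 0.1

    def test_mean_kappa_increases_with_true_coupling(self):
        means = []
        for kappa in [0.0, 0.25, 0.5, 0.75, 1.0]:
            hats = []
            for seed in range(1, 5):
                params = GatingParams(kappa=kappa, duration=1.0, seed=seed)
                rec, _ = simulate_coupled_record(params)
                levels = idealize_record(rec, baseline=0.0, n_max=8, hysteresis=0.75)
                hats.append(estimate_kappa(levels, n=8).kappa_hat)
            means.append(np.mean(hats))
        assert np.all(np.diff(means) > 0)

    def test_n_defaults_to_max_level(self):
        seq = np.tile(np.array([0] * 5 + [5] * 5), 30)
        res = estimate_kappa(seq)
        assert res.n == 5

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValidationError):
            estimate_kappa(np.array([0, 1, 0]), n=2)
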