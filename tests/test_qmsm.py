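"""Memory-kernel extraction and generalized-master-equation propagation."""

import numpy as np
import pytest

from mtsm import (
    StochasticMatrix,
    ToyParams,
    extract_kernel,
    implied_timescales,
    initial_derivative,
    normalized_kernel,
    propagate_gme,
    qmsm_propagate,
    select_kernel_time,
    toy_macro_md_series,
    toy_micro_matrix,
    validate_stochastic,
)
from mtsm.errors import SeriesTooShort, ThresholdNeverMet, ZeroNormalizer
from mtsm.qmsm import MemoryKernelSeries


def markov_series(T: np.ndarray, n_max: int) -> list[np.ndarray]:
    """Exact CK series T(n) = T^n of a Markov chain (oracle input)."""
    return [np.linalg.matrix_power(T, n) for n in range(n_max + 1)]


TWO_STATE = np.array([[0.75, 0.25], [0.25, 0.75]])


class TestInitialDerivative:
    def test_static_series_gives_zero(self):
        assert initial_derivative([np.eye(2), np.eye(2)], 1.0) == pytest.approx(
            np.zeros((2, 2))
        )

    def test_forward_difference(self):
        Td0 = initial_derivative([np.eye(2), TWO_STATE], 1.0)
        assert Td0 == pytest.approx(np.array([[-0.25, 0.25], [0.25, -0.25]]))

    def test_columns_sum_to_zero(self, toy_weak):
        series, dt = toy_macro_md_series(toy_weak, 5)
        Td0 = initial_derivative(series, dt)
        assert Td0.sum(axis=0) == pytest.approx(np.zeros(2), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(SeriesTooShort):
            initial_derivative([np.eye(2)], 1.0)


class TestExtraction:
    def test_markovian_kernel_vanishes(self):
        """Exact CK input: the Tdot(0) term carries everything, K = 0."""
        K = extract_kernel(markov_series(TWO_STATE, 12), 1.0)
        assert np.max(np.abs(K.kernels)) < 1e-12

    def test_kernel_at_zero_cancels(self, toy_weak):
        """K_0 = 0 identically: the Tdot(0) T(t) term cancels the kernel at t=0."""
        series, dt = toy_macro_md_series(toy_weak, 20)
        K = extract_kernel(series, dt)
        assert np.max(np.abs(K.kernels[0])) < 1e-14
        assert np.max(np.abs(K.kernels[1])) > 1e-4  # memory is real at h/k = 1

    def test_dropping_tdot0_moves_dynamics_into_k0(self):
        """Without the Tdot(0) term, K_0 = (1 - T_1)/dt^2 is the only
        nonzero kernel for Markovian input."""
        K = extract_kernel(markov_series(TWO_STATE, 8), 1.0, keep_Tdot0_term=False)
        assert K.kernels[0] == pytest.approx(np.eye(2) - TWO_STATE)
        assert np.max(np.abs(K.kernels[1:])) < 1e-12

    def test_toy_kernel_symmetry(self, toy_weak):
        """K_LL = K_RR = -K_LR = -K_RL for the symmetric two-macrostate model."""
        series, dt = toy_macro_md_series(toy_weak, 20)
        K = extract_kernel(series, dt).kernels
        assert K[:, 0, 0] == pytest.approx(K[:, 1, 1], abs=1e-13)
        assert K[:, 0, 0] == pytest.approx(-K[:, 0, 1], abs=1e-13)
        assert K[:, 0, 0] == pytest.approx(-K[:, 1, 0], abs=1e-13)


class TestNormalizedKernel:
    def test_unity_at_first_step(self, toy_weak):
        series, dt = toy_macro_md_series(toy_weak, 15)
        nk = normalized_kernel(extract_kernel(series, dt))
        assert nk[1] == pytest.approx(1.0)

    def test_zero_normalizer(self):
        K = MemoryKernelSeries(np.zeros((3, 2, 2)), 1.0, np.zeros((2, 2)))
        with pytest.raises(ZeroNormalizer):
            normalized_kernel(K)

    def test_toy_decay_rate(self, toy_weak):
        """At h/k = 1 the kernel decays geometrically by 1 - h - k - ... = 0.7."""
        series, dt = toy_macro_md_series(toy_weak, 15)
        nk = normalized_kernel(extract_kernel(series, dt))
        assert nk[2:6] == pytest.approx(0.7 ** np.arange(1, 5), rel=1e-8)


class TestKernelTimeSelection:
    def test_geometric_example(self):
        """Normalized series 1, 0.5, 0.25, ...: first value <= 0.1 at n = 5."""
        vals = 0.5 ** np.arange(8)  # K_1 = 1, K_2 = 0.5, ...
        kernels = np.zeros((9, 2, 2))
        kernels[1:, 0, 0] = vals
        K = MemoryKernelSeries(kernels, 1.0, np.zeros((2, 2)))
        assert select_kernel_time(K, threshold=0.1) == pytest.approx(5.0)

    def test_markovian_input_earliest_selection(self):
        """An identically zero kernel selects the earliest time dt."""
        K = extract_kernel(markov_series(TWO_STATE, 10), 1.0)
        assert select_kernel_time(K) == pytest.approx(1.0)

    def test_threshold_never_met(self):
        kernels = np.ones((6, 2, 2))
        K = MemoryKernelSeries(kernels, 1.0, np.zeros((2, 2)))
        with pytest.raises(ThresholdNeverMet):
            select_kernel_time(K, threshold=0.1)

    def test_persistence_skips_transient_dips(self):
        vals = np.array([0.0, 1.0, 0.05, 0.5, 0.04, 0.03, 0.02, 0.01])
        kernels = np.zeros((8, 2, 2))
        kernels[:, 0, 0] = vals
        K = MemoryKernelSeries(kernels, 1.0, np.zeros((2, 2)))
        # n = 2 dips below 0.1 but n = 3 rebounds; first persistent time is 4
        assert select_kernel_time(K, threshold=0.1) == pytest.approx(4.0)

    def test_toy_selections(self):
        for (h, k), expected in [((0.1, 0.1), 8.0), ((0.5, 0.1), 3.0),
                                 ((0.1, 0.5), 3.0)]:
            series, dt = toy_macro_md_series(ToyParams(h, k), 40)
            K = extract_kernel(series, dt)
            assert select_kernel_time(K) == pytest.approx(expected), (h, k)


class TestPropagation:
    def test_markovian_reduces_to_ck_powers(self):
        series = markov_series(TWO_STATE, 10)
        K = extract_kernel(series, 1.0)
        out = propagate_gme(series[:3], K, tau_K=2.0, horizon=50.0)
        assert out[50].probs == pytest.approx(
            np.linalg.matrix_power(TWO_STATE, 50), abs=1e-6
        )

    def test_training_window_roundtrip(self, toy_strong):
        """Extraction inverts propagation exactly on the training window."""
        series, dt = toy_macro_md_series(toy_strong, 30)
        prop, tau_K, _ = qmsm_propagate(series, dt, horizon=30.0)
        n_K = int(round(tau_K / dt))
        for n in range(n_K + 1):
            assert prop[n].probs == pytest.approx(series[n].probs, abs=1e-8)

    def test_probability_conservation(self, toy_weak):
        series, dt = toy_macro_md_series(toy_weak, 30)
        prop, _, _ = qmsm_propagate(series, dt, horizon=200.0)
        for T in prop:
            assert T.probs.sum(axis=0) == pytest.approx(np.ones(2), abs=1e-6)

    def test_iteration_idempotent(self, toy_weak):
        """Re-extracting from the propagated series and re-propagating
        changes nothing."""
        series, dt = toy_macro_md_series(toy_weak, 30)
        prop1, tau_K, _ = qmsm_propagate(series, dt, horizon=100.0)
        prop2, tau_K2, _ = qmsm_propagate(
            [T.probs for T in prop1[:31]], dt, horizon=100.0
        )
        assert tau_K2 == pytest.approx(tau_K)
        assert prop2[100].probs == pytest.approx(prop1[100].probs, abs=1e-10)

    def test_tdot0_term_barely_matters(self, toy_weak):
        """Populations with and without the Tdot(0) T(t) term differ < 1%."""
        series, dt = toy_macro_md_series(toy_weak, 30)
        with_term, _, _ = qmsm_propagate(series, dt, 100.0, keep_Tdot0_term=True)
        without, _, _ = qmsm_propagate(series, dt, 100.0, keep_Tdot0_term=False)
        for a, b in zip(with_term, without):
            assert np.max(np.abs(a.probs - b.probs)) < 0.01

    def test_markov_limit_timescale(self):
        """h/k <= 0.05: qMSM matches the microstate timescale within 2%."""
        p = ToyParams(h=0.01, k=0.45)
        t_micro = implied_timescales(toy_micro_matrix(p)).slowest
        series, dt = toy_macro_md_series(p, 40)
        prop, _, _ = qmsm_propagate(series, dt, horizon=100.0)
        t_q = implied_timescales(prop[100]).slowest
        assert abs(t_q - t_micro) / t_micro < 0.02

    def test_blowup_guard(self):
        """A grossly inconsistent kernel aborts instead of silently renormalizing."""
        from mtsm.errors import Blowup

        series = markov_series(TWO_STATE, 4)
        bad = np.zeros((3, 2, 2))
        bad[1] = [[5.0, -5.0], [-5.0, 5.0]]
        K = MemoryKernelSeries(bad, 1.0, initial_derivative(series, 1.0))
        with pytest.raises(Blowup):
            propagate_gme(series[:3], K, tau_K=2.0, horizon=20.0)
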