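import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from looplab.correlation import (
    HBondExistenceMatrix,
    fluorescence_autocorrelation,
    hbond_existence_autocorrelation,
    log_lag_grid,
)
from looplab.errors import DegenerateSignalError, InputError, LagError
from looplab.state_signal import StateSeries
from looplab.synthetic_data import TelegraphParams, gen_telegraph


def brute_force_g(states, ks):
    """O(N*L) reference: plain double loop, mean-squared normalisation."""
    x = states.astype(float)
    n = x.size
    mean = x.mean()
    out = []
    for k in ks:
        acc = 0.0
        for t in range(n - k):
            acc += x[t] * x[t + k]
        out.append((acc / (n - k)) / mean**2)
    return np.array(out)


def brute_force_c(H, ks, mode):
    n, nb = H.shape
    out = []
    for k in ks:
        num = 0.0
        den = 0.0
        for j in range(nb):
            for t in range(n - k):
                if H[t, j]:
                    den += 1.0
                    if mode == "intermittent":
                        num += H[t + k, j]
                    else:
                        num += 1.0 if all(H[t:t + k + 1, j]) else 0.0
        out.append(num / den)
    return np.array(out)


class TestFluorescenceG:
    def test_constant_signal_gives_unity(self):
        s = StateSeries(dt=1.0, states=np.ones(50, dtype=int))
        c = fluorescence_autocorrelation(s, lags=[0, 1, 5, 10])
        np.testing.assert_allclose(c.values, 1.0, atol=1e-14)

    def test_alternating_signal_hand_computation(self):
        s = StateSeries(dt=1.0, states=np.tile([1, 0], 25))
        c = fluorescence_autocorrelation(s, lags=[0.0, 1.0])
        assert c.values[0] == pytest.approx(2.0)
        assert c.values[1] == pytest.approx(0.0)

    def test_zero_lag_equals_inverse_mean(self, rng):
        states = (rng.random(1000) < 0.3).astype(int)
        s = StateSeries(dt=0.5, states=states)
        c = fluorescence_autocorrelation(s, lags=[0.0])
        assert c.values[0] == pytest.approx(1.0 / s.mean, rel=1e-12)

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(5):
            n = int(rng.integers(50, 400))
            states = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            if states.sum() == 0:
                states[0] = 1
            s = StateSeries(dt=0.1, states=states)
            ks = sorted(set(rng.integers(0, n - 1, size=8).tolist()))
            c = fluorescence_autocorrelation(s, lags=np.array(ks) * 0.1)
            np.testing.assert_allclose(
                c.values, brute_force_g(states, ks), rtol=0, atol=1e-12)

    def test_decays_to_one_for_mixing_input(self):
        p = TelegraphParams(k_close=0.5, k_open=0.5, dt=0.1, n_steps=300_000,
                            seed=3)
        s = gen_telegraph(p)
        c = fluorescence_autocorrelation(s, max_lag=200.0)
        tail = c.values[c.lags > 50.0]
        assert np.all(np.abs(tail - 1.0) < 0.05)

    def test_symmetric_telegraph_matches_analytic_form(self):
        """For k_close = k_open = k, G(tau) = 1 + exp(-2 k tau)."""
        k = 0.2
        p = TelegraphParams(k_close=k, k_open=k, dt=0.05, n_steps=2_000_000,
                            seed=8)
        s = gen_telegraph(p)
        c = fluorescence_autocorrelation(s, max_lag=30.0)
        expected = 1.0 + np.exp(-2.0 * k * c.lags)
        # sampling envelope ~ (1+G)/sqrt(n_eff); generous uniform bound
        assert np.max(np.abs(c.values - expected)) < 0.03

    def test_error_contracts(self):
        z = StateSeries(dt=1.0, states=np.zeros(10, dtype=int))
        with pytest.raises(DegenerateSignalError):
            fluorescence_autocorrelation(z, lags=[0.0])
        s = StateSeries(dt=1.0, states=np.array([1, 0, 1]))
        with pytest.raises(LagError):
            fluorescence_autocorrelation(s, lags=[5.0])

    def test_n_pairs_decreasing_and_lag_grid(self):
        s = StateSeries(dt=0.5, states=np.tile([1, 1, 0], 200))
        c = fluorescence_autocorrelation(s)
        assert np.all(np.diff(c.n_pairs_per_lag) <= 0)
        assert c.lags[-1] <= s.duration / 10.0 + 1e-9
        grid = log_lag_grid(0.5, 30.0)
        assert grid[0] == 0.0 and np.all(np.diff(grid) > 0)


class TestHBondC:
    def test_always_intact_bond_is_flat_one(self):
        H = np.ones((100, 2), dtype=int)
        m = HBondExistenceMatrix(dt=0.1, existence=H)
        c = hbond_existence_autocorrelation(m, lags=[0.0, 0.5, 1.0])
        np.testing.assert_allclose(c.values, 1.0)

    def test_zero_lag_is_one_in_both_modes(self, rng):
        H = (rng.random((200, 3)) < 0.6).astype(int)
        H[0] = 1
        m = HBondExistenceMatrix(dt=1.0, existence=H)
        for mode in ("intermittent", "continuous"):
            c = hbond_existence_autocorrelation(m, mode=mode, lags=[0.0, 3.0])
            assert c.values[0] == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_both_modes(self, seed):
        rng = np.random.default_rng(seed)
        H = (rng.random((int(rng.integers(20, 120)), int(rng.integers(1, 4))))
             < 0.55).astype(int)
        if not H.any():
            H[0, 0] = 1
        m = HBondExistenceMatrix(dt=1.0, existence=H)
        ks = [0, 1, 2, 5]
        ks = [k for k in ks if k < H.shape[0]]
        for mode in ("intermittent", "continuous"):
            c = hbond_existence_autocorrelation(m, mode=mode,
                                                lags=np.array(ks, float))
            np.testing.assert_allclose(
                c.values, brute_force_c(H, ks, mode), rtol=0, atol=1e-12)

    def test_continuous_mode_non_increasing(self, rng):
        H = (rng.random((300, 4)) < 0.7).astype(int)
        H[0] = 1
        m = HBondExistenceMatrix(dt=1.0, existence=H)
        c = hbond_existence_autocorrelation(m, mode="continuous",
                                            lags=np.arange(0.0, 30.0))
        assert np.all(np.diff(c.values) <= 1e-12)

    def test_markov_bond_matches_conditional_probability(self):
        from looplab.synthetic_data import HBondSeriesParams, gen_hbond_series
        kb, kr = 0.05, 0.075
        p = HBondSeriesParams(k_break=kb, k_reform=kr, n_bonds=20, dt=0.2,
                              n_steps=100_000, seed=21)
        m = gen_hbond_series(p)
        c = hbond_existence_autocorrelation(m, max_lag=80.0)
        pinf = kr / (kb + kr)
        expected = pinf + (1 - pinf) * np.exp(-(kb + kr) * c.lags)
        assert np.max(np.abs(c.values - expected)) < 0.02

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            HBondExistenceMatrix(dt=1.0, existence=np.zeros((5, 0)))
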