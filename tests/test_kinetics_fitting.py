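import numpy as np
import pytest

from looplab.correlation import CorrelationCurve, fluorescence_autocorrelation
from looplab.errors import InputError, NoRelaxationError, ParameterError
from looplab.kinetics_fitting import (
    derive_times,
    experimental_closing_rates,
    fit_hbond_lifetime,
    fit_multiexp,
    fit_powerlaw,
    fit_two_state,
    invert_times,
    load_labelled_time_constants,
    split_half_errors,
)
from looplab.synthetic_data import TelegraphParams, gen_telegraph


def _curve(lags, values, kind="fluorescence_G", mean=0.5, dt=None):
    lags = np.asarray(lags, float)
    return CorrelationCurve(
        lags=lags, values=np.asarray(values, float), kind=kind,
        mean_signal=mean, n_pairs_per_lag=np.arange(lags.size, 0, -1),
        source_length=float(lags[-1] * 10),
        dt=dt if dt is not None else float(lags[0] if lags[0] > 0 else lags[1]),
    )


class TestDeriveTimes:
    def test_symmetric_equilibrium(self):
        tau_c, tau_o, frac = derive_times(1.0, 15.0)
        assert tau_c == pytest.approx(30.0)
        assert tau_o == pytest.approx(30.0)
        assert frac == pytest.approx(0.5)

    def test_printed_row_consistency(self):
        """K = 0.4227, tau_r = 14.41 ns reproduces tau_c = 20.5, tau_o = 48.5."""
        K, tau_r = invert_times(20.5, 48.5)
        assert K == pytest.approx(0.4227, abs=2e-4)
        assert tau_r == pytest.approx(14.41, abs=0.01)
        tau_c, tau_o, _ = derive_times(K, tau_r)
        assert tau_c == pytest.approx(20.5, rel=1e-12)
        assert tau_o == pytest.approx(48.5, rel=1e-12)

    def test_round_trip_is_identity(self, rng):
        for _ in range(20):
            K = float(rng.uniform(0.05, 20))
            tau_r = float(rng.uniform(0.1, 500))
            tau_c, tau_o, _ = derive_times(K, tau_r)
            K2, tau_r2 = invert_times(tau_c, tau_o)
            assert K2 == pytest.approx(K, rel=1e-12)
            assert tau_r2 == pytest.approx(tau_r, rel=1e-12)

    def test_rate_additivity_invariant(self, rng):
        for _ in range(10):
            K = float(rng.uniform(0.1, 10))
            tau_r = float(rng.uniform(1, 100))
            tau_c, tau_o, frac = derive_times(K, tau_r)
            assert 1 / tau_r == pytest.approx(1 / tau_c + 1 / tau_o, rel=1e-9)
            assert frac == pytest.approx(tau_c / (tau_c + tau_o), rel=1e-9)

    def test_domain_checks(self):
        with pytest.raises(ParameterError):
            derive_times(-1.0, 5.0)
        with pytest.raises(ParameterError):
            derive_times(1.0, 0.0)


class TestTwoStateFit:
    def test_exact_curve_recovered(self):
        lags = np.linspace(6, 300, 60)
        vals = 1.0 + 0.5 * np.exp(-lags / 30.0)
        fit = fit_two_state(_curve(lags, vals))
        assert fit.K == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_r == pytest.approx(30.0, rel=1e-6)

    def test_flat_curve_raises_no_relaxation(self):
        lags = np.linspace(6, 300, 30)
        with pytest.raises(NoRelaxationError):
            fit_two_state(_curve(lags, np.ones_like(lags)))

    def test_telegraph_recovery_within_ten_percent(self):
        p = TelegraphParams(k_close=1 / 50.0, k_open=1 / 80.0, dt=0.1,
                            n_steps=2_000_000, seed=42)
        s = gen_telegraph(p)
        c = fluorescence_autocorrelation(s, max_lag=600.0)
        fit = fit_two_state(c)
        assert fit.tau_c == pytest.approx(50.0, rel=0.1)
        assert fit.tau_o == pytest.approx(80.0, rel=0.1)
        assert 1 / fit.tau_r == pytest.approx(1 / fit.tau_c + 1 / fit.tau_o,
                                              rel=1e-9)

    def test_k_convention_switch(self):
        lags = np.linspace(6, 300, 60)
        vals = 1.0 + 0.5 * np.exp(-lags / 30.0)
        fit = fit_two_state(_curve(lags, vals), k_convention="closed_over_open")
        assert fit.K == pytest.approx(0.5, rel=1e-6)
        # derived times always use the open/closed convention internally
        assert fit.tau_c == pytest.approx(30.0 * 3.0, rel=1e-6)


class TestMultiExp:
    def test_three_component_synthetic_recovery(self):
        """Stretched (50 ps, beta 0.5) + 3 ns + 40 ns recovered within 2%."""
        lags = np.logspace(np.log10(0.003), np.log10(400), 250)
        vals = (1.0 + 0.3 * np.exp(-((lags / 0.05) ** 0.5))
                + 0.4 * np.exp(-lags / 3.0) + 0.4 * np.exp(-lags / 40.0))
        fit = fit_multiexp(_curve(lags, vals), n_ns_exponentials=2, g0=2.1)
        assert fit.stretched.amplitude == pytest.approx(0.3, rel=0.02)
        assert fit.stretched.tau_1 == pytest.approx(0.05, rel=0.02)
        assert fit.stretched.beta == pytest.approx(0.5, rel=0.02)
        assert fit.exponentials[0].tau == pytest.approx(3.0, rel=0.02)
        assert fit.exponentials[1].tau == pytest.approx(40.0, rel=0.02)
        assert fit.r_correlation > 0.999

    def test_pure_single_exponential_degenerates_gracefully(self):
        lags = np.logspace(np.log10(0.003), np.log10(100), 150)
        vals = 1.0 + 0.6 * np.exp(-lags / 8.0)
        fit = fit_multiexp(_curve(lags, vals), n_ns_exponentials=1, g0=1.6)
        # either the stretched term vanishes or it collapses onto beta ~ 1
        collapsed = fit.stretched.amplitude < 0.05 or fit.stretched.beta > 0.9
        assert collapsed
        taus = [fit.stretched.tau_1, fit.exponentials[0].tau]
        amps = [fit.stretched.amplitude, fit.exponentials[0].amplitude]
        # total amplitude and dominant tau are still correct
        assert sum(amps) == pytest.approx(0.6, rel=0.02)
        assert taus[int(np.argmax(amps))] == pytest.approx(8.0, rel=0.05)

    def test_auto_mode_selects_two_when_separated(self):
        lags = np.logspace(np.log10(0.003), np.log10(500), 220)
        vals = (1.0 + 0.2 * np.exp(-((lags / 0.03) ** 0.6))
                + 0.4 * np.exp(-lags / 4.0) + 0.4 * np.exp(-lags / 60.0))
        fit = fit_multiexp(_curve(lags, vals), n_ns_exponentials="auto", g0=2.0)
        assert len(fit.exponentials) == 2

    def test_relative_amplitudes_reported_as_percent(self):
        lags = np.logspace(np.log10(0.003), np.log10(100), 150)
        vals = 1.0 + 0.25 * np.exp(-((lags / 0.05) ** 0.7)) + 0.5 * np.exp(-lags / 10.0)
        fit = fit_multiexp(_curve(lags, vals), n_ns_exponentials=1, g0=2.0)
        assert fit.exponentials[0].relative_pct == pytest.approx(50.0, rel=0.05)


class TestHBondLifetime:
    def test_markov_bond_plateau_corrected_recovery(self):
        pinf = 0.4
        lags = np.logspace(-3, np.log10(80), 200)
        vals = pinf + (1 - pinf) * np.exp(-lags / 10.0)
        fit = fit_hbond_lifetime(_curve(lags, vals, kind="hbond_C"))
        assert fit.lifetime_ns == pytest.approx(10.0, rel=0.05)
        assert fit.baseline == pytest.approx(pinf, abs=0.02)

    def test_two_population_fixture_recovers_slow_rate(self):
        lags = np.logspace(-3, np.log10(120), 220)
        vals = (0.2 + 0.3 * np.exp(-((lags / 0.02) ** 0.6))
                + 0.5 * np.exp(-lags / 25.0))
        fit = fit_hbond_lifetime(_curve(lags, vals, kind="hbond_C"))
        assert fit.lifetime_ns == pytest.approx(25.0, rel=0.1)

    def test_always_intact_bond_raises(self):
        lags = np.logspace(-2, 2, 60)
        with pytest.raises(NoRelaxationError):
            fit_hbond_lifetime(_curve(lags, np.ones_like(lags), kind="hbond_C"))


class TestPowerLaw:
    def test_exact_square_law(self):
        pts = [(n, n ** -2.0) for n in (5, 10, 20, 40)]
        fit = fit_powerlaw(pts)
        assert fit.exponent == pytest.approx(-2.0, abs=1e-12)

    def test_three_points_match_closed_form_ols(self):
        pts = [(4.0, 2.0), (9.0, 1.1), (25.0, 0.3)]
        x = np.log([p[0] for p in pts])
        y = np.log([p[1] for p in pts])
        slope = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sum((x - x.mean()) ** 2))
        fit = fit_powerlaw(pts)
        assert fit.exponent == pytest.approx(slope, rel=1e-12)

    def test_scale_equivariance(self):
        pts = [(8.0, 0.5), (16.0, 0.2), (32.0, 0.07), (64.0, 0.03)]
        f1 = fit_powerlaw(pts)
        f2 = fit_powerlaw([(n, 100.0 * k) for n, k in pts])
        assert f2.exponent == pytest.approx(f1.exponent, rel=1e-12)
        assert f2.prefactor == pytest.approx(100.0 * f1.prefactor, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_powerlaw([(10.0, 1.0), (20.0, 0.5)])

    def test_packaged_table_loads_and_filters(self):
        df = load_labelled_time_constants()
        assert list(df["n_peptide_bonds"]) == [4, 6, 10, 14, 18, 24, 30]
        rates = experimental_closing_rates(n_min=10)
        assert len(rates) == 5
        assert rates[0] == (10.0, pytest.approx(1 / 20.5))


class TestSplitHalf:
    def test_identical_halves_give_zero(self):
        series = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        out = split_half_errors(series, lambda h: float(np.sum(h)))
        assert out["sigma"] == 0.0

    def test_two_point_sample_standard_deviation(self):
        series = np.array([10.0, 10.0, 12.0, 12.0])
        out = split_half_errors(series, lambda h: float(h.mean()))
        assert out["sigma"] == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_consistent_with_replica_spread_for_telegraph(self):
        """Split-half sigma of the open fraction ~ replica-to-replica spread."""
        def analysis(s):
            return float(np.mean(s.states if hasattr(s, "states") else s))

        p = TelegraphParams(k_close=0.05, k_open=0.05, dt=0.5,
                            n_steps=200_000, seed=0)
        sigmas = []
        replica_means = []
        for seed in range(12):
            s = gen_telegraph(TelegraphParams(k_close=0.05, k_open=0.05,
                                              dt=0.5, n_steps=200_000,
                                              seed=seed))
            sigmas.append(split_half_errors(s, analysis)["sigma"])
            replica_means.append(analysis(s))
        spread = np.std(replica_means, ddof=1)
        med_sigma = np.median(sigmas)
        assert med_sigma == pytest.approx(spread, rel=1.0)  # within factor 2
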