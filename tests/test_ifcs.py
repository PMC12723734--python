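import numpy as np
import pytest

from tabsr import ifcs, simulate

from .conftest import isolated_site_movie, make_movie


class TestPixelACF:
    def test_alternating_trace_hand_value(self):
        """Trace [2,0,2,0,2,0]: mean 1, C2(1) = -1, G = -1/mean^2 = -1."""
        data = np.array([2, 0, 2, 0, 2, 0], dtype=float)[:, None, None] * np.ones((1, 2, 2))
        m = make_movie(data)
        _, g, valid = ifcs.pixel_acf(m, np.array([1]))
        np.testing.assert_allclose(g[0], -1.0)
        assert valid.all()

    def test_constant_trace_gives_zero(self):
        m = make_movie(np.full((10, 2, 2), 3.0))
        _, g, valid = ifcs.pixel_acf(m, np.array([1, 2]))
        np.testing.assert_allclose(g, 0.0)
        assert valid.all()

    def test_zero_mean_trace_flagged_invalid(self):
        data = np.zeros((10, 2, 2))
        data[:, 0, 0] = 1.0
        m = make_movie(data)
        _, g, valid = ifcs.pixel_acf(m, np.array([1]))
        assert valid[0, 0]
        assert not valid[1, 1]
        assert np.isnan(g[0, 1, 1])

    def test_telegraph_correlation_time(self):
        """A two-state telegraph emitter's ACF decays with the closed-form
        Markov correlation time -1/ln(1 - p_on_off - p_off_on)."""
        m, state = simulate.simulate_blinking_emitter(
            n_frames=120_000, fov_px=(8, 8), position_px=(3.5, 3.5),
            photons_per_frame=500.0, noise=False, seed=5,
        )
        lags = np.arange(1, 6)
        _, g, _ = ifcs.pixel_acf(m, lags)
        gc = g[:, 4, 4]
        tau_frames = -1.0 / np.polyfit(lags, np.log(gc), 1)[0]
        p_off_on = 1 / 3.0
        p_on_off = p_off_on * 0.3 / 0.7
        expected = -1.0 / np.log(1 - p_off_on - p_on_off)
        assert abs(tau_frames - expected) / expected < 0.10

    def test_lag_bound(self):
        m = make_movie(np.ones((10, 2, 2)))
        with pytest.raises(ValueError):
            ifcs.pixel_acf(m, np.array([10]))


class TestAverageSegments:
    def test_identical_segments_have_zero_sem(self):
        g = np.ones((3, 2, 2))
        stack = ifcs.average_segments([g, g, g], np.array([2.5, 5.0, 7.5]), 2.5, 46.0)
        np.testing.assert_allclose(stack.sem, 0.0)
        assert stack.n_segments == 3

    def test_two_segments_hand_values(self):
        """G = 0.9 and 1.1 in two segments: mean 1.0, SEM 0.1."""
        g1 = np.full((1, 1, 1), 0.9)
        g2 = np.full((1, 1, 1), 1.1)
        stack = ifcs.average_segments([g1, g2], np.array([2.5]), 2.5, 46.0)
        assert np.isclose(stack.G[0, 0, 0], 1.0)
        assert np.isclose(stack.sem[0, 0, 0], 0.1)

    def test_six_segments_recorded(self, rng):
        gs = [rng.random((4, 2, 2)) for _ in range(6)]
        stack = ifcs.average_segments(gs, np.arange(1, 5) * 2.5, 2.5, 46.0)
        assert stack.n_segments == 6

    def test_single_segment_sem_flagged(self):
        stack = ifcs.average_segments([np.ones((2, 1, 1))], np.array([1.0, 2.0]), 2.5, 46.0)
        assert np.all(np.isnan(stack.sem))


def _record(G, sem=None, lags=None):
    n = len(G)
    return ifcs.ACFRecord(
        pixel=(0, 0),
        lags_ms=np.arange(1, n + 1) * 2.5 if lags is None else lags,
        G=np.asarray(G, dtype=float),
        sem=np.full(n, 0.01) if sem is None else sem,
        n_segments=6,
    )


class TestSNR:
    def test_amplitude_over_tail_std(self):
        """Amplitude 1.0 over tail std 0.1 gives SNR exactly 10, which the
        strict > 10 gate excludes."""
        tail = np.array([0.1, -0.1, 0.1, -0.1, 0.1])  # std = 0.1 (population)
        g = np.concatenate([[1.0, 1.0, 1.0], [0.5, 0.3], tail])
        snr = ifcs.estimate_snr(_record(g))
        assert np.isclose(snr, 1.0 / np.std(tail))
        assert np.isclose(snr, 10.0, rtol=0.03)
        assert not (snr > 10.0) or snr < 10.5  # boundary lies at the gate

    def test_flat_zero_acf_gives_zero(self):
        assert ifcs.estimate_snr(_record(np.zeros(10))) == 0.0

    def test_strong_acf_included(self):
        tail = np.array([0.05, -0.05, 0.05, -0.05, 0.05])
        g = np.concatenate([[2.0, 2.0, 2.0], [1.0, 0.5], tail])
        snr = ifcs.estimate_snr(_record(g))
        assert np.isclose(snr, 2.0 / np.std(tail))
        assert snr > 10.0

    def test_zero_tail_std_is_inf(self):
        g = np.concatenate([[1.0, 1.0, 1.0], np.zeros(7)])
        assert ifcs.estimate_snr(_record(g)) == np.inf

    def test_too_few_lags(self):
        with pytest.raises(ValueError):
            ifcs.estimate_snr(_record(np.ones(5)))


class TestLagGrid:
    def test_monotone_unique_integers(self):
        lags = ifcs.make_lag_grid(6000)
        assert lags.dtype.kind == "i"
        assert np.all(np.diff(lags) > 0)
        assert lags[0] == 1
        assert lags[-1] <= 1500

    def test_short_trace_all_linear(self):
        lags = ifcs.make_lag_grid(20)
        np.testing.assert_array_equal(lags, np.arange(1, 6))


class TestFitACF:
    def test_noiseless_self_consistency(self):
        """Fitting the model to its own noiseless curve recovers all
        parameters to < 1%."""
        lags = ifcs.make_lag_grid(6000) * 2.5
        truth = dict(G0=0.5, tau_fast_ms=20.0, tau_slow_ms=400.0,
                     f_fast=0.6, f_slow=0.4, G_inf=0.0)
        g = ifcs.acf_model(lags, **truth)
        rec = ifcs.ACFRecord((0, 0), lags, g, np.full(len(g), 1e-4), 6)
        fit = ifcs.fit_acf(rec, "two_component")
        assert fit.converged
        for name, val in truth.items():
            if val != 0:
                assert abs(getattr(fit, name) - val) / val < 0.01, name

    def test_relabeling_enforces_tau_order(self):
        fit = ifcs.FitResult(
            G0=1.0, tau_fast_ms=400.0, tau_slow_ms=20.0, f_fast=0.3, f_slow=0.7,
            G_inf=0.0, reduced_chi2=1.0, snr=20.0, converged=True,
        )
        assert fit.tau_fast_ms == 20.0
        assert fit.f_fast == 0.7

    def test_one_component_fails_on_two_component_curve(self):
        """A single-exponential fit to a well-separated two-component curve
        leaves reduced chi2 >> 1; the two-component fit achieves ~0."""
        lags = ifcs.make_lag_grid(6000) * 2.5
        g = ifcs.acf_model(lags, 0.5, 20.0, 400.0, 0.6, 0.4, 0.0)
        sem = np.full(len(g), 0.005)  # 1% of amplitude
        rec = ifcs.ACFRecord((0, 0), lags, g, sem, 6)
        fit1 = ifcs.fit_acf(rec, "one_component")
        fit2 = ifcs.fit_acf(rec, "two_component")
        assert fit1.reduced_chi2 > 3 * max(fit2.reduced_chi2, 1.0)

    def test_fast_weight_fraction_definition(self):
        fit = ifcs.FitResult(1.0, 20.0, 400.0, 0.25, 0.5, 0.0, 1.0, 20.0, True)
        assert np.isclose(fit.fast_weight_fraction, 0.25 / 0.75)


class TestSimulatorRecovery:
    def test_acf_amplitude_scales_inversely_with_occupancy(self):
        """At fixed kinetics, G amplitude ~ 1/occupancy over three occupancy
        levels (isolated-site scenario, fixed seed)."""
        lags = ifcs.make_lag_grid(30_000, max_lag=1500)
        products = []
        for rate in (0.6, 1.8, 5.4):
            movie, kin, centers = isolated_site_movie(rate, seed=7)
            _, g, _ = ifcs.pixel_acf(movie, lags)
            gm = np.mean([g[:, r, c] for r, c in centers], axis=0)
            products.append(gm[:3].mean() * kin.mean_occupancy())
        assert max(products) / min(products) < 1.25

    def test_simulated_acf_matches_analytic_reference_shape(self):
        """Mean isolated-site ACF correlates > 0.98 with the analytic
        two-component reference at the simulator's parameters."""
        lags = ifcs.make_lag_grid(30_000, max_lag=1500)
        movie, kin, centers = isolated_site_movie(1.8, seed=7)
        lags_ms, g, _ = ifcs.pixel_acf(movie, lags)
        gm = np.mean([g[:, r, c] for r, c in centers], axis=0)
        ref = simulate.expected_acf(kin, kin.mean_occupancy(), lags_ms)
        assert np.corrcoef(gm, ref)[0, 1] > 0.98


class TestBuildMaps:
    def _fits(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"row": 0, "col": 0, "snr": 15.0, "G0": 1.0, "tau_fast_ms": 20.0,
                 "tau_slow_ms": 400.0, "f_fast": 0.5, "f_slow": 0.5, "G_inf": 0.0,
                 "fast_weight_fraction": 0.5, "reduced_chi2": 1.0, "converged": True},
                {"row": 0, "col": 1, "snr": 8.0, "G0": 1.0, "tau_fast_ms": 25.0,
                 "tau_slow_ms": 300.0, "f_fast": 0.5, "f_slow": 0.5, "G_inf": 0.0,
                 "fast_weight_fraction": 0.5, "reduced_chi2": 1.0, "converged": True},
                {"row": 1, "col": 1, "snr": 30.0, "G0": 1.0, "tau_fast_ms": 25.0,
                 "tau_slow_ms": 300.0, "f_fast": 0.5, "f_slow": 0.5, "G_inf": 0.0,
                 "fast_weight_fraction": 0.5, "reduced_chi2": 1.0, "converged": False},
            ]
        )

    def test_gating_and_convergence_mask(self):
        maps = ifcs.build_maps(self._fits(), (2, 2), snr_gate=10.0)
        assert maps.valid[0, 0]
        assert not maps.valid[0, 1]  # below gate
        assert not maps.valid[1, 1]  # non-converged
        assert not maps.valid[1, 0]  # never fit
        assert np.isnan(maps.tau_slow_ms[0, 1])
        assert np.isnan(maps.tau_fast_ms[1, 0])

    def test_all_below_gate_fully_masked(self):
        maps = ifcs.build_maps(self._fits(), (2, 2), snr_gate=100.0)
        assert not maps.valid.any()

    def test_fraction_map_in_unit_interval(self):
        maps = ifcs.build_maps(self._fits(), (2, 2), snr_gate=10.0)
        vals = maps.fast_weight_fraction[maps.valid]
        assert np.all((vals >= 0) & (vals <= 1))
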