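"""Finite QIF networks: heterogeneity sampling, rates, spectra."""

import numpy as np
import pytest
from scipy import stats

import gammalock as gl
from gammalock.errors import InsufficientDataError, InvalidParameterError
from gammalock.params import PopulationParams, SynapticCouplings

UNCOUPLED = SynapticCouplings(j_ee=0, j_ei=0, j_ie=0, j_ii=0, tau_s=1.0)


class TestLorentzianSampling:
    def test_quantile_grid_median_is_center(self):
        v = gl.sample_lorentzian(-5.0, 1.0, 5001)
        assert np.median(v) == pytest.approx(-5.0, abs=1e-12)

    def test_zero_width_is_degenerate(self):
        assert np.all(gl.sample_lorentzian(-5.0, 0.0, 100) == -5.0)

    def test_random_draws_match_cauchy_cdf(self):
        # oracle: closed-form sub-threshold fraction (Cauchy CDF at 0)
        v = gl.sample_lorentzian(-5.0, 1.0, 10**5, mode="random", seed=42)
        frac = float(np.mean(v < 0))
        assert frac == pytest.approx(gl.fraction_non_oscillatory(-5.0, 1.0), abs=0.01)

    def test_random_reproducible(self):
        a = gl.sample_lorentzian(0.0, 2.0, 1000, mode="random", seed=7)
        b = gl.sample_lorentzian(0.0, 2.0, 1000, mode="random", seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("bad", [dict(half_width=-1.0), dict(count=0)])
    def test_invalid_arguments(self, bad):
        kw = dict(center=0.0, half_width=1.0, count=10)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            gl.sample_lorentzian(**kw)


class TestFractionNonOscillatory:
    def test_symmetric_center_gives_half(self):
        assert gl.fraction_non_oscillatory(0.0, 1.0) == pytest.approx(0.5)

    def test_matches_cauchy_cdf_numerically(self):
        for c, w in [(-5.0, 1.0), (2.0, 0.5), (-1.0, 3.0)]:
            assert gl.fraction_non_oscillatory(c, w) == pytest.approx(
                stats.cauchy.cdf(0.0, loc=c, scale=w), abs=1e-10
            )

    def test_limit_large_positive_center(self):
        assert gl.fraction_non_oscillatory(1e8, 1.0) < 1e-7

    def test_invalid_width(self):
        with pytest.raises(InvalidParameterError):
            gl.fraction_non_oscillatory(0.0, 0.0)


class TestSpikingNetwork:
    def test_single_qif_period_closed_form(self):
        # tau dv/dt = eta + v^2 has period pi tau / sqrt(eta) at infinite cutoffs
        e1 = PopulationParams(tau=10.0, eta_bar=1.0, delta=0.0, size=1)
        i1 = PopulationParams(tau=10.0, eta_bar=-5.0, delta=0.0, size=1)
        raster, _ = gl.simulate_spiking_network(e1, i1, UNCOUPLED,
                                                duration=200.0, step=1e-3)
        isi = np.diff(raster.split()[0])
        assert isi.size >= 4
        assert np.mean(isi) == pytest.approx(np.pi * 10.0, rel=0.01)

    def test_all_subthreshold_network_is_silent(self):
        pop = PopulationParams(tau=10.0, eta_bar=-5.0, delta=0.0, size=200)
        raster, trace = gl.simulate_spiking_network(pop, pop, UNCOUPLED,
                                                    duration=100.0)
        assert raster.n_spikes == 0
        assert np.all(trace.r_e == 0) and np.all(trace.r_i == 0)

    def test_rates_nonnegative_and_seeded_runs_identical(self):
        b = gl.figure_preset("fig2_ping")
        from dataclasses import replace
        e = replace(b.e_params, size=300)
        i = replace(b.i_params, size=300)
        r1, t1 = gl.simulate_spiking_network(e, i, b.couplings, 10.0, 0.0,
                                             duration=120.0, seed=5,
                                             heterogeneity="random")
        r2, t2 = gl.simulate_spiking_network(e, i, b.couplings, 10.0, 0.0,
                                             duration=120.0, seed=5,
                                             heterogeneity="random")
        assert np.all(t1.r_e >= 0) and np.all(t1.r_i >= 0)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.ids, r2.ids)


class TestEstimateRate:
    def _raster(self, times, ids, n_e=100, n_i=50, window=(0.0, 100.0)):
        return gl.SpikeRaster(times=np.asarray(times, float),
                              ids=np.asarray(ids, np.int64),
                              n_e=n_e, n_i=n_i, window=window)

    def test_empty_raster_gives_zero_trace(self):
        tr = gl.estimate_rate(self._raster([], []))
        assert np.all(tr.r_e == 0) and np.all(tr.r_i == 0)

    @pytest.mark.parametrize("bin_width", [0.25, 0.5, 2.0])
    @pytest.mark.parametrize("sigma", [0.0, 1.0])
    def test_count_conservation_exact(self, bin_width, sigma):
        tr = gl.estimate_rate(self._raster([12.3], [7]), bin_width, sigma)
        assert tr.r_e.sum() * tr.bin_width * 100 == pytest.approx(1.0, abs=1e-12)

    def test_constant_rate_recovered_within_counting_error(self):
        # homogeneous synthetic spikes: Poisson with rate rho per neuron
        rng = np.random.default_rng(11)
        rho, n, dur = 0.05, 200, 400.0
        total = rng.poisson(rho * n * dur)
        times = rng.uniform(0, dur, total)
        ids = rng.integers(0, n, total)
        tr = gl.estimate_rate(self._raster(times, ids, n_e=n, n_i=1,
                                           window=(0.0, dur)), 1.0)
        est = tr.r_e.mean()
        se = np.sqrt(rho / (n * dur))  # binomial counting oracle
        assert abs(est - rho) < 3 * se

    def test_invalid_bin(self):
        with pytest.raises(InvalidParameterError):
            gl.estimate_rate(self._raster([], []), bin_width=0.0)


class TestOscillationFrequency:
    def test_sinusoid_period_25ms_is_40hz(self):
        t = np.arange(0, 500, 0.5)
        f = gl.oscillation_frequency((t, 1 + 0.3 * np.sin(2 * np.pi * t / 25.0)))
        assert f == pytest.approx(40.0, abs=0.5)

    def test_constant_trace_has_no_peak(self):
        t = np.arange(0, 500, 0.5)
        assert gl.oscillation_frequency((t, np.ones_like(t))) is None

    def test_too_few_cycles_raises(self):
        t = np.arange(0, 60, 0.5)
        with pytest.raises(InsufficientDataError):
            gl.oscillation_frequency((t, np.sin(2 * np.pi * t / 25.0)))

    def test_ping_reduced_trace_in_gamma_band(self, ping_cycle):
        b = gl.figure_preset("fig2_ping")
        traj = gl.integrate_mf(ping_cycle.states[0], b.e_params, b.i_params,
                               b.couplings, 10.0, 0.0, duration=500.0)
        f = gl.oscillation_frequency((traj.t, traj.r_e))
        assert 30.0 <= f <= 150.0
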