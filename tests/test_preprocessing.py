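import numpy as np
import pytest

from balancesrm.preprocessing import (
    BETA_BINS,
    EMG_BINS,
    BinnedResponse,
    CorticalFeatures,
    ErspMatrix,
    beta_power,
    com_acceleration,
    ersp,
    integrate_bins,
    n1_features,
    normalize_emg,
    process_emg,
    savgol_velocity,
    wavelet_cycles,
)
from balancesrm.timeseries import TimeSeries

EPOCH_T = np.arange(-400.0, 1401.0)  # 1 kHz EMG epoch


def emg_epoch(values):
    return TimeSeries(values, 1000.0, -400.0)


class TestProcessEmg:
    def test_zero_in_zero_out(self):
        out = process_emg(emg_epoch(np.zeros(EPOCH_T.size)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_dc_rejected(self):
        c = 7.3
        out = process_emg(emg_epoch(np.full(EPOCH_T.size, c)))
        interior = out.values[200:-200]
        assert np.abs(interior).max() < 1e-6 * c

    def test_highpass_attenuation_10_vs_100_hz(self):
        """The zero-lag high-pass keeps 100 Hz and kills 10 Hz by >= 60 dB."""

        def envelope_power(freq):
            x = np.sin(2 * np.pi * freq * EPOCH_T / 1000.0)
            env = process_emg(emg_epoch(x)).values[300:-300]
            return np.mean(env**2)

        ratio_db = 10 * np.log10(envelope_power(100.0) / envelope_power(10.0))
        assert ratio_db >= 60.0

    def test_wrong_rate_rejected(self):
        with pytest.raises(ValueError):
            process_emg(TimeSeries(np.zeros(100), 500.0, -400.0))

    def test_zero_lag_preserves_pulse_symmetry(self):
        """A symmetric burst keeps its centre: no group delay from filtfilt.

        The carrier is phase-aligned to the burst centre so the rectified
        signal is itself symmetric about 300 ms.
        """
        t = EPOCH_T
        burst = np.cos(2 * np.pi * 120.0 * (t - 300.0) / 1000.0) * np.exp(
            -((t - 300.0) ** 2) / (2 * 40.0**2)
        )
        env = process_emg(emg_epoch(burst)).values
        centroid = float((t * env).sum() / env.sum())
        assert abs(centroid - 300.0) <= 1.0
        # mirror symmetry about the centre within the burst support
        i0 = int(300.0 - t[0])
        d = np.arange(1, 200)
        np.testing.assert_allclose(env[i0 + d], env[i0 - d], atol=1e-6 * env.max())

    def test_envelope_essentially_nonnegative(self):
        """On a realistic amplitude-modulated surrogate the normalized
        envelope stays above -1e-3 (the final low-pass rings only weakly)."""
        from scipy import signal as sps

        rng = np.random.default_rng(0)
        sos = sps.butter(4, [60, 250], btype="bandpass", fs=1000, output="sos")
        carrier = sps.sosfilt(sos, rng.normal(0, 1, EPOCH_T.size))
        mod = (
            0.2
            + np.exp(-((EPOCH_T - 150.0) ** 2) / (2 * 40.0**2))
            + 0.5 * np.exp(-((EPOCH_T - 280.0) ** 2) / (2 * 60.0**2))
        )
        env = process_emg(emg_epoch(carrier * mod)).values
        assert env.min() >= -1e-3 * env.max()


class TestNormalizeEmg:
    def test_single_trial_max_becomes_one(self):
        tr = emg_epoch(np.full(EPOCH_T.size, 0.4))
        (out,) = normalize_emg([tr])
        assert out.values.max() == 1.0

    def test_shared_group_divisor(self):
        a = TimeSeries([0.0, 2.0], 1000.0)
        b = TimeSeries([0.0, 4.0], 1000.0)
        oa, ob = normalize_emg([a, b], groups=["g", "g"])
        assert oa.values.max() == 0.5 and ob.values.max() == 1.0

    def test_independent_groups(self):
        a = TimeSeries([0.0, 2.0], 1000.0)
        b = TimeSeries([0.0, 4.0], 1000.0)
        oa, ob = normalize_emg([a, b], groups=["left", "right"])
        assert oa.values.max() == 1.0 and ob.values.max() == 1.0

    def test_idempotent(self):
        a = TimeSeries([0.0, 0.5, 1.0], 1000.0)
        (out,) = normalize_emg(normalize_emg([a]))
        np.testing.assert_array_equal(out.values, a.values)

    def test_all_zero_group_rejected(self):
        with pytest.raises(ValueError):
            normalize_emg([TimeSeries([0.0, 0.0], 1000.0)])


class TestIntegrateBins:
    def test_constant_envelope(self):
        env = emg_epoch(np.ones(EPOCH_T.size))
        out = integrate_bins(env, [(75.0, 200.0)])
        assert out.values[0] == pytest.approx(125.0, rel=1e-12)

    def test_zero_envelope(self):
        out = integrate_bins(emg_epoch(np.zeros(EPOCH_T.size)), EMG_BINS)
        assert out.values == (0.0, 0.0, 0.0)

    def test_triangle_area(self):
        # triangular pulse of height 1 spanning exactly 200-300 ms -> area 50
        vals = np.interp(EPOCH_T, [200.0, 250.0, 300.0], [0.0, 1.0, 0.0], left=0, right=0)
        out = integrate_bins(emg_epoch(vals), [(200.0, 300.0)])
        assert out.values[0] == pytest.approx(50.0, rel=1e-9)

    def test_bin_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            integrate_bins(emg_epoch(np.ones(EPOCH_T.size)), [(1300.0, 1500.0)])

    def test_bins_must_ascend(self):
        with pytest.raises(ValueError):
            BinnedResponse(((0.0, 100.0), (50.0, 150.0)), (1.0, 2.0))


class TestSavgolVelocity:
    def test_linear_signal(self):
        c = 3.4  # cm per sample-time unit
        t = np.arange(200) / 120.0
        d = TimeSeries(c * t, 120.0, 0.0)
        v = savgol_velocity(d)
        np.testing.assert_allclose(v.values[30:-30], c, rtol=1e-9)

    def test_constant_signal(self):
        v = savgol_velocity(TimeSeries(np.full(200, 2.0), 120.0))
        np.testing.assert_allclose(v.values, 0.0, atol=1e-9)

    def test_cubic_polynomial_exact(self):
        t = np.arange(300) / 120.0
        d = TimeSeries(0.5 * t**3 - 2.0 * t**2 + 3.0 * t - 1.0, 120.0)
        v = savgol_velocity(d)
        expected = 1.5 * t**2 - 4.0 * t + 3.0
        interior = slice(25, -25)
        np.testing.assert_allclose(v.values[interior], expected[interior], rtol=1e-9, atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            savgol_velocity(TimeSeries(np.zeros(40), 120.0))


class TestComAcceleration:
    def grid(self, vals):
        return TimeSeries(vals, 120.0, -400.0)

    def test_zero_inputs(self):
        z = self.grid(np.zeros(100))
        out = com_acceleration(z, 70.0, z)
        assert not out.values.any()

    def test_force_over_mass_in_cm(self):
        grf = self.grid(np.full(100, 70.0))  # N
        out = com_acceleration(grf, 70.0, self.grid(np.zeros(100)))
        np.testing.assert_allclose(out.values, 100.0)  # 1 m/s^2 = 100 cm/s^2

    def test_platform_term_sign(self):
        plat = self.grid(np.full(100, 0.23 * 981.0))
        out = com_acceleration(self.grid(np.zeros(100)), 70.0, plat)
        np.testing.assert_allclose(out.values, -0.23 * 981.0)

    def test_nonpositive_mass_rejected(self):
        z = self.grid(np.zeros(100))
        with pytest.raises(ValueError):
            com_acceleration(z, 0.0, z)


class TestN1Features:
    def cz(self, values, fs=500.0):
        return TimeSeries(values, fs, -500.0)

    def test_gaussian_trough(self):
        t = np.arange(-500.0, 2001.0, 2.0)
        vals = -5.0 * np.exp(-((t - 150.0) ** 2) / (2 * 10.0**2))
        f = n1_features(self.cz(vals))
        assert f.n1_amplitude == pytest.approx(-5.0, abs=1e-6)
        assert f.n1_latency == pytest.approx(150.0)

    def test_constant_epoch_ties_to_window_start(self):
        t = np.arange(-500.0, 2001.0, 2.0)
        f = n1_features(self.cz(np.full(t.size, 3.0)))
        assert f.n1_amplitude == 0.0
        assert f.n1_latency == 100.0

    def test_baseline_subtraction(self):
        # +10 uV baseline with an absolute -20 uV trough at 137 ms -> -30 uV
        t = np.arange(-500.0, 2001.0, 1.0)
        vals = np.full(t.size, 10.0)
        vals[(t >= 130) & (t <= 144)] = -20.0
        f = n1_features(TimeSeries(vals, 1000.0, -500.0))
        assert f.n1_amplitude == pytest.approx(-30.0)
        assert f.n1_latency == pytest.approx(130.0)  # earliest minimum sample

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            n1_features(TimeSeries(np.zeros(100), 500.0, 0.0))


class TestErsp:
    def test_cycle_counts_at_band_edges(self):
        assert wavelet_cycles(6.0) == 3.0
        assert wavelet_cycles(50.0) == 23.0

    def test_baseline_mean_zero_by_construction(self):
        rng = np.random.default_rng(1)
        epoch = TimeSeries(rng.normal(0, 1, 1251), 500.0, -500.0)
        mat = ersp(epoch)
        bmask = (mat.times >= -400.0) & (mat.times <= -100.0)
        np.testing.assert_allclose(mat.power[:, bmask].mean(axis=1), 0.0, atol=1e-9)

    def test_burst_localised_in_time_and_frequency(self):
        rng = np.random.default_rng(2)
        t = np.arange(-500.0, 2001.0, 2.0)
        x = rng.normal(0, 1, t.size)
        burst = (t >= 100) & (t <= 300)
        x[burst] += 4.0 * np.sin(2 * np.pi * 20.0 * t[burst] / 1000.0)
        mat = ersp(TimeSeries(x, 500.0, -500.0))
        f20 = int(np.argmin(np.abs(mat.freqs - 20.0)))
        t_at_max = mat.times[int(np.argmax(mat.power[f20]))]
        assert 100.0 <= t_at_max <= 300.0

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            ersp(TimeSeries(np.zeros(100), 500.0, -100.0))


class TestBetaPower:
    def make_mat(self, power_value):
        freqs = np.arange(6.0, 51.0)
        times = np.arange(-370.0, 1001.0, 2.0)
        power = np.full((freqs.size, times.size), power_value)
        return ErspMatrix(freqs, times, power)

    def test_uniform_zero(self):
        trace, bins = beta_power(self.make_mat(0.0))
        assert not trace.values.any()
        assert bins.values == (0.0, 0.0, 0.0)

    def test_uniform_constant(self):
        trace, bins = beta_power(self.make_mat(3.0))
        np.testing.assert_allclose(trace.values, 3.0)
        assert bins.values == (3.0, 3.0, 3.0)

    def test_band_must_be_sampled(self):
        freqs = np.array([6.0, 8.0, 10.0])
        times = np.arange(0.0, 600.0, 2.0)
        mat = ErspMatrix(freqs, times, np.zeros((3, times.size)))
        with pytest.raises(ValueError):
            beta_power(mat)

    def test_burst_elevates_mid_bin(self):
        """A 20 Hz burst at 100-300 ms lifts the 150-250 ms beta bin."""
        rng = np.random.default_rng(3)
        t = np.arange(-500.0, 2001.0, 2.0)
        mats = []
        for _ in range(20):
            x = rng.normal(0, 1, t.size)
            burst = (t >= 100) & (t <= 300)
            x[burst] += 3.0 * np.sin(2 * np.pi * 20.0 * t[burst] / 1000.0)
            mats.append(ersp(TimeSeries(x, 500.0, -500.0)))
        avg = ErspMatrix(mats[0].freqs, mats[0].times, np.mean([m.power for m in mats], axis=0))
        trace, bins = beta_power(avg)
        pre = trace.values[trace.times < 0].mean()
        assert bins.values[1] > pre
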