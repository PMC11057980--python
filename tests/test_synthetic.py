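import numpy as np
import pytest

from balancesrm import (
    MAGNITUDES,
    ComKinematics,
    NoiseModel,
    PerturbationMagnitude,
    PlantParams,
    TimeSeries,
    accel_phase_duration,
    com_response,
    generate_dataset,
    generate_trial,
    platform_profile,
)
from balancesrm.experiments import reference_hsrm_truth
from balancesrm.synthetic import G_CM, TrialTruth, draw_participant_truth


class TestPlatformProfile:
    def test_small_magnitude_exact(self):
        prof = platform_profile(MAGNITUDES["small"])
        assert abs(prof.d.values[-1]) == pytest.approx(7.7, rel=1e-9)
        assert np.abs(prof.v.values).max() == pytest.approx(16.0, rel=1e-9)
        assert np.abs(prof.a.values).max() == pytest.approx(0.23 * G_CM, rel=1e-9)

    @pytest.mark.parametrize("label", list(MAGNITUDES))
    def test_all_magnitudes_exact(self, label):
        mag = MAGNITUDES[label]
        prof = platform_profile(mag)
        assert abs(prof.d.values[-1]) == pytest.approx(mag.displacement, rel=1e-9)
        assert np.abs(prof.v.values).max() == pytest.approx(mag.peak_velocity, rel=1e-9)

    def test_starts_from_rest_at_onset(self):
        prof = platform_profile(MAGNITUDES["small"])
        i0 = int(round(-prof.t0 * prof.fs / 1000.0))
        assert prof.v.values[i0] == 0.0
        assert prof.d.values[i0] == 0.0
        assert not prof.v.values[:i0].any()

    def test_accel_phase_duration_closed_form(self):
        dur = accel_phase_duration(MAGNITUDES["small"])
        assert dur == pytest.approx(16.0 / (0.23 * 981.0), rel=1e-12)
        assert dur == pytest.approx(0.0709, abs=5e-5)

    def test_infeasible_magnitude_rejected(self):
        with pytest.raises(ValueError):
            PerturbationMagnitude(0.5, 50.0, 0.2)


class TestComResponse:
    def make_platform(self, a_vals, fs=1000.0, t0=-400.0):
        n = a_vals.size
        z = TimeSeries(np.zeros(n), fs, t0)
        return ComKinematics(z, z.with_values(np.zeros(n)), z.with_values(a_vals))

    def test_zero_platform_zero_response(self):
        com = com_response(self.make_platform(np.zeros(500)))
        assert not com.d.values.any() and not com.a.values.any()

    def test_static_gain(self):
        """Steady forcing settles at -a0/K (platform frame)."""
        plant = PlantParams(effective_stiffness=20.0, damping=6.0)
        a0 = 50.0
        com = com_response(self.make_platform(np.full(6000, a0)), plant)
        assert com.d.values[-1] == pytest.approx(-a0 / 20.0, rel=1e-4)

    def test_impulse_response_matches_damped_oscillator(self):
        """One-sample impulse approximates the analytic damped response."""
        K, B = 20.0, 6.0
        fs = 1000.0
        n = 3000
        a = np.zeros(n)
        a[400] = -fs  # unit-area impulse of -a_platform
        com = com_response(self.make_platform(a, fs=fs), PlantParams(K, B))
        t = np.arange(n - 400) / fs
        wd = np.sqrt(K - (B / 2) ** 2)
        analytic = (1.0 / wd) * np.exp(-B / 2 * t) * np.sin(wd * t)
        np.testing.assert_allclose(com.d.values[400:], analytic, atol=2e-3)

    def test_sharp_transient_at_onset(self):
        com = com_response(platform_profile(MAGNITUDES["small"]))
        i0 = int(round(-com.t0 * com.fs / 1000.0))
        assert com.a.values[i0] == pytest.approx(0.23 * G_CM, rel=1e-9)
        assert not com.a.values[:i0].any()

    def test_unstable_plant_rejected(self):
        with pytest.raises(ValueError):
            PlantParams(effective_stiffness=-1.0, damping=1.0)


class TestGenerateTrial:
    def truth(self):
        draw = draw_participant_truth(np.random.default_rng(0))
        return TrialTruth(reference_hsrm_truth(), draw["cz"], draw["beta"])

    def test_noiseless_limit_is_bit_exact(self, small_com):
        tr = generate_trial(small_com, self.truth(), NoiseModel(0.0, 0.0, seed=5))
        clean = tr.noiseless()
        assert np.array_equal(tr.emg.values, clean["emg"].values)
        assert np.array_equal(tr.cz.values, clean["cz"].values)
        assert np.array_equal(tr.beta.values, clean["beta"].values)

    def test_same_seed_reproduces_trial(self, small_com):
        t1 = generate_trial(small_com, self.truth(), NoiseModel(0.02, 0.05, seed=9))
        t2 = generate_trial(small_com, self.truth(), NoiseModel(0.02, 0.05, seed=9))
        assert np.array_equal(t1.emg.values, t2.emg.values)
        assert np.array_equal(t1.cz.values, t2.cz.values)

    def test_noise_floor_calibration(self, small_com):
        """sigma0 = 0.05: std over flat (pre-onset) segments ~ 5% of peak.

        Measured on the unclipped beta trace (EMG clipping at zero halves
        the apparent std on flat segments).
        """
        truth = self.truth()
        tr = generate_trial(small_com, truth, NoiseModel(0.05, 0.0, seed=11))
        clean = tr.noiseless()["beta"]
        flat = tr.beta.times < 0
        assert flat.sum() >= 300
        resid = tr.beta.values[flat] - clean.values[flat]
        peak = np.abs(clean.values).max()
        assert np.std(resid) / peak == pytest.approx(0.05, rel=0.20)

    def test_emg_clipped_nonnegative(self, small_com):
        tr = generate_trial(small_com, self.truth(), NoiseModel(0.1, 0.1, seed=3))
        assert tr.emg.values.min() >= 0.0


class TestGenerateDataset:
    def test_default_design_counts(self):
        # full design is 17 x 3 x 8 = 408; verify the arithmetic on a
        # scaled-down call plus the default parameters themselves
        trials, manifest = generate_dataset(
            n_participants=2, trials_per_cell=3, base_seed=0
        )
        assert len(trials) == 2 * 3 * 3
        assert len(manifest["participants"]) == 2
        import inspect

        sig = inspect.signature(generate_dataset)
        assert sig.parameters["n_participants"].default == 17
        assert sig.parameters["trials_per_cell"].default == 8
        assert sig.parameters["n_participants"].default * 3 * sig.parameters[
            "trials_per_cell"
        ].default == 408

    def test_single_cell_dataset(self):
        trials, _ = generate_dataset(1, ["small"], 1, base_seed=4)
        assert len(trials) == 1

    def test_same_base_seed_identical_manifest_and_trials(self):
        t1, m1 = generate_dataset(2, ["small", "large"], 2, base_seed=77)
        t2, m2 = generate_dataset(2, ["small", "large"], 2, base_seed=77)
        assert m1 == m2
        for a, b in zip(t1, t2):
            assert np.array_equal(a.emg.values, b.emg.values)

    def test_second_loop_gain_scales_with_magnitude(self):
        _, manifest = generate_dataset(1, base_seed=2)
        cells = manifest["participants"]["P01"]["cells"]
        k = [cells[m]["truth"]["muscle"]["gains2"]["k_a"] for m in ("small", "medium", "large")]
        assert k[0] < k[1] < k[2]

    def test_truth_roundtrip_through_manifest(self):
        """Manifest truths regenerate the noiseless traces bit-exactly."""
        from balancesrm.forward import SRMParams
        from balancesrm.synthetic import make_com
        from balancesrm import reconstruct

        trials, manifest = generate_dataset(1, ["small"], 1, base_seed=8)
        tr = trials[0]
        truth_dict = manifest["participants"]["P01"]["cells"]["small"]["truth"]
        cz_params = SRMParams.from_dict(truth_dict["cz"])
        cz = reconstruct(cz_params, tr.com)
        assert np.array_equal(cz.values, tr.noiseless()["cz"].values)
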