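import numpy as np
import pytest

from balancesrm import (
    ComKinematics,
    FeedbackGains,
    LoopTiming,
    SRMParams,
    SRMSpec,
    TimeSeries,
    Variant,
    delay_shift,
    reconstruct,
    reconstruct_csrm,
    reconstruct_hsrm_cortical,
    reconstruct_hsrm_kin,
    reconstruct_msrm,
)

from .conftest import random_com
from .oracles import brute_reconstruct

FS = 1000.0


def com_impulse_a(n=500, t0=-100.0):
    """Kinematics with a unit acceleration impulse at t = 0, quiet before."""
    z = np.zeros(n)
    a = z.copy()
    a[int(-t0)] = 1.0
    return ComKinematics(
        TimeSeries(z, FS, t0), TimeSeries(z.copy(), FS, t0), TimeSeries(a, FS, t0)
    )


def at_ms(ts, t):
    return ts.values[int(round((t - ts.t0) * ts.fs / 1000.0))]


def com_constant(n=50, d=0.0, v=0.0, a=0.0):
    return ComKinematics(
        TimeSeries(np.full(n, d), FS, 0.0),
        TimeSeries(np.full(n, v), FS, 0.0),
        TimeSeries(np.full(n, a), FS, 0.0),
    )


class TestMsrm:
    def test_zero_gains_zero_output(self):
        out = reconstruct_msrm(com_constant(a=5.0), FeedbackGains(), LoopTiming(100.0))
        assert not out.values.any()

    def test_impulse_scaled_and_shifted(self):
        out = reconstruct_msrm(com_impulse_a(), FeedbackGains(k_a=0.5), LoopTiming(100.0))
        assert at_ms(out, 100.0) == 0.5
        assert out.values.sum() == 0.5

    def test_rectification_floor(self):
        # d=1 cm, v=-2 cm/s with unit gains: pre-rectification sum -1 -> 0
        com = com_constant(d=1.0, v=-2.0)
        out = reconstruct_msrm(com, FeedbackGains(k_d=1.0, k_v=1.0), LoopTiming(10.0))
        assert not out.values.any()


class TestHsrmKin:
    def test_zero_second_loop_equals_msrm_bitwise(self, small_com):
        g1 = FeedbackGains(0.03, 0.01, 0.002)
        timing = LoopTiming(100.0, 200.0)
        h = reconstruct_hsrm_kin(small_com, g1, FeedbackGains(), timing)
        m = reconstruct_msrm(small_com, g1, timing)
        assert np.array_equal(h.values, m.values)

    def test_loop_symmetry(self, small_com):
        # empty first loop with accel-only second loop == mSRM at lambda_c
        g2 = FeedbackGains(k_a=0.002)
        h = reconstruct_hsrm_kin(small_com, FeedbackGains(), g2, LoopTiming(100.0, 200.0))
        m = reconstruct_msrm(small_com, g2, LoopTiming(200.0))
        assert np.array_equal(h.values, m.values)

    def test_two_impulse_superposition(self):
        com = com_impulse_a()
        out = reconstruct_hsrm_kin(
            com, FeedbackGains(k_a=1.0), FeedbackGains(k_a=2.0), LoopTiming(100.0, 200.0)
        )
        assert at_ms(out, 100.0) == 1.0
        assert at_ms(out, 200.0) == 2.0
        assert out.values.sum() == 3.0

    def test_requires_lambda_c(self):
        with pytest.raises(ValueError):
            reconstruct_hsrm_kin(
                com_impulse_a(), FeedbackGains(), FeedbackGains(), LoopTiming(100.0)
            )


class TestHsrmCortical:
    def test_zero_signal_gain_equals_msrm_bitwise(self, small_com):
        g1 = FeedbackGains(0.03, 0.01, 0.002)
        cz = TimeSeries(np.sin(small_com.times / 50.0), small_com.fs, small_com.t0)
        timing = LoopTiming(100.0, lambda_c=200.0, tau_c=80.0)
        h = reconstruct_hsrm_cortical(small_com, g1, cz, 0.0, timing)
        m = reconstruct_msrm(small_com, g1, timing)
        assert np.array_equal(h.values, m.values)

    def test_zero_efferent_delay_adds_unshifted(self):
        com = com_constant(n=100)
        cz = TimeSeries(np.linspace(0, 1, 100), FS, 0.0)
        out = reconstruct_hsrm_cortical(
            com, FeedbackGains(), cz, 2.0, LoopTiming(0.0, delta_c=0.0)
        )
        np.testing.assert_array_equal(out.values, 2.0 * cz.values)

    def test_negative_trough_rectified_bump(self):
        # Gaussian trough depth -1 at 137 ms, k = -2, delta_c = 50 ms
        n = 400
        t = np.arange(n)  # ms at 1 kHz
        cz = TimeSeries(-np.exp(-((t - 137.0) ** 2) / (2 * 15.0**2)), FS, 0.0)
        out = reconstruct_hsrm_cortical(
            com_constant(n=n), FeedbackGains(), cz, -2.0, LoopTiming(0.0, delta_c=50.0)
        )
        peak = int(np.argmax(out.values))
        assert peak == 187
        assert out.values[peak] == pytest.approx(2.0, rel=1e-12)

    def test_mismatched_grid_rejected(self, small_com):
        cz = TimeSeries(np.zeros(50), 500.0, 0.0)
        with pytest.raises(ValueError):
            reconstruct_hsrm_cortical(
                small_com, FeedbackGains(), cz, 1.0, LoopTiming(0.0, delta_c=0.0)
            )


class TestCsrm:
    def test_zero_gains(self):
        out = reconstruct_csrm(com_impulse_a(), FeedbackGains(), LoopTiming(tau_c=50.0), -1)
        assert not out.values.any()

    @pytest.mark.parametrize("polarity", [+1, -1])
    def test_polarity_symmetry(self, polarity):
        out = reconstruct_csrm(
            com_impulse_a(), FeedbackGains(k_a=1.0), LoopTiming(tau_c=50.0), polarity
        )
        assert at_ms(out, 50.0) == polarity
        assert np.abs(out.values).sum() == 1.0


class TestInvariants:
    def variants(self, com, cz):
        g1 = FeedbackGains(0.4, -0.2, 0.7)
        g1pos = FeedbackGains(0.4, 0.2, 0.7)
        g2 = FeedbackGains(0.1, 0.3, -0.2)
        return [
            (
                SRMParams(SRMSpec.for_variant("mSRM"), g1, LoopTiming(3.2)),
                dict(gains1=g1.as_array(), lambda1_ms=3.2),
            ),
            (
                SRMParams(
                    SRMSpec.for_variant("hSRM-kin"), g1, LoopTiming(3.2, 7.9), gains2=g2
                ),
                dict(gains1=g1.as_array(), lambda1_ms=3.2, gains2=g2.as_array(), lambda2_ms=7.9),
            ),
            (
                SRMParams(
                    SRMSpec.for_variant("hSRM-N1"),
                    g1,
                    LoopTiming(3.2, delta_c=4.5),
                    k_signal=-1.3,
                ),
                dict(gains1=g1.as_array(), lambda1_ms=3.2, cortical=cz, k_signal=-1.3, delta_ms=4.5),
            ),
            (
                SRMParams(
                    SRMSpec.for_variant("cSRM-N1"), g1pos, LoopTiming(0.0, tau_c=2.7)
                ),
                dict(gains1=g1pos.as_array(), lambda1_ms=2.7, polarity=-1),
            ),
            (
                SRMParams(
                    SRMSpec.for_variant("cSRM-beta"), g1pos, LoopTiming(0.0, tau_c=2.7)
                ),
                dict(gains1=g1pos.as_array(), lambda1_ms=2.7),
            ),
        ]

    def test_brute_force_oracle_equivalence(self, rng):
        """Every reconstruction matches a per-sample literal evaluation to 1e-12."""
        for _ in range(5):
            com = random_com(rng, n=20)
            cz = TimeSeries(rng.normal(size=20), com.fs, com.t0)
            for params, brute_kw in self.variants(com, cz):
                got = reconstruct(params, com, cortical=cz).values
                want = brute_reconstruct(com, **brute_kw)
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_polarity_sign_of_outputs(self, rng):
        com = random_com(rng, n=30)
        g = FeedbackGains(0.5, 0.5, 0.5)
        neg = reconstruct_csrm(com, g, LoopTiming(tau_c=3.0), -1)
        pos = reconstruct_csrm(com, g, LoopTiming(tau_c=3.0), +1)
        assert (neg.values <= 0).all() and (pos.values >= 0).all()

    def test_positive_homogeneity(self, rng):
        com = random_com(rng, n=40)
        g = FeedbackGains(0.4, -0.2, 0.7)
        base = reconstruct_msrm(com, g, LoopTiming(2.5)).values
        c = 3.7
        scaled = reconstruct_msrm(
            com, FeedbackGains(c * g.k_d, c * g.k_v, c * g.k_a), LoopTiming(2.5)
        ).values
        np.testing.assert_allclose(scaled, c * base, atol=1e-12)

    def test_shift_covariance(self, small_com):
        """Delaying the inputs commutes with reconstruction on the overlap."""
        g = FeedbackGains(0.03, 0.01, 0.002)
        shift = 37.0
        shifted_com = ComKinematics(
            delay_shift(small_com.d, shift),
            delay_shift(small_com.v, shift),
            delay_shift(small_com.a, shift),
        )
        a = reconstruct_msrm(shifted_com, g, LoopTiming(100.0)).values
        b = delay_shift(reconstruct_msrm(small_com, g, LoopTiming(100.0)), shift).values
        start = int(shift) + 1
        np.testing.assert_allclose(a[start:], b[start:], atol=1e-10)


class TestSpecValidation:
    def test_single_loop_forbids_loop2(self):
        with pytest.raises(ValueError):
            SRMSpec(Variant.MSRM, frozenset("dva"), frozenset("a"))

    def test_cortical_variant_requires_cortical_loop2(self):
        with pytest.raises(ValueError):
            SRMSpec(Variant.HSRM_N1, frozenset("dva"), frozenset("a"))

    @pytest.mark.parametrize(
        "variant,accel1,accel2,expected",
        [
            ("mSRM", False, False, 4),
            ("hSRM-kin", False, False, 8),
            ("hSRM-kin", False, True, 6),
            ("hSRM-N1", False, False, 6),
            ("hSRM-beta", False, False, 6),
            ("cSRM-N1", False, False, 4),
            ("cSRM-N1", True, False, 2),
        ],
    )
    def test_free_parameter_counts(self, variant, accel1, accel2, expected):
        spec = SRMSpec.for_variant(variant, accel_only_loop1=accel1, accel_only_loop2=accel2)
        assert spec.n_params == expected

    def test_timing_ordering_enforced(self):
        with pytest.raises(ValueError):
            LoopTiming(lambda_bs=150.0, lambda_c=100.0)
        with pytest.raises(ValueError):
            LoopTiming(lambda_bs=100.0, lambda_c=150.0, tau_c=200.0)
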