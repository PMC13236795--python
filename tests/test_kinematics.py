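"""Signal processing: zero-lag filter, CP formula, differentiation, integration."""

import numpy as np
import pytest

from stepinit.kinematics import (
    cm_acceleration,
    cm_velocity,
    cop_ap,
    differentiate,
    lowpass_zero_lag,
)

FS = 1000.0


class TestLowpassZeroLag:
    def test_constant_signal_unchanged(self):
        x = np.full(2000, 3.7)
        assert np.allclose(lowpass_zero_lag(x, FS), x, atol=1e-9)

    def test_symmetric_pulse_peak_not_shifted(self):
        t = np.arange(4000) / FS
        x = np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))
        y = lowpass_zero_lag(x, FS)
        assert int(np.argmax(y)) == int(np.argmax(x))

    def test_gain_at_cutoff_is_half(self):
        """Forward-backward 4th-order Butterworth: |H|^2 at 10 Hz = 0.5."""
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = lowpass_zero_lag(x, FS, cutoff_hz=10.0)
        mid = slice(int(5 * FS), int(15 * FS))  # steady state
        gain = np.max(np.abs(y[mid]))
        assert gain == pytest.approx(0.5, abs=0.005)

    def test_zero_phase_on_noise_plus_trend(self):
        rng = np.random.default_rng(0)
        t = np.arange(5000) / FS
        x = 0.3 * t + np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.1, t.size)
        y = lowpass_zero_lag(x, FS)
        xc = x - x.mean()
        lags = np.arange(-20, 21)
        corr = [np.dot(xc[20:-20], (y - y.mean())[20 + k : y.size - 20 + k]) for k in lags]
        assert lags[int(np.argmax(corr))] == 0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lowpass_zero_lag(np.zeros(10), FS)
        with pytest.raises(ValueError):
            lowpass_zero_lag(np.zeros(1000), sampling_rate=15.0, cutoff_hz=10.0)


class TestCopAp:
    def test_direct_substitution(self):
        yP = cop_ap(np.zeros(3), np.full(3, 600.0), np.full(3, -264.0), z_offset=0.0)
        assert np.allclose(yP, -0.44)

    def test_origin(self):
        assert np.allclose(cop_ap(np.zeros(5), np.full(5, 700.0), np.zeros(5)), 0.0)

    def test_joint_scale_invariance_and_linearity(self):
        rng = np.random.default_rng(1)
        fy, fz, mx = rng.normal(0, 5, 50), rng.uniform(500, 900, 50), rng.normal(0, 30, 50)
        base = cop_ap(fy, fz, mx, z_offset=0.02)
        assert np.allclose(cop_ap(2 * fy, 2 * fz, 2 * mx, 0.02), base)
        # exactly linear in Mx at fixed Fz
        d = cop_ap(fy, fz, mx + 1.0, 0.02) - base
        assert np.allclose(d, 1.0 / fz)

    def test_nonpositive_fz_rejected(self):
        with pytest.raises(ValueError):
            cop_ap(np.zeros(3), np.array([600.0, 0.0, 600.0]), np.zeros(3))


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / FS
        d = differentiate(3.2 * t, FS)
        assert np.allclose(d[1:-1], 3.2)

    def test_constant_zero(self):
        assert np.allclose(differentiate(np.full(50, 7.0), FS), 0.0)

    def test_sine_error_within_taylor_bound(self):
        """Central-difference error bounded by (2 pi f)^3 / (6 fs^2)."""
        f = 7.0
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * f * t)
        d = differentiate(x, FS)
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f) ** 3 / (6 * FS**2)
        assert np.max(np.abs(d[1:-1] - exact[1:-1])) <= bound

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            differentiate(np.zeros(2), FS)


class TestCmAcceleration:
    def test_zero_force(self):
        assert np.allclose(cm_acceleration(np.zeros(100), 70.0, slice(0, 50)), 0.0)

    def test_newton_step(self):
        fy = np.concatenate([np.zeros(500), np.full(500, 70.0)])
        acc = cm_acceleration(fy, 70.0, slice(0, 500))
        assert np.allclose(acc[500:], 1.0)

    def test_constant_bias_removed(self):
        acc = cm_acceleration(np.full(200, 5.0), 70.0, slice(0, 100))
        assert np.allclose(acc, 0.0)

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            cm_acceleration(np.zeros(10), 0.0, slice(0, 5))


class TestCmVelocity:
    def test_constant_acceleration_closed_form(self):
        acc = np.full(1000, 2.0)
        v = cm_velocity(acc, 200, FS)
        t = np.arange(1000) / FS
        assert np.allclose(v[200:], 2.0 * (t[200:] - t[200]))
        assert np.allclose(v[:200], 0.0)

    def test_zero_acceleration(self):
        assert np.allclose(cm_velocity(np.zeros(500), 100, FS), 0.0)

    def test_raised_cosine_pulse_peak_matches_analytic_integral(self):
        """Trapezoid over the full raised-cosine lobe is spectrally exact."""
        T, a = 0.4, 1.3
        n = int(T * FS)
        acc = np.zeros(2000)
        tt = np.arange(n + 1) / FS
        acc[500 : 500 + n + 1] = a * (1 - np.cos(2 * np.pi * tt / T)) / 2
        v = cm_velocity(acc, 500, FS)
        assert v[500 + n] == pytest.approx(a * T / 2, rel=1e-6)

    def test_onset_outside_record_rejected(self):
        with pytest.raises(ValueError):
            cm_velocity(np.zeros(100), 100, FS)


def test_differentiate_inverts_integration_on_smooth_signal():
    t = np.arange(3000) / FS
    acc = np.sin(2 * np.pi * 1.5 * t) ** 2
    v = cm_velocity(acc, 0, FS)
    back = differentiate(v, FS)
    assert np.max(np.abs(back[2:-2] - acc[2:-2])) < 1e-4  # O(fs^-2)


def test_reduce_record_is_newton_consistent(clean_record, clean_kinematics):
    """y''G recomputed from the stored force equals the derived series."""
    acc = (clean_record.fy - 0.0) / clean_record.mass
    # the 10 Hz filter only rounds the template's onset kink (~5% of peak)
    assert np.max(np.abs(clean_kinematics.yG_acc - acc)) < 0.06 * np.max(acc)
    i_on = clean_kinematics.onset_index
    assert np.allclose(clean_kinematics.yG_acc[: i_on - 100], 0.0, atol=1e-6)
    assert np.allclose(clean_kinematics.yP[: i_on - 100], -0.44, atol=1e-6)


from hypothesis import given, settings, strategies as st


@given(
    st.floats(0.1, 10.0),
    st.floats(-50.0, 50.0),
    st.floats(300.0, 1200.0),
    st.floats(-100.0, 100.0),
)
@settings(max_examples=25, deadline=None)
def test_cop_joint_scale_invariance_property(scale, fy, fz, mx):
    """Scaling forces and moment together never moves the CP."""
    a = cop_ap(np.array([fy]), np.array([fz]), np.array([mx]), z_offset=0.01)
    b = cop_ap(np.array([fy * scale]), np.array([fz * scale]), np.array([mx * scale]), z_offset=0.01)
    assert b[0] == pytest.approx(a[0], rel=1e-9, abs=1e-12)
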