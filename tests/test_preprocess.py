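import numpy as np
import pytest

from sts2walk.preprocess import (
    FilterSpec,
    acceleration_modulus,
    derive,
    estimate_gravity_axis,
    fir_lowpass,
    moving_average,
)

FS = 100.0


class TestFirLowpass:
    def test_unit_dc_gain_on_constant(self):
        out = fir_lowpass(np.full(500, 3.7), FilterSpec(), FS)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, bound, passband",
        [(20.0, 0.05, False), (0.3, 0.02, True)],
    )
    def test_frequency_response(self, freq, bound, passband):
        """Stopband tones are crushed; passband tones pass within 2%."""
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = fir_lowpass(x, FilterSpec(), FS)
        core = slice(500, 2500)  # avoid edge transients
        ratio = np.max(np.abs(y[core])) / np.max(np.abs(x[core]))
        if passband:
            assert ratio == pytest.approx(1.0, abs=bound)
        else:
            assert ratio < bound

    def test_linearity(self, rng):
        x = rng.normal(size=800)
        y = rng.normal(size=800)
        spec = FilterSpec()
        lhs = fir_lowpass(2.0 * x - 3.0 * y, spec, FS)
        rhs = 2.0 * fir_lowpass(x, spec, FS) - 3.0 * fir_lowpass(y, spec, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_preserves_length(self, rng):
        x = rng.normal(size=777)
        assert fir_lowpass(x, FilterSpec(), FS).shape == x.shape

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fir_lowpass(np.zeros(10), FilterSpec(), FS)


class TestMovingAverage:
    def test_hand_computed_example(self):
        out = moving_average(np.array([0.0, 0, 3, 0, 0]), 0.03, FS)
        np.testing.assert_allclose(out, [0.0, 1, 1, 1, 0])

    def test_constant_unchanged(self):
        out = moving_average(np.full(50, -2.5), 0.25, FS)
        np.testing.assert_allclose(out, -2.5)

    def test_matches_direct_convolution_oracle(self, rng):
        x = rng.normal(size=200)
        k = 25
        out = moving_average(x, k / FS, FS)
        # oracle: explicit shrinking-window mean
        expected = np.array(
            [
                x[max(0, i - k // 2) : min(len(x), i + k // 2 + 1)].mean()
                for i in range(len(x))
            ]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_alternating_series_attenuated(self):
        x = np.tile([1.0, -1.0], 50)
        out = moving_average(x, 0.05, FS)  # 5-sample window
        core = out[5:-5]
        assert np.max(np.abs(core)) == pytest.approx(1.0 / 5.0, abs=1e-12)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 0.0, FS)


class TestAccelerationModulus:
    def test_stationary_unit_vector(self):
        acc = np.tile([0.0, 0.0, 1.0], (100, 1))
        np.testing.assert_allclose(acceleration_modulus(acc), 1.0)

    def test_3_4_5_triangle(self):
        assert acceleration_modulus(np.array([[3.0, 4.0, 0.0]]))[0] == 5.0

    def test_matches_norm_oracle_and_symmetry(self, rng):
        acc = rng.normal(size=(300, 3))
        mod = acceleration_modulus(acc)
        oracle = np.sqrt(acc[:, 0] ** 2 + acc[:, 1] ** 2 + acc[:, 2] ** 2)
        np.testing.assert_allclose(mod, oracle, atol=1e-12)
        # invariant to axis permutation and sign flips
        np.testing.assert_allclose(
            acceleration_modulus(-acc[:, [2, 0, 1]]), mod, atol=1e-12
        )

    def test_nan_rejected(self):
        acc = np.array([[0.0, np.nan, 1.0]])
        with pytest.raises(ValueError):
            acceleration_modulus(acc)


class TestGravityAxis:
    def test_noisy_stationary_within_2_degrees(self):
        angles = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            acc = np.tile([0.0, 0.0, 1.0], (1000, 1)) + rng.normal(0, 0.01, (1000, 3))
            g, _ = estimate_gravity_axis(acc, FS)
            angles.append(np.degrees(np.arccos(np.clip(g @ [0, 0, 1], -1, 1))))
        assert max(angles) < 2.0

    def test_constant_direction_normalized(self):
        acc = np.tile([0.0, 0.6, 0.8], (1000, 1))
        g, proj = estimate_gravity_axis(acc, FS)
        np.testing.assert_allclose(g, [0.0, 0.6, 0.8], atol=1e-12)
        np.testing.assert_allclose(proj, 1.0, atol=1e-12)

    def test_tilting_phone_projection_tracks_cosine(self):
        """Programmed tilt with no linear acceleration: the gravity
        projection equals cos(tilt) × 1 g within 3%."""
        from sts2walk import KinematicParams, synth

        rec, _ = synth.simulate_recording(
            KinematicParams(
                n_cycles=8,
                stand_duration=1.0,
                sit_duration=1.0,
                dwell_stand=2.0,
                dwell_sit=2.0,
                max_trunk_lean=20.0,
                peak_acc=1.0,  # pure rotation, no vertical acceleration
                noise_sd_acc=0.0,
                noise_sd_gyro=0.0,
                seed=0,
            )
        )
        _, proj = estimate_gravity_axis(rec.acc, FS)
        # exact tilt from the noise-free gyro (pitch rate about x)
        tilt = np.radians(np.cumsum(rec.gyro[:, 0]) / FS)
        assert np.max(np.abs(proj - np.cos(tilt))) < 0.03

    def test_free_fall_rejected(self):
        acc = np.zeros((1000, 3))
        with pytest.raises(ValueError, match="gravity"):
            estimate_gravity_axis(acc, FS)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            estimate_gravity_axis(np.tile([0.0, 0, 1], (100, 1)), FS)


def test_derive_stationary_recording_has_tiny_gravity_cv(clean_recording):
    """Stationary phone: projection CV bounded by the (zero) noise level."""
    from sts2walk import KinematicParams, synth

    rec, _ = synth.simulate_recording(
        KinematicParams(n_cycles=0, noise_sd_acc=0.005, noise_sd_gyro=0.5, seed=2)
    )
    d = derive(rec)
    assert np.std(d.acc_grav) / np.mean(d.acc_grav) < 0.01
    assert abs(np.linalg.norm(d.g_axis) - 1) < 1e-12
    assert (d.acc_mod >= 0).all()
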