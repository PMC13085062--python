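import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sts2walk import KinematicParams, synth
from sts2walk.features import (
    FEATURE_COLUMNS,
    SampEnParams,
    count_repetitions,
    down_fraction,
    extract_all,
    gravity_cv,
    max_acceleration,
    mean_sts_time,
    sample_entropy,
    trunk_angle_max,
)
from sts2walk.preprocess import derive
from sts2walk.segmentation import STSCycle, SegmentationResult, segment


def sampen_oracle(x, m=2, r_factor=0.2):
    """Naive double-loop template-counting oracle (independent of the
    vectorized implementation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_factor * np.std(x)
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                d_full = max(d_m, abs(x[i + m] - x[j + m]))
                if d_full <= r:
                    a += 1
    if b == 0:
        raise ValueError("no matches at m")
    return math.inf if a == 0 else -math.log(a / b)


class TestSampleEntropy:
    def test_periodic_series_matches_oracle_exactly(self):
        x = np.tile([1.0, 2.0, 3.0], 20)  # N = 60
        got = sample_entropy(x)
        assert got == sampen_oracle(x)

    @pytest.mark.parametrize("n", [30, 75, 200])
    def test_random_series_match_oracle_exactly(self, n):
        rng = np.random.default_rng(n)
        x = np.cumsum(rng.normal(size=n))  # correlated, realistic-ish
        assert sample_entropy(x) == sampen_oracle(x)

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(0)
        t = np.arange(400) / 100.0
        sine = np.sin(2 * np.pi * 0.4 * t)
        noise = rng.normal(size=400)
        noise = noise / np.std(noise) * np.std(sine)
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_infinite_tolerance_gives_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        assert sample_entropy(x, SampEnParams(r_factor=1e9)) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            sample_entropy(np.ones(50))

    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-50.0, 50.0),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift, seed):
        """r scales with the SD, so SampEn(a·x + b) == SampEn(x)."""
        x = np.random.default_rng(seed).normal(size=80)
        assert sample_entropy(scale * x + shift) == pytest.approx(
            sample_entropy(x), rel=1e-9
        )

    def test_nonnegative_when_finite(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=120)
            se = sample_entropy(x)
            assert se >= 0 or math.isinf(se)


class TestCycleFeatures:
    def _seg(self, durations):
        cycles = []
        t = 0.0
        for d in durations:
            cycles.append(STSCycle(t, t + d, t + d + 0.4, t + 2 * d + 0.4))
            t += 2 * d + 1.0
        return SegmentationResult(cycles=cycles)

    def test_mean_sts_time_arithmetic(self):
        seg = self._seg([1.0, 1.5, 2.0])
        assert mean_sts_time(seg) == pytest.approx(1.5)

    def test_single_cycle_mean(self):
        assert mean_sts_time(self._seg([1.3])) == pytest.approx(1.3)

    def test_empty_segmentation_gives_missing(self):
        seg = SegmentationResult()
        assert count_repetitions(seg) == 0
        assert math.isnan(mean_sts_time(seg))
        assert math.isnan(down_fraction(seg))

    def test_down_fraction_equal_dwells(self):
        rec, truth = synth.simulate_recording(
            KinematicParams(
                n_cycles=15,
                stand_duration=0.9,
                sit_duration=0.9,
                dwell_stand=0.6,
                dwell_sit=0.6,
                noise_sd_acc=0.01,
                seed=8,
            )
        )
        assert down_fraction(segment(rec)) == pytest.approx(0.5, abs=0.02)

    def test_down_fraction_two_to_one(self):
        rec, _ = synth.simulate_recording(
            KinematicParams(
                n_cycles=12,
                stand_duration=1.0,
                sit_duration=1.0,
                dwell_stand=0.5,
                dwell_sit=1.0,
                noise_sd_acc=0.01,
                seed=9,
            )
        )
        assert down_fraction(segment(rec)) == pytest.approx(2.0 / 3.0, abs=0.03)


class TestSignalFeatures:
    def test_stationary_max_acceleration_is_one_g(self):
        rec, _ = synth.simulate_recording(
            KinematicParams(n_cycles=0, noise_sd_acc=0.002, seed=1)
        )
        d = derive(rec)
        assert max_acceleration(d) == pytest.approx(1.0, abs=0.01)
        assert gravity_cv(d) < 0.005

    def test_programmed_peak_recovered_modulo_filter(self):
        rec, _ = synth.simulate_recording(
            KinematicParams(
                n_cycles=15,
                stand_duration=1.2,
                sit_duration=1.2,
                dwell_stand=0.3,
                dwell_sit=0.3,
                peak_acc=1.8,
                noise_sd_acc=0.0,
                seed=2,
            )
        )
        amax = max_acceleration(derive(rec))
        # low-pass filtering attenuates the programmed 1.8 g peak somewhat
        assert 1.0 + 0.5 * 0.8 < amax <= 1.81

    def test_gravity_cv_hand_value(self):
        # alternating 0.8/1.2 g: mean 1.0, SD 0.2 → CV 0.2
        from sts2walk.preprocess import DerivedSignals

        grav = np.tile([0.8, 1.2], 500)
        d = DerivedSignals(
            acc_filt=np.zeros((1000, 3)),
            acc_mod=np.ones(1000),
            g_axis=np.array([0.0, 0.0, 1.0]),
            acc_grav=grav,
            acc_grav_filt=grav,
        )
        assert gravity_cv(d) == pytest.approx(0.2)

    def test_trunk_angle_recovers_programmed_lean(self):
        rec, _ = synth.simulate_recording(
            KinematicParams(
                n_cycles=18,
                stand_duration=1.0,
                sit_duration=1.0,
                dwell_stand=0.5,
                dwell_sit=0.5,
                max_trunk_lean=40.0,
                noise_sd_acc=0.02,
                noise_sd_gyro=1.0,
                seed=5,
            )
        )
        assert trunk_angle_max(rec, segment(rec)) == pytest.approx(40.0, abs=3.0)


class TestExtractAll:
    def test_schema_39_finite_named_entries(self, noisy_recording):
        rec, _ = noisy_recording
        vec = extract_all(rec, segment(rec))
        assert list(vec.index) == list(FEATURE_COLUMNS)
        assert len(vec) == 39
        assert np.isfinite(vec.to_numpy()).all()

    def test_determinism(self, noisy_recording):
        rec, _ = noisy_recording
        seg = segment(rec)
        a = extract_all(rec, seg)
        b = extract_all(rec, seg)
        assert (a == b).all()

    def test_zero_cycle_recording_gives_count_zero_and_missing(self):
        rec, _ = synth.simulate_recording(
            KinematicParams(n_cycles=0, noise_sd_acc=0.01, seed=3)
        )
        vec = extract_all(rec, segment(rec))
        assert vec["count"] == 0
        assert math.isnan(vec["mean_sts_time"])
        assert math.isnan(vec["down_pct"])
        assert math.isnan(vec["trunk_ang"])

    def test_cadence_monotonicity(self):
        """More programmed cycles: higher count, shorter transitions."""
        vecs = []
        for n_cyc, trans in ((12, 1.4), (30, 0.6)):
            period = 58.0 / n_cyc
            leftover = max(period - 2 * trans, 0.2)
            rec, _ = synth.simulate_recording(
                KinematicParams(
                    n_cycles=n_cyc,
                    stand_duration=trans,
                    sit_duration=trans,
                    dwell_stand=leftover / 2,
                    dwell_sit=leftover / 2,
                    noise_sd_acc=0.02,
                    seed=6,
                )
            )
            vecs.append(extract_all(rec, segment(rec)))
        slow, fast = vecs
        assert fast["count"] > slow["count"]
        assert fast["mean_sts_time"] < slow["mean_sts_time"]
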