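"""Per-recording movement features for the one-minute sit-to-stand test.

Seven headline features quantify repetition frequency, movement speed,
rest behaviour, signal regularity, force exertion, vertical-axis
variability, and postural control:

``count``          repetitions completed in the minute
``mean_sts_time``  mean stand-up transition duration (s)
``down_pct``       fraction of dwell time spent seated, within complete cycles
``samp_en``        sample entropy of the filtered acceleration modulus
``acc_max``        maximum acceleration modulus (g)
``g_cv``           coefficient of variation of gravity-axis acceleration
``trunk_ang``      maximum forward trunk lean during stand-up (deg)

They are extended by per-phase duration statistics, per-axis signal
summaries, cycle-duration variability/fatigue proxies and jerk summaries
to the fixed, versioned 39-column set ``FEATURE_COLUMNS`` (tag
``FEATURE_SET_VERSION``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DerivedSignals, FilterSpec, derive
from .segmentation import SegmentationResult

__all__ = [
    "SampEnParams",
    "FEATURE_COLUMNS",
    "FEATURE_SET_VERSION",
    "NAMED_FEATURES",
    "count_repetitions",
    "mean_sts_time",
    "down_fraction",
    "sample_entropy",
    "max_acceleration",
    "gravity_cv",
    "trunk_angle_max",
    "extract_all",
]

FEATURE_SET_VERSION = "v1"

NAMED_FEATURES = (
    "count",
    "mean_sts_time",
    "down_pct",
    "samp_en",
    "acc_max",
    "g_cv",
    "trunk_ang",
)

#: the fixed 39-column feature set (order is part of the contract)
FEATURE_COLUMNS = NAMED_FEATURES + (
    # stand-up / sit-down transition duration statistics
    "standup_time_sd",
    "standup_time_cv",
    "sitdown_time_mean",
    "sitdown_time_sd",
    "sitdown_time_cv",
    # dwell statistics
    "stand_dwell_mean",
    "stand_dwell_sd",
    "sit_dwell_mean",
    "sit_dwell_sd",
    # cycle duration variability and fatigue proxy
    "cycle_time_mean",
    "cycle_time_sd",
    "cycle_time_cv",
    "cycle_rate_trend",
    # per-axis filtered acceleration summaries
    "acc_x_mean",
    "acc_x_sd",
    "acc_x_absmax",
    "acc_y_mean",
    "acc_y_sd",
    "acc_y_absmax",
    "acc_z_mean",
    "acc_z_sd",
    "acc_z_absmax",
    # modulus and gyro magnitude summaries
    "acc_mod_mean",
    "acc_mod_sd",
    "gyro_mod_mean",
    "gyro_mod_sd",
    "gyro_mod_max",
    # jerk summaries
    "jerk_rms",
    "jerk_max",
    # gravity-axis excursion summaries
    "acc_grav_min",
    "acc_grav_max",
    "acc_grav_range",
)

assert len(FEATURE_COLUMNS) == 39


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters: template length ``m`` and tolerance
    ``r = r_factor * SD(series)``."""

    m: int = 2
    r_factor: float = 0.2

    def validate(self, n: int) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if n <= self.m + 1:
            raise ValueError(f"series length {n} must exceed m+1 = {self.m + 1}")


def count_repetitions(seg: SegmentationResult) -> int:
    """Number of sit-and-stand repetitions in the minute."""
    return seg.count


def mean_sts_time(seg: SegmentationResult) -> float:
    """Arithmetic mean of stand-up transition durations (s); NaN if no cycles."""
    if not seg.cycles:
        return math.nan
    return float(np.mean([c.stand_up_duration for c in seg.cycles]))


def down_fraction(seg: SegmentationResult) -> float:
    """Fraction of dwell time spent seated within the span of complete cycles.

    Seated dwell is the gap between one cycle's sit-down end and the next
    cycle's stand-up start; standing dwell is the time between a cycle's
    two transitions.  Transitions themselves belong to neither state.
    """
    if not seg.cycles:
        return math.nan
    stand_dwell = sum(c.stand_dwell for c in seg.cycles)
    sit_dwell = sum(
        b.stand_start - a.sit_end for a, b in zip(seg.cycles, seg.cycles[1:])
    )
    total = stand_dwell + sit_dwell
    if total <= 0:
        return math.nan
    return sit_dwell / total


def sample_entropy(
    series: np.ndarray, params: SampEnParams | None = None
) -> float:
    """Sample entropy SampEn(m, r) of a scalar series.

    −ln(A/B) where B is the probability that two distinct templates of
    length m match within tolerance r (Chebyshev distance), and A the same
    at length m+1.  Templates are the N−m runs that admit an (m+1)-length
    extension, so the two counts are over matched pairs; self-matches are
    excluded.  Tolerance r = r_factor·SD(series) (population SD), making
    the statistic invariant to affine rescaling of the series.

    Returns ``inf`` when no (m+1)-templates match (callers treat it as
    missing); raises on zero-variance input.
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    n = x.size
    params.validate(n)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("zero-variance series: sample entropy undefined")
    r = params.r_factor * sd
    m = params.m

    n_templates = n - m  # templates that extend to length m+1
    # (n_templates, m+1) template matrix
    idx = np.arange(n_templates)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]

    b_count = 0  # matches at length m
    a_count = 0  # matches at length m+1
    chunk = 512
    for lo in range(0, n_templates, chunk):
        hi = min(lo + chunk, n_templates)
        # Chebyshev distances of chunk templates vs all templates
        block = templates[lo:hi]
        absdiff = np.abs(block[:, None, :] - templates[None, :, :])
        d_m = absdiff[:, :, :m].max(axis=-1)
        d_full = np.maximum(d_m, absdiff[:, :, m])
        # count ordered pairs j > i only (each unordered pair once)
        mask_upper = np.arange(n_templates)[None, :] > np.arange(lo, hi)[:, None]
        b_count += int(np.count_nonzero((d_m <= r) & mask_upper))
        a_count += int(np.count_nonzero((d_full <= r) & mask_upper))

    if b_count == 0:
        raise ValueError("no template matches at length m; r too small")
    if a_count == 0:
        return math.inf
    return -math.log(a_count / b_count)


def max_acceleration(derived: DerivedSignals) -> float:
    """Maximum of the filtered acceleration modulus (g)."""
    if derived.acc_mod.size == 0:
        raise ValueError("empty acceleration series")
    return float(np.max(derived.acc_mod))


def gravity_cv(derived: DerivedSignals) -> float:
    """Coefficient of variation of the gravity-axis acceleration."""
    g = derived.acc_grav
    if g.size == 0:
        raise ValueError("empty gravity projection")
    mean = float(np.mean(g))
    if mean == 0:
        raise ValueError("zero-mean gravity projection")
    return float(np.std(g) / abs(mean))


def _pitch_trajectory(recording) -> np.ndarray:
    """Trunk pitch (deg) vs time from a complementary filter.

    Gyro pitch rate about the dominant rotation axis is integrated and
    blended (coefficient 0.98) with the accelerometer tilt — the angle
    between instantaneous acceleration and the *initial* (seated)
    orientation, signed by the gyro-integrated pitch.  Referencing the
    tilt to the first second's mean acceleration, rather than the
    whole-recording gravity mean, avoids biasing the peak lean by the
    time the trunk spends inclined.
    """
    fs = recording.fs
    g_axis = recording.acc[: int(fs)].mean(axis=0)
    g_axis = g_axis / np.linalg.norm(g_axis)
    gyro = recording.gyro
    if gyro is None or not np.any(np.std(gyro, axis=0) > 0):
        # accelerometer-tilt-only fallback
        acc = recording.acc
        norm = np.linalg.norm(acc, axis=1)
        norm[norm == 0] = 1.0
        cosang = np.clip((acc @ g_axis) / norm, -1.0, 1.0)
        tilt = np.degrees(np.arccos(cosang))
        return tilt - tilt[: int(fs)].mean()

    # pitch axis: rotation about the gravity axis (yaw) cannot tilt the
    # trunk, so project it out and take the principal horizontal axis
    gyro_h = gyro - np.outer(gyro @ g_axis, g_axis)
    power = gyro_h.T @ gyro_h
    eigval, eigvec = np.linalg.eigh(power)
    rate = gyro_h @ eigvec[:, -1]
    # sign so that the first large excursion is positive (forward lean)
    peak_idx = int(np.argmax(np.abs(rate)))
    # integrated gyro pitch up to the first extreme decides the sign
    raw_int = np.cumsum(rate) / fs
    sign = 1.0 if raw_int[peak_idx] >= 0 else -1.0
    rate = sign * rate

    acc = recording.acc
    norm = np.linalg.norm(acc, axis=1)
    norm[norm == 0] = 1.0
    cosang = np.clip((acc @ g_axis) / norm, -1.0, 1.0)
    tilt = np.degrees(np.arccos(cosang))  # unsigned accelerometer tilt

    alpha = 0.98
    dt = 1.0 / fs
    pitch = np.empty(acc.shape[0])
    pitch[0] = 0.0
    for i in range(1, acc.shape[0]):
        gyro_pred = pitch[i - 1] + rate[i] * dt
        acc_tilt = math.copysign(tilt[i], gyro_pred) if tilt[i] > 0 else gyro_pred
        pitch[i] = alpha * gyro_pred + (1 - alpha) * acc_tilt
    return pitch - pitch[: int(fs)].mean()


def trunk_angle_max(recording, seg: SegmentationResult) -> float:
    """Maximum forward trunk lean (deg) across stand-up transitions.

    Forward lean is positive, referenced to the initial seated posture.
    NaN when there are no complete cycles.
    """
    if not seg.cycles:
        return math.nan
    pitch = _pitch_trajectory(recording)
    t = recording.t - recording.t[0]
    best = 0.0
    for c in seg.cycles:
        window = (t >= c.stand_start) & (t <= c.stand_end)
        if window.any():
            best = max(best, float(np.max(pitch[window])))
    return best


def extract_all(
    recording,
    seg: SegmentationResult,
    filter_spec: FilterSpec | None = None,
    sampen: SampEnParams | None = None,
) -> pd.Series:
    """Compute the full 39-column feature vector for one recording.

    Deterministic; never mutates its inputs.  When there are no complete
    cycles, ``count`` is 0 and all cycle-dependent features are NaN.
    """
    derived = derive(recording, filter_spec)
    fs = recording.fs
    vals: dict[str, float] = {}

    vals["count"] = float(count_repetitions(seg))
    vals["mean_sts_time"] = mean_sts_time(seg)
    vals["down_pct"] = down_fraction(seg)
    try:
        se = sample_entropy(derived.acc_mod, sampen)
        vals["samp_en"] = se if math.isfinite(se) else math.nan
    except ValueError:
        vals["samp_en"] = math.nan
    vals["acc_max"] = max_acceleration(derived)
    vals["g_cv"] = gravity_cv(derived)
    vals["trunk_ang"] = trunk_angle_max(recording, seg)

    def _stats(xs: list[float]) -> tuple[float, float, float]:
        if not xs:
            return math.nan, math.nan, math.nan
        m = float(np.mean(xs))
        s = float(np.std(xs))
        return m, s, (s / abs(m) if m != 0 else math.nan)

    ups = [c.stand_up_duration for c in seg.cycles]
    downs = [c.sit_down_duration for c in seg.cycles]
    stand_dwells = [c.stand_dwell for c in seg.cycles]
    sit_dwells = [
        b.stand_start - a.sit_end for a, b in zip(seg.cycles, seg.cycles[1:])
    ]
    cyc = [c.cycle_duration for c in seg.cycles]

    _, vals["standup_time_sd"], vals["standup_time_cv"] = _stats(ups)
    (
        vals["sitdown_time_mean"],
        vals["sitdown_time_sd"],
        vals["sitdown_time_cv"],
    ) = _stats(downs)
    vals["stand_dwell_mean"], vals["stand_dwell_sd"], _ = _stats(stand_dwells)
    vals["sit_dwell_mean"], vals["sit_dwell_sd"], _ = _stats(sit_dwells)
    vals["cycle_time_mean"], vals["cycle_time_sd"], vals["cycle_time_cv"] = _stats(cyc)

    # fatigue proxy: completed cycles starting in the first vs second half
    if seg.cycles:
        half = (recording.t[-1] - recording.t[0]) / 2
        first = sum(1 for c in seg.cycles if c.stand_start <= half)
        vals["cycle_rate_trend"] = float(first - (len(seg.cycles) - first))
    else:
        vals["cycle_rate_trend"] = math.nan

    for k, name in enumerate(("x", "y", "z")):
        ax = derived.acc_filt[:, k]
        vals[f"acc_{name}_mean"] = float(np.mean(ax))
        vals[f"acc_{name}_sd"] = float(np.std(ax))
        vals[f"acc_{name}_absmax"] = float(np.max(np.abs(ax)))

    vals["acc_mod_mean"] = float(np.mean(derived.acc_mod))
    vals["acc_mod_sd"] = float(np.std(derived.acc_mod))
    gyro_mod = np.linalg.norm(recording.gyro, axis=1)
    vals["gyro_mod_mean"] = float(np.mean(gyro_mod))
    vals["gyro_mod_sd"] = float(np.std(gyro_mod))
    vals["gyro_mod_max"] = float(np.max(gyro_mod))

    jerk = np.diff(derived.acc_mod) * fs
    vals["jerk_rms"] = float(np.sqrt(np.mean(jerk**2)))
    vals["jerk_max"] = float(np.max(np.abs(jerk)))

    grav = derived.acc_grav_filt
    vals["acc_grav_min"] = float(np.min(grav))
    vals["acc_grav_max"] = float(np.max(grav))
    vals["acc_grav_range"] = vals["acc_grav_max"] - vals["acc_grav_min"]

    return pd.Series(vals, index=list(FEATURE_COLUMNS), dtype=float)
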