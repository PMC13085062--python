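"""Synthetic test bed: kinematic IMU recordings of repeated sit-to-stand
motion with exact ground-truth timestamps, and cohort-level feature/6MWD
tables calibrated to published COPD cohort statistics.

Sensor model
------------
The phone is held flat against the chest; in the sensor frame the z-axis
points along the upright trunk (reads +1 g when still) and forward trunk
lean is a rotation of angle θ about the x-axis.  The accelerometer reads
specific force: with vertical chest acceleration a_v (g, upward positive)
and lean θ,

    az = (1 + a_v)·cos θ,   ay = (1 + a_v)·sin θ,   ax = 0,

plus white noise per axis; the gyroscope reads gx = dθ/dt (deg/s) plus
noise.  Each transition uses C¹-smooth profiles over its duration T with
phase s = t/T ∈ [0, 1]:

    stand-up:  a_v(s) = A·sin(2πs)    (accelerate up, brake)
    sit-down:  a_v(s) = −A·sin(2πs)   (drop, brake)
    lean:      θ(s) = θ_max·sin²(πs)  (lean forward, straighten)

where A = peak_acc − 1.  Transition boundaries are the exact ground-truth
timestamps; dwell phases (seated / standing, θ = 0, a_v = 0) separate
them.

Cohort model
------------
One latent capacity factor Z ~ N(0,1) per subject.  6MWD is a two-sided
Gaussian (piecewise-linear) transform of Z whose quartiles equal the
published 350 / 417.5 / 450 m; each feature is linear in Z plus
independent Gaussian noise, with the loading solved in closed form so the
feature–distance Pearson correlation hits its target despite the
transform's attenuation (and, for the integer count, rounding noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IMURecording
from .segmentation import STSCycle

__all__ = [
    "KinematicParams",
    "CohortParams",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "simulate_study",
    "COHORT_TARGETS",
]

#: standard-normal quartile
_Z_QUARTILE = 0.6744897501960817


@dataclass(frozen=True)
class KinematicParams:
    """Kinematic schedule and sensor-noise parameters for one recording."""

    n_cycles: int = 23
    stand_duration: float = 1.0  # s, stand-up transition
    sit_duration: float = 1.0  # s, sit-down transition
    dwell_stand: float = 0.3  # s, standing between transitions
    dwell_sit: float = 0.3  # s, seated between cycles
    max_trunk_lean: float = 25.0  # deg
    peak_acc: float = 1.4  # g, peak acceleration modulus
    noise_sd_acc: float = 0.02  # g per axis
    noise_sd_gyro: float = 1.0  # deg/s per axis
    lead_in: float = 1.5  # s seated before the first stand-up
    duration: float = 60.0  # s, total test length
    fs: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        for name in ("stand_duration", "sit_duration", "dwell_stand", "dwell_sit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peak_acc < 1.0:
            raise ValueError("peak_acc is a modulus peak and must be >= 1 g")


@dataclass
class GroundTruth:
    """Exact cycle schedule of a simulated recording."""

    cycles: list[STSCycle] = field(default_factory=list)
    truncated: bool = False
    max_lean: float = 0.0
    sit_fraction: float = math.nan  # programmed seated share of dwell time
    #: (start, end) of a final stand-up whose sit-down did not fit in the
    #: test window — the subject is standing when time runs out
    trailing_stand: tuple[float, float] | None = None

    @property
    def count(self) -> int:
        return len(self.cycles)

    def transition_times(self) -> list[tuple[str, float, float]]:
        out = []
        for c in self.cycles:
            out.append(("stand_up", c.stand_start, c.stand_end))
            out.append(("sit_down", c.sit_start, c.sit_end))
        return out


def simulate_recording(
    params: KinematicParams, subject_id: str = "synthetic"
) -> tuple[IMURecording, GroundTruth]:
    """Simulate one chest-held-phone recording with ground-truth timestamps.

    Cycles that do not complete within ``duration`` are dropped and the
    ground truth flagged as truncated; a final stand-up that completes on
    its own is rendered and reported via ``trailing_stand``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.fs
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    a_v = np.zeros(n)  # vertical chest acceleration, g
    theta = np.zeros(n)  # trunk lean, deg
    amp = params.peak_acc - 1.0

    cycles: list[STSCycle] = []
    truncated = False
    trailing: tuple[float, float] | None = None
    cursor = params.lead_in
    for _ in range(params.n_cycles):
        stand_start = cursor
        stand_end = stand_start + params.stand_duration
        sit_start = stand_end + params.dwell_stand
        sit_end = sit_start + params.sit_duration
        if sit_end > params.duration:
            truncated = True
            if stand_end <= params.duration:
                # the stand-up completes; the subject is standing at cut-off
                i0, i1 = int(round(stand_start * fs)), int(round(stand_end * fs))
                s = (t[i0:i1] - stand_start) / params.stand_duration
                a_v[i0:i1] += amp * np.sin(2 * np.pi * s)
                theta[i0:i1] += params.max_trunk_lean * np.sin(np.pi * s) ** 2
                trailing = (stand_start, stand_end)
            break
        for (t0, t1), sign in (((stand_start, stand_end), 1.0),
                               ((sit_start, sit_end), -1.0)):
            i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n - 1)
            s = (t[i0:i1] - t0) / (t1 - t0)
            a_v[i0:i1] += sign * amp * np.sin(2 * np.pi * s)
            theta[i0:i1] += params.max_trunk_lean * np.sin(np.pi * s) ** 2
        cycles.append(
            STSCycle(
                stand_start=stand_start,
                stand_end=stand_end,
                sit_start=sit_start,
                sit_end=sit_end,
            )
        )
        cursor = sit_end + params.dwell_sit

    th = np.radians(theta)
    acc = np.column_stack(
        [
            np.zeros(n),
            (1.0 + a_v) * np.sin(th),
            (1.0 + a_v) * np.cos(th),
        ]
    )
    acc += rng.normal(0.0, params.noise_sd_acc, size=acc.shape)
    pitch_rate = np.gradient(theta, 1.0 / fs)  # deg/s about x
    gyro = np.column_stack([pitch_rate, np.zeros(n), np.zeros(n)])
    gyro += rng.normal(0.0, params.noise_sd_gyro, size=gyro.shape)

    rec = IMURecording(subject_id=subject_id, t=t, acc=acc, gyro=gyro, fs=fs)
    truth = GroundTruth(
        cycles=cycles,
        truncated=truncated,
        max_lean=params.max_trunk_lean if cycles else 0.0,
        sit_fraction=(
            params.dwell_sit / (params.dwell_sit + params.dwell_stand)
            if cycles
            else math.nan
        ),
        trailing_stand=trailing,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: published cohort calibration: feature -> (target r vs 6MWD, median, IQR half
#: spread as (q1, q3)); count and distance quartiles are matched exactly.
COHORT_TARGETS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "count": (0.77, 23.0, (18.0, 28.0)),
    "mean_sts_time": (-0.75, 1.25, (1.05, 1.45)),
    "down_pct": (-0.73, 0.55, (0.49, 0.61)),
    "samp_en": (-0.69, 0.25, (0.19, 0.31)),
    "acc_max": (0.67, 1.40, (1.28, 1.52)),
    "g_cv": (0.59, 0.14, (0.11, 0.17)),
    "trunk_ang": (-0.57, 25.0, (19.0, 31.0)),
}

DISTANCE_QUARTILES = (350.0, 417.5, 450.0)  # m


@dataclass(frozen=True)
class CohortParams:
    """Cohort size, calibration targets, and noise for the table generator."""

    n_subjects: int = 66
    targets: dict[str, tuple[float, float, tuple[float, float]]] = field(
        default_factory=lambda: dict(COHORT_TARGETS)
    )
    distance_quartiles: tuple[float, float, float] = DISTANCE_QUARTILES
    distance_noise: float = 0.0  # m, additive on 6MWD
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("n_subjects must be >= 5")
        for name, (r, _, (q1, q3)) in self.targets.items():
            if not -1 < r < 1:
                raise ValueError(f"target correlation for {name} must be in (-1, 1)")
            if not q1 < q3:
                raise ValueError(f"IQR for {name} must have q1 < q3")


def _distance_transform(z: np.ndarray, quartiles: tuple[float, float, float]) -> np.ndarray:
    """Two-sided Gaussian transform with the given (q1, median, q3)."""
    q1, med, q3 = quartiles
    s_lo = (med - q1) / _Z_QUARTILE
    s_hi = (q3 - med) / _Z_QUARTILE
    return med + np.where(z < 0, s_lo * z, s_hi * z)


def _transform_moments(quartiles: tuple[float, float, float]) -> tuple[float, float]:
    """(cov(Z, g(Z)), sd(g(Z))) for the two-sided Gaussian transform g."""
    q1, med, q3 = quartiles
    s_lo = (med - q1) / _Z_QUARTILE
    s_hi = (q3 - med) / _Z_QUARTILE
    cov = 0.5 * (s_lo + s_hi)
    ex2 = 0.5 * (s_lo**2 + s_hi**2)
    mean_dev = (s_hi - s_lo) / math.sqrt(2 * math.pi)  # E[g] - med
    var = ex2 - mean_dev**2
    return cov, math.sqrt(var)


def simulate_cohort(params: CohortParams | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a calibrated cohort table; returns (table, latent capacity).

    Each feature's latent loading a is solved in closed form so that the
    Pearson correlation with the transformed (and possibly noisy) distance
    equals the target; infeasible targets (|a| ≥ 1 required) raise.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    z = rng.standard_normal(n)

    distance = _distance_transform(z, params.distance_quartiles)
    cov_zd, sd_d = _transform_moments(params.distance_quartiles)
    if params.distance_noise > 0:
        distance = distance + rng.normal(0.0, params.distance_noise, n)
        sd_d = math.sqrt(sd_d**2 + params.distance_noise**2)
    # corr(Z, distance) after transform + noise
    kappa = cov_zd / sd_d

    cols: dict[str, np.ndarray] = {}
    for name, (r_target, med, (q1, q3)) in params.targets.items():
        sigma = (q3 - q1) / (2 * _Z_QUARTILE)
        attenuation = kappa
        if name == "count":
            # rounding adds ~Var=1/12 of noise to the feature
            attenuation *= sigma / math.sqrt(sigma**2 + 1.0 / 12.0)
        a = r_target / attenuation
        if not -1 < a < 1:
            raise ValueError(
                f"target correlation {r_target} for {name} is infeasible "
                f"after transform attenuation"
            )
        noise = rng.standard_normal(n)
        latent = a * z + math.sqrt(1 - a * a) * noise
        feat = med + sigma * latent
        if name == "count":
            feat = np.clip(np.round(feat), 1, None)
        elif name == "down_pct":
            feat = np.clip(feat, 0.01, 0.99)
        elif name in ("mean_sts_time", "samp_en", "g_cv", "trunk_ang", "acc_max"):
            feat = np.maximum(feat, 0.01)
        cols[name] = feat

    table = pd.DataFrame(cols)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(n)])
    table["distance"] = distance
    return table, pd.Series(z, name="capacity")


def _capacity_to_kinematics(z: float, seed: int) -> KinematicParams:
    """Monotone capacity → kinematics mapping.

    Higher capacity: more cycles, faster transitions, larger peak
    acceleration, smaller forward lean, smaller seated share — matching
    the signs of the published feature–6MWD correlations.
    """
    n_cycles = int(np.clip(round(23 + (28 - 18) / (2 * _Z_QUARTILE) * z), 8, 38))
    duration = 60.0
    lead_in = 1.5
    period = (duration - lead_in) / n_cycles
    trans = float(np.clip(1.25 - 0.18 * z, 0.45, 0.35 * period))
    leftover = max(period - 2 * trans, 0.2)
    sit_share = float(np.clip(0.55 - 0.05 * z, 0.35, 0.75))
    return KinematicParams(
        n_cycles=n_cycles,
        stand_duration=trans,
        sit_duration=trans,
        dwell_stand=leftover * (1 - sit_share),
        dwell_sit=leftover * sit_share,
        max_trunk_lean=float(np.clip(25 - 6 * z, 6.0, 44.0)),
        peak_acc=float(np.clip(1.40 + 0.12 * z, 1.12, 1.80)),
        noise_sd_acc=0.02,
        noise_sd_gyro=1.0,
        lead_in=lead_in,
        seed=seed,
    )


def simulate_study(
    n_subjects: int, seed: int = 0
) -> tuple[list[tuple[IMURecording, GroundTruth]], pd.Series]:
    """End-to-end study: latent capacities → kinematics → raw recordings.

    Returns the recordings (with ground truth) and the latent capacity per
    subject, so the full pipeline can run from raw signals alone.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_subjects)
    recordings = []
    for i, zi in enumerate(z):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = _capacity_to_kinematics(float(zi), sub_seed)
        recordings.append(simulate_recording(params, subject_id=f"S{i:04d}"))
    return recordings, pd.Series(z, name="capacity")
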