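"""Signal conditioning: FIR low-pass + moving-average filtering and the
scalar series (acceleration modulus, gravity-axis projection) that the
segmentation and feature layers consume.

All filtering is zero-phase so transition timestamps downstream are not
shifted by group delay.  Sit-to-stand movement energy lives below ~3 Hz;
the default 5 Hz cutoff keeps it intact while stripping hand tremor and
sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "DerivedSignals",
    "fir_lowpass",
    "moving_average",
    "acceleration_modulus",
    "estimate_gravity_axis",
    "derive",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filtering parameters.

    fir_cutoff : Hz, FIR low-pass cutoff (must be < fs/2)
    fir_order : taps of the (odd-length, symmetric) FIR filter
    ma_window : seconds, centered moving-average window
    """

    fir_cutoff: float = 5.0
    fir_order: int = 51
    ma_window: float = 0.25

    def validate(self, fs: float) -> None:
        if not 0 < self.fir_cutoff < fs / 2:
            raise ValueError("fir_cutoff must lie in (0, fs/2)")
        if self.fir_order < 2:
            raise ValueError("fir_order must be >= 2")
        if self.ma_window <= 0:
            raise ValueError("ma_window must be positive")


@dataclass
class DerivedSignals:
    """Filtered acceleration and the scalar series derived from it."""

    acc_filt: np.ndarray  # (n, 3), g
    acc_mod: np.ndarray  # (n,), g — Euclidean norm of acc_filt
    g_axis: np.ndarray  # (3,), unit gravity direction in the sensor frame
    acc_grav: np.ndarray  # (n,), g — raw acceleration projected on g_axis
    acc_grav_filt: np.ndarray  # (n,), g — filtered projection


def fir_lowpass(series: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase FIR low-pass (Hamming-window design, unit DC gain).

    Applied forward-backward, so the effective magnitude response is the
    design response squared; phase is exactly zero and length is preserved.
    """
    series = np.asarray(series, dtype=float)
    spec.validate(fs)
    numtaps = spec.fir_order | 1  # odd taps -> integer group delay, type I
    n = series.shape[-1]
    if n <= numtaps:
        raise ValueError(f"series length {n} too short for a {numtaps}-tap filter")
    taps = sps.firwin(numtaps, spec.fir_cutoff, fs=fs, window="hamming")
    padlen = min(3 * numtaps, n - 1)
    return sps.filtfilt(taps, [1.0], series, axis=-1, padlen=padlen)


def moving_average(series: np.ndarray, window: float, fs: float) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` is in seconds; it is converted to samples and must cover at
    least 2 samples.  Constant input maps to itself.
    """
    series = np.asarray(series, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    k = max(2, int(round(window * fs)))
    kernel = np.ones(k)
    num = np.convolve(series, kernel, mode="same")
    cnt = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / cnt


def acceleration_modulus(acc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration axes."""
    acc = np.asarray(acc, dtype=float)
    if np.isnan(acc).any():
        raise ValueError("NaN in acceleration")
    return np.linalg.norm(acc, axis=-1)


def estimate_gravity_axis(
    acc: np.ndarray, fs: float, *, smooth_window: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the gravity direction and project acceleration onto it.

    The direction is the normalized mean of heavily smoothed acceleration
    (2 s moving average), i.e. the dominant quasi-static component; body
    accelerations average out over a ≥5 s recording.  Returns
    ``(g_axis, projection)`` where projection is the raw acceleration dotted
    with the unit gravity vector (in g: ≈1 when still and upright).
    """
    acc = np.asarray(acc, dtype=float)
    if acc.shape[0] < int(5 * fs):
        raise ValueError("need at least 5 s of data to estimate gravity")
    smooth = np.column_stack(
        [moving_average(acc[:, k], smooth_window, fs) for k in range(3)]
    )
    mean_vec = smooth.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm < 0.1:
        raise ValueError("near-zero mean acceleration; cannot estimate gravity")
    g_axis = mean_vec / norm
    return g_axis, acc @ g_axis


def derive(recording, spec: FilterSpec | None = None) -> DerivedSignals:
    """Compute all derived signals for a recording."""
    spec = spec or FilterSpec()
    fs = recording.fs
    acc_filt = np.column_stack(
        [
            moving_average(fir_lowpass(recording.acc[:, k], spec, fs), spec.ma_window, fs)
            for k in range(3)
        ]
    )
    acc_mod = acceleration_modulus(acc_filt)
    g_axis, acc_grav = estimate_gravity_axis(recording.acc, fs)
    grav_filt = moving_average(fir_lowpass(acc_grav, spec, fs), spec.ma_window, fs)
    return DerivedSignals(
        acc_filt=acc_filt,
        acc_mod=acc_mod,
        g_axis=g_axis,
        acc_grav=acc_grav,
        acc_grav_filt=grav_filt,
    )
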