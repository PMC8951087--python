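"""Windowing and the two PPG filtering procedures.

Procedure 1 isolates the cardiac band (0.5–2.75 Hz band-pass, moving average,
winsorization) and feeds pulse-peak detection.  Procedure 2 isolates the
respiration band (0.15–0.4 Hz band-pass, moving average) and feeds the
frequency-domain respiration features directly.  Filters are third-order
Butterworth applied zero-phase (forward–backward), so pulse timing is not
biased by phase distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic_data import RawRecording


def bandpass(x, fs: float, low: float, high: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass; length-preserving."""
    x = np.asarray(x, dtype=float)
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) for fs={fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def moving_average(x, width_samples: int) -> np.ndarray:
    """Centered moving average; the kernel shrinks at the edges (no padding bias)."""
    x = np.asarray(x, dtype=float)
    w = int(width_samples)
    if w < 1 or w % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    if w == 1 or len(x) == 0:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def winsorize(x, lower_pct: float = 1.0, upper_pct: float = 99.0) -> np.ndarray:
    """Clamp values outside the [lower_pct, upper_pct] percentile bounds to the bounds."""
    x = np.asarray(x, dtype=float)
    if not (0.0 <= lower_pct < upper_pct <= 100.0):
        raise ValueError("percentile bounds must satisfy 0 <= lower < upper <= 100")
    if len(x) == 0:
        return x.copy()
    lo, hi = np.percentile(x, [lower_pct, upper_pct])
    return np.clip(x, lo, hi)


def filter_procedure_1(
    ppg_raw,
    fs: float,
    band: tuple[float, float] = (0.5, 2.75),
    order: int = 3,
    ma_width: int = 5,
    winsor_limits: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Cardiac-band filtering chain used before pulse-peak detection."""
    y = bandpass(ppg_raw, fs, band[0], band[1], order=order)
    y = moving_average(y, ma_width)
    return winsorize(y, *winsor_limits)


def filter_procedure_2(
    ppg_raw,
    fs: float,
    band: tuple[float, float] = (0.15, 0.4),
    order: int = 3,
    ma_width: int = 25,
) -> np.ndarray:
    """Respiration-band filtering chain feeding the PPG spectral features."""
    y = bandpass(ppg_raw, fs, band[0], band[1], order=order)
    return moving_average(y, ma_width)


@dataclass
class WindowBundle:
    """One analysis window: raw slices, both filtered variants, and its label."""

    subject_id: str
    start_s: float
    window_s: float
    fs_ppg: float
    fs_accel: float
    ppg_raw: np.ndarray
    ppg_cardiac: np.ndarray
    ppg_resp: np.ndarray
    accel_mag: np.ndarray
    label_bpm: float
    straddles_boundary: bool = False


def segment(
    recording: RawRecording,
    window_s: float = 20.0,
    slide_s: float = 1.0,
    filter_params: dict | None = None,
) -> list[WindowBundle]:
    """Slice a recording into overlapping windows and filter each one.

    Windows start at 0, slide, 2·slide, …; the last window lies fully inside
    the recording.  The label is the duration-weighted mean of the true
    breathing rate over the window; windows that straddle a protocol-segment
    boundary keep that weighted label and are flagged.  A recording shorter
    than one window yields an empty list with a warning.
    """
    if slide_s <= 0:
        raise ValueError("slide_s must be positive")
    fp = filter_params or {}
    duration = recording.duration_s
    if duration < window_s:
        warnings.warn(
            f"recording {recording.subject_id} shorter than one {window_s}-s window",
            stacklevel=2,
        )
        return []
    mag = np.linalg.norm(recording.accel, axis=1)
    windows: list[WindowBundle] = []
    n_windows = int(np.floor((duration - window_s) / slide_s)) + 1
    for k in range(n_windows):
        start = k * slide_s
        i0, i1 = int(round(start * recording.fs_ppg)), int(
            round((start + window_s) * recording.fs_ppg)
        )
        a0, a1 = int(round(start * recording.fs_accel)), int(
            round((start + window_s) * recording.fs_accel)
        )
        ppg_raw = recording.ppg[i0:i1]
        truth = recording.truth_br[i0:i1]
        windows.append(
            WindowBundle(
                subject_id=recording.subject_id,
                start_s=start,
                window_s=window_s,
                fs_ppg=recording.fs_ppg,
                fs_accel=recording.fs_accel,
                ppg_raw=ppg_raw,
                ppg_cardiac=filter_procedure_1(
                    ppg_raw, recording.fs_ppg, **fp.get("procedure_1", {})
                ),
                ppg_resp=filter_procedure_2(
                    ppg_raw, recording.fs_ppg, **fp.get("procedure_2", {})
                ),
                accel_mag=mag[a0:a1],
                label_bpm=float(np.mean(truth)),
                straddles_boundary=bool(np.ptp(truth) > 1e-9),
            )
        )
    return windows
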