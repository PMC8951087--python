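"""Accelerometer-based signal-quality assessment and motion-artifact rejection.

Movement is quantified per second as the absolute sum of changes of the
acceleration-magnitude signal.  Seconds whose value exceeds a threshold
calibrated on low-motion reference data are marked bad.  Two rules then gate
the two PPG processing paths:

* Rule 1 (time-domain / P-P extraction): excise bad seconds; keep the window
  only if at least ``min_clean_s`` seconds of clean signal remain.
* Rule 2 (frequency-domain respiration features): discard the window if a run
  of ``run_len`` or more consecutive bad seconds occurs anywhere except
  anchored at the very beginning or end of the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import WindowBundle


def acc_magnitude(ax, ay=None, az=None) -> np.ndarray:
    """Euclidean norm of the three acceleration axes.

    Accepts either three equal-length vectors or a single (n, 3) array.
    """
    if ay is None:
        arr = np.asarray(ax, dtype=float)
        return np.linalg.norm(arr, axis=1)
    return np.sqrt(
        np.asarray(ax, dtype=float) ** 2
        + np.asarray(ay, dtype=float) ** 2
        + np.asarray(az, dtype=float) ** 2
    )


def abs_sum_changes(x) -> float:
    """Sum of absolute first differences, sum_i |x[i+1] - x[i]|."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def calibrate_threshold(
    asc_values, mode: str = "tukey", percentile: float = 99.0
) -> float:
    """Upper-extreme threshold of pooled per-second motion scores from low-motion data.

    ``mode="tukey"`` (default) returns the Tukey upper fence Q3 + 1.5·IQR,
    which is robust to a single glitch in the calibration data; ``"max"`` and
    ``"percentile"`` are alternatives.  Requires at least 30 values.
    """
    v = np.asarray(asc_values, dtype=float)
    if v.size < 30:
        raise ValueError("need at least 30 calibration values")
    if mode == "tukey":
        q1, q3 = np.percentile(v, [25.0, 75.0])
        return float(q3 + 1.5 * (q3 - q1))
    if mode == "max":
        return float(np.max(v))
    if mode == "percentile":
        return float(np.percentile(v, percentile))
    raise ValueError(f"unknown threshold mode {mode!r}")


def _runs(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    """Half-open (start, end) index runs where ``mask == value``."""
    mask = np.asarray(mask, dtype=bool)
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m == value and start is None:
            start = i
        elif m != value and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def rule1_apply(bad_mask, min_clean_s: int = 15) -> tuple[bool, list[tuple[int, int]]]:
    """Excision rule for the P-P extraction path.

    Returns ``(keep, clean_segments)`` where ``clean_segments`` are the
    maximal runs of clean seconds (half-open, in seconds from window start)
    and ``keep`` is true iff the total clean duration is at least
    ``min_clean_s`` seconds.
    """
    bad = np.asarray(bad_mask, dtype=bool)
    clean_segments = _runs(bad, False)
    keep = int(np.sum(~bad)) >= min_clean_s
    return keep, clean_segments


def rule2_apply(bad_mask, run_len: int = 3) -> bool:
    """Whole-window rule for the respiration-band spectral path.

    Discard iff a run of at least ``run_len`` consecutive bad seconds exists
    that is not anchored at the first or last second of the window (an
    edge-anchored run of any length is exempt).
    """
    bad = np.asarray(bad_mask, dtype=bool)
    n = len(bad)
    for start, end in _runs(bad, True):
        if end - start >= run_len and start != 0 and end != n:
            return False
    return True


@dataclass
class QualityReport:
    """Per-window motion scores, threshold, and the two rule verdicts."""

    asc_per_second: np.ndarray
    threshold: float
    bad_mask: np.ndarray
    rule1_keep: bool
    rule1_clean_seconds: int
    clean_segments: list[tuple[int, int]]  # seconds, half-open
    rule2_keep: bool


def assess(
    window: WindowBundle,
    threshold: float,
    min_clean_s: int = 15,
    run_len: int = 3,
) -> QualityReport:
    """Score every 1-s accelerometer-magnitude slice and apply both rules."""
    fs = window.fs_accel
    n_seconds = int(round(len(window.accel_mag) / fs))
    asc = np.array(
        [
            abs_sum_changes(window.accel_mag[int(i * fs) : int((i + 1) * fs)])
            for i in range(n_seconds)
        ]
    )
    bad = asc > threshold
    rule1_keep, clean_segments = rule1_apply(bad, min_clean_s=min_clean_s)
    return QualityReport(
        asc_per_second=asc,
        threshold=float(threshold),
        bad_mask=bad,
        rule1_keep=rule1_keep,
        rule1_clean_seconds=int(np.sum(~bad)),
        clean_segments=clean_segments,
        rule2_keep=rule2_apply(bad, run_len=run_len),
    )


def calibration_values(recordings, fs_accel: float | None = None) -> np.ndarray:
    """Pool per-second motion scores over whole recordings (for threshold calibration)."""
    values = []
    for rec in recordings:
        mag = acc_magnitude(rec.accel)
        fs = fs_accel or rec.fs_accel
        n_seconds = int(len(mag) // fs)
        for i in range(n_seconds):
            values.append(abs_sum_changes(mag[int(i * fs) : int((i + 1) * fs)]))
    return np.asarray(values)
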