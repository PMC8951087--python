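"""Systolic-peak detection and P-P interval series extraction.

The detector is an adaptive-threshold local-maximum search: candidate peaks
must clear a rolling-percentile amplitude floor and be separated by a minimum
distance derived from a coarse Welch estimate of the dominant cardiac
frequency (never below 60/220 s, the physiological ceiling of 220 beats/min).
Intervals are indexed at the time of their closing peak, outliers are removed
with a Hampel filter, and the cleaned series is oversampled to 25 Hz with a
quadratic interpolant for spectral analysis.  Interpolation never bridges
excised (motion-corrupted) gaps: only the longest run of valid intervals is
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, signal

MIN_PEAK_SEPARATION_S = 60.0 / 220.0


@dataclass
class PPIntervals:
    """P-P intervals indexed at the closing peak; ``valid`` marks intervals
    whose two bounding peaks lie inside the same clean segment."""

    onset_times: np.ndarray  # time of the later peak of each pair, s
    intervals: np.ndarray  # s
    valid: np.ndarray  # bool


@dataclass
class PulseSeries:
    """Peak times, interval series and its evenly resampled version for one window."""

    peak_times: np.ndarray
    pp: PPIntervals
    interp_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    interp_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    undetectable: bool = False


def _dominant_cardiac_freq(x: np.ndarray, fs: float, band=(0.5, 2.75)) -> float:
    nper = min(len(x), int(8 * fs))
    if nper < 16:
        return 1.2
    f, p = signal.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel) or np.max(p[sel]) <= 0:
        return 1.2
    return float(f[sel][np.argmax(p[sel])])


def detect_peaks(
    ppg_cardiac,
    fs: float,
    clean_segments: list[tuple[float, float]] | None = None,
    floor_percentile: float = 60.0,
    floor_window_s: float = 2.0,
) -> np.ndarray:
    """Return systolic peak times (s from window start) in cardiac-band PPG.

    ``clean_segments`` are half-open (start_s, end_s) spans; peaks outside
    them are dropped.  Fewer than two retained peaks means the window is
    pulse-undetectable (callers flag it via :func:`extract_pulse`).
    """
    x = np.asarray(ppg_cardiac, dtype=float)
    if len(x) < 4 or np.allclose(x, x[0]):
        return np.empty(0)
    f_card = _dominant_cardiac_freq(x, fs)
    distance = int(round(fs * max(MIN_PEAK_SEPARATION_S, 0.6 / f_card)))
    floor = ndimage.percentile_filter(
        x, floor_percentile, size=int(floor_window_s * fs) | 1, mode="nearest"
    )
    prominence = 0.25 * float(np.std(x))
    idx, _ = signal.find_peaks(
        x, distance=max(distance, 1), height=floor, prominence=prominence
    )
    times = idx / fs
    if clean_segments is not None:
        keep = np.zeros(len(times), dtype=bool)
        for s0, s1 in clean_segments:
            keep |= (times >= s0) & (times < s1)
        times = times[keep]
    return times


def pp_from_peaks(
    peak_times, clean_segments: list[tuple[float, float]] | None = None
) -> PPIntervals:
    """Successive peak-time differences; an interval is valid only if both
    bounding peaks lie inside one clean segment (no bridging of excised gaps)."""
    pk = np.asarray(peak_times, dtype=float)
    if len(pk) < 2:
        return PPIntervals(np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    intervals = np.diff(pk)
    onsets = pk[1:]
    if clean_segments is None:
        valid = np.ones(len(intervals), dtype=bool)
    else:
        valid = np.zeros(len(intervals), dtype=bool)
        for s0, s1 in clean_segments:
            valid |= (pk[:-1] >= s0) & (pk[:-1] < s1) & (onsets >= s0) & (onsets < s1)
    return PPIntervals(onsets, intervals, valid)


def hampel_filter(values, half_window: int = 3, n_sigmas: float = 3.0) -> np.ndarray:
    """Replace points deviating from the local median by more than
    ``n_sigmas`` scaled MADs (1.4826·MAD) with that local median."""
    x = np.asarray(values, dtype=float).copy()
    n = len(x)
    orig = x.copy()
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        w = orig[lo:hi]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if np.abs(orig[i] - med) > n_sigmas * 1.4826 * mad:
            x[i] = med
    return x


def hampel_pp(pp: PPIntervals, half_window: int = 3, n_sigmas: float = 3.0) -> PPIntervals:
    """Apply the Hampel filter within each maximal run of valid intervals."""
    vals = pp.intervals.copy()
    for run in _valid_runs(pp.valid):
        lo, hi = run
        vals[lo:hi] = hampel_filter(vals[lo:hi], half_window, n_sigmas)
    return PPIntervals(pp.onset_times, vals, pp.valid)


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(valid):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(valid)))
    return runs


def interpolate_pp(
    pp: PPIntervals, target_fs: float = 25.0
) -> tuple[np.ndarray, np.ndarray] | None:
    """Quadratically oversample the longest run of valid intervals to ``target_fs``.

    Returns ``(times, values)`` on an even grid spanning the run's interval
    onsets, or ``None`` when fewer than three valid intervals are available
    (a quadratic needs three knots); interpolation across excised gaps is
    deliberately forbidden.
    """
    runs = _valid_runs(pp.valid)
    if not runs:
        return None
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    if hi - lo < 3:
        return None
    t_knots = pp.onset_times[lo:hi]
    v_knots = pp.intervals[lo:hi]
    f = interpolate.interp1d(t_knots, v_knots, kind="quadratic", assume_sorted=True)
    span = t_knots[-1] - t_knots[0]
    n = int(np.floor(span * target_fs)) + 1
    times = t_knots[0] + np.arange(n) / target_fs
    # float rounding can push the final grid point a ulp past the last knot
    times = np.minimum(times, t_knots[-1])
    return times, f(times)


def extract_pulse(
    ppg_cardiac,
    fs: float,
    clean_segments: list[tuple[float, float]] | None = None,
    hampel_half_window: int = 3,
    hampel_n_sigmas: float = 3.0,
    target_fs: float = 25.0,
) -> PulseSeries:
    """Full pulse chain: detect peaks, build/clean the P-P series, oversample it."""
    peaks = detect_peaks(ppg_cardiac, fs, clean_segments)
    pp = pp_from_peaks(peaks, clean_segments)
    if len(peaks) < 2 or not np.any(pp.valid):
        return PulseSeries(peaks, pp, undetectable=True)
    pp = hampel_pp(pp, hampel_half_window, hampel_n_sigmas)
    interp = interpolate_pp(pp, target_fs)
    if interp is None:
        return PulseSeries(peaks, pp, undetectable=True)
    times, values = interp
    return PulseSeries(peaks, pp, times, values, undetectable=False)
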