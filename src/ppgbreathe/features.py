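"""The four feature groups computed per analysis window.

* PRV (4): time-domain pulse-rate-variability summaries of the P-P intervals.
* RR_PSD (20): Welch power-spectral-density features of the oversampled P-P
  interval series (5 dominant frequencies + 5 normalized amplitudes + a
  10-bin magnitude distribution over 0–2 Hz).
* PEAK_VALLEY (9): peak-to-following-valley geometry of the oversampled P-P
  series (amplitude/duration/speed deltas, each aggregated by median/min/max).
* PPG_PSD (20): the same 20 spectral features computed from the
  respiration-band filtered PPG.

Group availability is gated by the quality rules: Rule 1 licenses the three
P-P-derived groups, Rule 2 licenses the PPG spectral group.  Missing groups
are encoded as NaN so a tree model with native missing-value support can
consume partial vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import WindowBundle, moving_average
from .pulse import PPIntervals, PulseSeries
from .quality import QualityReport

PRV_FEATURES = ["prv_pp_std", "prv_increase_time", "prv_pp_median", "prv_peaks_per_sec"]


def _psd_names(prefix: str) -> list[str]:
    return (
        [f"{prefix}_dom{i}_freq" for i in range(1, 6)]
        + [f"{prefix}_dom{i}_amp" for i in range(1, 6)]
        + [f"{prefix}_bin{i}" for i in range(1, 11)]
    )


RR_PSD_FEATURES = _psd_names("rr")
PPG_PSD_FEATURES = _psd_names("ppg")
PEAK_VALLEY_FEATURES = [
    f"pv_{metric}_{stat}"
    for metric in ("amp", "dur", "speed")
    for stat in ("median", "min", "max")
]
ALL_FEATURES = PRV_FEATURES + RR_PSD_FEATURES + PEAK_VALLEY_FEATURES + PPG_PSD_FEATURES

FEATURE_GROUPS = {
    "PRV": PRV_FEATURES,
    "RR_PSD": RR_PSD_FEATURES,
    "PEAK_VALLEY": PEAK_VALLEY_FEATURES,
    "PPG_PSD": PPG_PSD_FEATURES,
}


@dataclass
class Spectrum:
    """One-sided PSD on an ascending grid from 0 to the Nyquist frequency."""

    frequencies: np.ndarray
    power: np.ndarray


def welch_psd(
    series,
    fs: float,
    seg_s: float = 10.0,
    overlap: float = 0.5,
    grid_hz: float = 0.025,
) -> Spectrum:
    """Welch PSD (Hann window, 50% overlap by default), zero-padded so the
    frequency grid spacing is at most ``grid_hz``."""
    x = np.asarray(series, dtype=float)
    nperseg = int(min(len(x), round(seg_s * fs)))
    nfft = max(nperseg, int(2 ** np.ceil(np.log2(max(fs / grid_hz, 2)))))
    f, p = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        nfft=nfft,
        detrend="constant",
    )
    return Spectrum(f, p)


def prv_features(pp: PPIntervals, n_peaks: int | None = None, window_s: float = 20.0) -> dict:
    """Time-domain PRV summaries of the valid P-P intervals.

    ``prv_increase_time`` is the mean duration, in seconds of signal time, of
    the maximal strictly-increasing runs of consecutive intervals (a run's
    duration is the sum of its intervals; runs shorter than two intervals do
    not count; 0 when no interval ever increases).  Returns NaNs when fewer
    than two valid intervals exist.
    """
    vals = pp.intervals[pp.valid]
    if len(vals) < 2:
        return {k: np.nan for k in PRV_FEATURES}
    if n_peaks is None:
        n_peaks = len(vals) + 1
    runs = []
    run = [vals[0]]
    for prev, cur in zip(vals[:-1], vals[1:]):
        if cur > prev:
            run.append(cur)
        else:
            if len(run) >= 2:
                runs.append(sum(run))
            run = [cur]
    if len(run) >= 2:
        runs.append(sum(run))
    return {
        "prv_pp_std": float(np.std(vals)),
        "prv_increase_time": float(np.mean(runs)) if runs else 0.0,
        "prv_pp_median": float(np.median(vals)),
        "prv_peaks_per_sec": float(n_peaks) / float(window_s),
    }


def psd_features(spectrum: Spectrum, prefix: str, bin_range: tuple[float, float] = (0.0, 2.0)) -> dict:
    """Five dominant spectral peaks plus a 10-bin magnitude distribution.

    Peaks of the PSD are ranked by power; amplitudes (sqrt of power) are
    normalized by the largest peak's amplitude, so the first is always 1.
    The binned distribution sums sqrt-power magnitudes into 10 equal-width
    bins over ``bin_range`` and normalizes them to unit sum, making the bins
    a distribution over the sub-2-Hz band.  Missing peak slots are zero.
    """
    f, p = spectrum.frequencies, spectrum.power
    out = {k: 0.0 for k in _psd_names(prefix)}
    peak_idx, _ = signal.find_peaks(p)
    if len(peak_idx):
        order = peak_idx[np.argsort(p[peak_idx])[::-1]][:5]
        amps = np.sqrt(p[order])
        ref = amps[0] if amps[0] > 0 else 1.0
        for i, (fi, ai) in enumerate(zip(f[order], amps), start=1):
            out[f"{prefix}_dom{i}_freq"] = float(fi)
            out[f"{prefix}_dom{i}_amp"] = float(ai / ref)
    edges = np.linspace(bin_range[0], bin_range[1], 11)
    mag = np.sqrt(p)
    bins = np.array(
        [float(np.sum(mag[(f >= edges[i]) & (f < edges[i + 1])])) for i in range(10)]
    )
    total = bins.sum()
    if total > 0:
        bins = bins / total
    for i in range(10):
        out[f"{prefix}_bin{i + 1}"] = float(bins[i])
    return out


def peak_valley_features(
    interp_times,
    interp_values,
    fs: float = 25.0,
    smooth_s: float = 0.4,
    prominence_frac: float = 0.05,
) -> dict:
    """Peak-to-following-valley geometry of the oversampled P-P series.

    Each detected peak is paired with the first valley after it; the pair
    yields an amplitude delta (s), a duration delta (s) and their ratio
    (speed).  The three metrics are aggregated by median, min and max.
    Returns NaNs when no peak-valley pair exists.
    """
    missing = {k: np.nan for k in PEAK_VALLEY_FEATURES}
    t = np.asarray(interp_times, dtype=float)
    x = np.asarray(interp_values, dtype=float)
    if len(x) < 5:
        return missing
    width = int(round(smooth_s * fs)) | 1
    xs = moving_average(x, width)
    prom = prominence_frac * float(np.ptp(xs))
    if prom <= 0:
        return missing
    peaks, _ = signal.find_peaks(xs, prominence=prom)
    valleys, _ = signal.find_peaks(-xs, prominence=prom)
    amp, dur, speed = [], [], []
    for pk in peaks:
        nxt = valleys[valleys > pk]
        if not len(nxt):
            continue
        v = nxt[0]
        a = xs[pk] - xs[v]
        d = t[v] - t[pk]
        if d <= 0:
            continue
        amp.append(a)
        dur.append(d)
        speed.append(a / d)
    if not amp:
        return missing
    out = {}
    for metric, vals in (("amp", amp), ("dur", dur), ("speed", speed)):
        out[f"pv_{metric}_median"] = float(np.median(vals))
        out[f"pv_{metric}_min"] = float(np.min(vals))
        out[f"pv_{metric}_max"] = float(np.max(vals))
    return out


def assemble(
    window: WindowBundle,
    pulse: PulseSeries | None,
    quality: QualityReport,
    welch_params: dict | None = None,
) -> dict:
    """Compute the quality-licensed feature groups for one window.

    Rule 1 licenses the PRV, RR_PSD and PEAK_VALLEY groups (all derived from
    the P-P series); Rule 2 licenses the PPG_PSD group (derived from the
    respiration-band PPG).  Unlicensed or uncomputable groups are NaN.
    """
    wp = welch_params or {}
    feats = {k: np.nan for k in ALL_FEATURES}
    pulse_ok = pulse is not None and not pulse.undetectable
    if quality.rule1_keep and pulse_ok:
        feats.update(
            prv_features(pulse.pp, n_peaks=len(pulse.peak_times), window_s=window.window_s)
        )
        detrended = pulse.interp_values - np.mean(pulse.interp_values)
        feats.update(psd_features(welch_psd(detrended, fs=25.0, **wp), "rr"))
        feats.update(
            peak_valley_features(pulse.interp_times, pulse.interp_values, fs=25.0)
        )
    if quality.rule2_keep:
        feats.update(psd_features(welch_psd(window.ppg_resp, window.fs_ppg, **wp), "ppg"))
    return feats
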