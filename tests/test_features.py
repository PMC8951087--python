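"""The four feature groups and their assembly under quality gating."""

import numpy as np
import pytest

from ppgbreathe.features import (
    ALL_FEATURES,
    FEATURE_GROUPS,
    Spectrum,
    assemble,
    peak_valley_features,
    prv_features,
    psd_features,
    welch_psd,
)
from ppgbreathe.pulse import PPIntervals, extract_pulse
from ppgbreathe.preprocessing import segment
from ppgbreathe.quality import assess


def _pp(vals, t0=0.0):
    vals = np.asarray(vals, dtype=float)
    t = t0 + np.cumsum(vals)
    return PPIntervals(t, vals, np.ones(len(vals), dtype=bool))


class TestPRV:
    def test_constant_intervals(self):
        pp = _pp([1.0] * 19)
        f = prv_features(pp, n_peaks=20, window_s=20.0)
        assert f["prv_pp_std"] == 0.0
        assert f["prv_pp_median"] == 1.0
        assert f["prv_peaks_per_sec"] == pytest.approx(1.0)
        assert f["prv_increase_time"] == 0.0  # nothing ever increases

    def test_median_example(self):
        f = prv_features(_pp([0.8, 0.9, 1.0, 0.9]))
        assert f["prv_pp_median"] == pytest.approx(0.9)

    def test_increase_time_hand_enumeration(self):
        # runs of strictly increasing intervals: [0.8,0.9,1.0] (2.7 s of signal)
        # and [0.9,1.0] (1.9 s); mean run duration = 2.3 s
        f = prv_features(_pp([0.8, 0.9, 1.0, 0.9, 1.0]))
        assert f["prv_increase_time"] == pytest.approx((2.7 + 1.9) / 2)

    def test_insufficient_intervals_marked_missing(self):
        f = prv_features(_pp([0.8]))
        assert all(np.isnan(v) for v in f.values())


class TestWelch:
    def test_pure_tone_bin(self):
        t = np.arange(0, 20, 1 / 25.0)
        spec = welch_psd(np.sin(2 * np.pi * 0.3 * t), fs=25.0)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(0.3, abs=0.05)

    def test_support_spans_zero_to_nyquist(self):
        spec = welch_psd(np.random.default_rng(0).standard_normal(500), fs=25.0)
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[-1] == pytest.approx(12.5)
        assert np.all(np.diff(spec.frequencies) > 0)

    def test_white_noise_flat_and_parseval(self):
        rng = np.random.default_rng(1)
        powers = []
        var_ratio = []
        for _ in range(30):
            x = rng.standard_normal(2000)
            spec = welch_psd(x, fs=25.0)
            df = spec.frequencies[1] - spec.frequencies[0]
            var_ratio.append(np.sum(spec.power) * df / np.var(x))
            lo = spec.power[(spec.frequencies > 1) & (spec.frequencies < 5)].mean()
            hi = spec.power[(spec.frequencies > 8) & (spec.frequencies < 12)].mean()
            powers.append(lo / hi)
        assert np.mean(powers) == pytest.approx(1.0, rel=0.1)
        assert np.mean(var_ratio) == pytest.approx(1.0, rel=0.1)

    def test_zero_series_zero_power(self):
        spec = welch_psd(np.zeros(500), fs=25.0)
        assert np.allclose(spec.power, 0.0)


class TestPSDFeatures:
    def _two_tone_spectrum(self, p1=4.0, p2=1.0):
        f = np.linspace(0, 12.5, 501)
        p = np.zeros_like(f)
        p[np.argmin(np.abs(f - 0.25))] = p1
        p[np.argmin(np.abs(f - 0.75))] = p2
        return Spectrum(f, p)

    def test_single_tone_self_normalized(self):
        spec = self._two_tone_spectrum(p2=0.0)
        out = psd_features(spec, "ppg")
        assert out["ppg_dom1_freq"] == pytest.approx(0.25, abs=0.02)
        assert out["ppg_dom1_amp"] == 1.0

    def test_vector_length_is_twenty(self):
        out = psd_features(self._two_tone_spectrum(), "rr")
        assert len(out) == 20
        assert sorted(out) == sorted(FEATURE_GROUPS["RR_PSD"])

    def test_amplitude_normalization_is_sqrt_power(self):
        # powers 4:1 -> amplitudes 2:1 -> normalized [1.0, 0.5]
        out = psd_features(self._two_tone_spectrum(4.0, 1.0), "ppg")
        assert out["ppg_dom1_amp"] == 1.0
        assert out["ppg_dom2_amp"] == pytest.approx(0.5)

    def test_binned_distribution_sums_to_one(self):
        out = psd_features(self._two_tone_spectrum(), "ppg")
        bins = [out[f"ppg_bin{i}"] for i in range(1, 11)]
        assert sum(bins) == pytest.approx(1.0)
        # 0.25 Hz falls in bin 2 (0.2–0.4), 0.75 Hz in bin 4 (0.6–0.8)
        assert bins[1] > 0 and bins[3] > 0


class TestPeakValley:
    def test_sine_geometry(self):
        T, a, fs = 5.0, 0.05, 25.0
        t = np.arange(0, 20, 1 / fs)
        x = 0.8 + a * np.sin(2 * np.pi * t / T)
        out = peak_valley_features(t, x, fs=fs)
        assert out["pv_amp_median"] == pytest.approx(2 * a, rel=0.05)
        assert out["pv_dur_median"] == pytest.approx(T / 2, rel=0.05)
        assert out["pv_speed_median"] == pytest.approx(4 * a / T, rel=0.1)
        assert out["pv_amp_min"] == pytest.approx(out["pv_amp_max"], rel=0.05)
        assert len(out) == 9

    def test_monotone_series_has_no_pairs(self):
        t = np.arange(0, 20, 0.04)
        out = peak_valley_features(t, 1.0 - 0.01 * t)
        assert all(np.isnan(v) for v in out.values())


@pytest.fixture(scope="module")
def window_and_pulse(clean_recording):
    win = segment(clean_recording, window_s=20.0, slide_s=20.0)[1]
    rep = assess(win, threshold=1e9)  # everything clean
    pulse = extract_pulse(
        win.ppg_cardiac, win.fs_ppg,
        clean_segments=[(float(a), float(b)) for a, b in rep.clean_segments],
    )
    return win, pulse, rep


class TestAssemble:
    def test_full_vector_has_53_named_features(self, window_and_pulse):
        win, pulse, rep = window_and_pulse
        feats = assemble(win, pulse, rep)
        assert sorted(feats) == sorted(ALL_FEATURES)
        assert len(feats) == 53
        assert not any(np.isnan(v) for v in feats.values())

    def test_dominant_ppg_frequency_matches_breathing_rate(self, window_and_pulse):
        win, pulse, rep = window_and_pulse
        feats = assemble(win, pulse, rep)
        # 12 bpm = 0.2 Hz; dominant PPG-PSD frequency within one grid bin
        assert feats["ppg_dom1_freq"] == pytest.approx(0.2, abs=0.03)
        # RR-PSD bin containing 0.2 Hz (bin 1: 0–0.2 or bin 2: 0.2–0.4) dominates
        rr_bins = [feats[f"rr_bin{i}"] for i in range(1, 11)]
        assert max(rr_bins[:2]) == max(rr_bins)

    def test_rule_gating_controls_group_availability(self, window_and_pulse):
        win, pulse, rep = window_and_pulse
        import dataclasses

        only_rule2 = dataclasses.replace(rep, rule1_keep=False)
        feats = assemble(win, pulse, only_rule2)
        assert all(np.isnan(feats[k]) for k in FEATURE_GROUPS["PRV"])
        assert all(np.isnan(feats[k]) for k in FEATURE_GROUPS["PEAK_VALLEY"])
        assert not any(np.isnan(feats[k]) for k in FEATURE_GROUPS["PPG_PSD"])

        only_rule1 = dataclasses.replace(rep, rule2_keep=False)
        feats = assemble(win, pulse, only_rule1)
        assert all(np.isnan(feats[k]) for k in FEATURE_GROUPS["PPG_PSD"])
        assert not any(np.isnan(feats[k]) for k in FEATURE_GROUPS["PRV"])

    def test_features_invariant_to_time_shift(self, clean_recording):
        # two windows with identical content but different absolute start times
        wins = segment(clean_recording, window_s=20.0, slide_s=20.0)
        w = wins[2]
        import dataclasses

        shifted = dataclasses.replace(w, start_s=w.start_s + 37.0)
        rep = assess(w, threshold=1e9)
        segs = [(float(a), float(b)) for a, b in rep.clean_segments]
        pulse = extract_pulse(w.ppg_cardiac, w.fs_ppg, clean_segments=segs)
        f1 = assemble(w, pulse, rep)
        f2 = assemble(shifted, pulse, rep)
        for k in ALL_FEATURES:
            assert f1[k] == f2[k] or (np.isnan(f1[k]) and np.isnan(f2[k]))
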