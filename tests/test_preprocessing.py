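"""Windowing and filtering-procedure contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

import ppgbreathe as pb
from ppgbreathe.preprocessing import (
    bandpass,
    filter_procedure_1,
    filter_procedure_2,
    moving_average,
    segment,
    winsorize,
)
from ppgbreathe.synthetic_data import SynthParams

FS = 25.0


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration,expected", [(140.0, 121), (20.0, 1), (40.0, 21)]
    )
    def test_window_count(self, duration, expected):
        rec = pb.generate_recording(
            pb.constant_rate_protocol([12.0], duration), SynthParams(seed=0)
        )
        assert len(segment(rec, window_s=20.0, slide_s=1.0)) == expected

    def test_short_recording_warns_and_returns_empty(self):
        rec = pb.generate_recording(
            pb.constant_rate_protocol([12.0], 19.0), SynthParams(seed=0)
        )
        with pytest.warns(UserWarning, match="shorter"):
            assert segment(rec, window_s=20.0) == []

    def test_straddling_window_gets_weighted_label(self, study_protocol):
        rec = pb.generate_recording(study_protocol, SynthParams(seed=0))
        wins = segment(rec, window_s=20.0, slide_s=1.0)
        # window starting at 50 s covers 10 s at 9 bpm and 10 s at 12 bpm
        w = next(w for w in wins if w.start_s == 50.0)
        assert w.straddles_boundary
        assert w.label_bpm == pytest.approx(10.5, abs=0.1)
        w0 = wins[0]
        assert not w0.straddles_boundary and w0.label_bpm == 9.0


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(np.full(1000, 3.7), FS, 0.5, 2.75)
        assert np.max(np.abs(out)) < 1e-6

    def test_passband_tone_matches_design_response(self):
        # amplitude after zero-phase filtering must equal |H(f)|^2 from the design
        t = np.arange(0, 120, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass(x, FS, 0.5, 2.75)
        sos = signal.butter(3, [0.5, 2.75], btype="bandpass", fs=FS, output="sos")
        _, h = signal.sosfreqz(sos, worN=[1.0], fs=FS)
        expected = np.abs(h[0]) ** 2  # forward-backward pass squares the gain
        core = slice(len(t) // 4, 3 * len(t) // 4)
        measured = np.max(np.abs(y[core]))
        assert measured == pytest.approx(expected, rel=0.02)
        assert expected > 0.95

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(0, 400, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, FS, 0.15, 0.4)
        core = slice(len(t) // 4, 3 * len(t) // 4)
        attenuation_db = -20 * np.log10(np.max(np.abs(y[core])))
        assert attenuation_db >= 20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, 2.75, 0.5)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), FS, 0.5, 13.0)


class TestMovingAverage:
    def test_constant_unchanged(self):
        x = np.full(50, 2.5)
        assert np.allclose(moving_average(x, 5), x)

    def test_impulse_spreads_to_plateau(self):
        x = np.zeros(51)
        x[25] = 1.0
        y = moving_average(x, 5)
        assert np.allclose(y[23:28], 1 / 5)
        assert y[20] == 0

    def test_white_noise_variance_reduced_by_width(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        y = moving_average(x, 9)
        assert np.var(y) == pytest.approx(np.var(x) / 9, rel=0.05)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 4)


class TestWinsorize:
    def test_interior_data_unchanged(self):
        x = np.linspace(0, 1, 100)
        assert np.allclose(winsorize(x, 0, 100), x)

    def test_spike_clamped_to_percentile_bound(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 1000)
        x[500] = 1e6
        hi = np.percentile(x, 99)
        y = winsorize(x, 1, 99)
        assert y[500] == pytest.approx(hi)
        interior = (x > np.percentile(x, 1)) & (x < hi)
        assert np.array_equal(y[interior], x[interior])

    def test_all_equal_unchanged(self):
        x = np.full(20, 3.0)
        assert np.array_equal(winsorize(x, 1, 99), x)


class TestFilterProcedures:
    def test_cardiac_chain_preserves_beat_periodicity(self):
        rec = pb.generate_recording(
            pb.constant_rate_protocol([12.0], 60.0),
            SynthParams(hr_baseline=60.0, rsa_depth=0.0, am_depth=0.0,
                        bw_amplitude=0.0, noise_sd=0.0, seed=0),
        )
        y = filter_procedure_1(rec.ppg, FS)
        y = y - y.mean()
        ac = np.correlate(y, y, mode="full")[len(y) - 1 :]
        # autocorrelation peak (excluding lag 0 region) at ~1 s for 60 beats/min
        search = ac[int(0.5 * FS) : int(1.5 * FS)]
        lag = (np.argmax(search) + int(0.5 * FS)) / FS
        assert lag == pytest.approx(1.0, abs=0.08)

    def test_cardiac_chain_rejects_respiration_band(self):
        t = np.arange(0, 60, 1 / FS)
        y = filter_procedure_1(np.sin(2 * np.pi * 0.2 * t), FS)
        assert np.max(np.abs(y[200:-200])) < 0.05

    def test_resp_chain_rejects_cardiac_band(self):
        t = np.arange(0, 60, 1 / FS)
        y = filter_procedure_2(np.sin(2 * np.pi * 1.0 * t), FS)
        assert np.max(np.abs(y[200:-200])) < 0.05

    def test_resp_chain_passes_breathing_tone(self):
        t = np.arange(0, 120, 1 / FS)
        y = filter_procedure_2(np.sin(2 * np.pi * 0.25 * t), FS)
        f, p = signal.periodogram(y, fs=FS)
        assert f[np.argmax(p)] == pytest.approx(0.25, abs=f[1] - f[0])

    def test_zero_in_zero_out_and_length_preserved(self):
        x = np.zeros(500)
        for proc in (filter_procedure_1, filter_procedure_2):
            y = proc(x, FS)
            assert len(y) == 500 and np.allclose(y, 0)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(600)
        for proc in (filter_procedure_1, filter_procedure_2):
            assert np.allclose(proc(scale * x, FS), scale * proc(x, FS), atol=1e-9 * scale)

    @pytest.mark.parametrize("rate", [9.0, 12.0, 18.0, 24.0])
    def test_resp_chain_plus_dominant_frequency_recovers_rate(self, rate):
        # the respiration-band chain followed by the dominant-frequency rule
        # recovers clean synthetic rates across the 9–24 bpm passband
        rec = pb.generate_recording(
            pb.constant_rate_protocol([rate], 60.0),
            SynthParams(noise_sd=0.0, seed=4),
        )
        y = filter_procedure_2(rec.ppg, FS)
        est = pb.baseline_ppg_dominant(y, FS)
        assert est == pytest.approx(rate, abs=1.5)  # one 0.025-Hz bin
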