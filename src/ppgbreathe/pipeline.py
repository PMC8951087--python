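"""End-to-end glue: recordings → quality-gated per-window feature table.

This is the engine behind both the CLI and the examples: it calibrates the
motion threshold, windows each recording, applies the two quality rules, runs
the pulse chain, computes the licensed feature groups and the two baseline
estimates, and returns one tidy row per window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as F
from . import pulse as P
from . import quality as Q
from .estimation import baseline_ppg_dominant, baseline_rr_dominant
from .preprocessing import segment


def calibrate_cohort_threshold(recordings, mode: str = "tukey") -> float:
    """Motion threshold from pooled per-second scores of low-motion recordings."""
    return Q.calibrate_threshold(Q.calibration_values(recordings), mode=mode)


def featurize_recording(
    recording,
    threshold: float,
    window_s: float = 20.0,
    slide_s: float = 1.0,
    min_clean_s: int = 15,
    run_len: int = 3,
    filter_params: dict | None = None,
    welch_params: dict | None = None,
) -> pd.DataFrame:
    """One feature row per analysis window of a single recording."""
    rows = []
    for win in segment(recording, window_s=window_s, slide_s=slide_s, filter_params=filter_params):
        report = Q.assess(win, threshold, min_clean_s=min_clean_s, run_len=run_len)
        pulse = None
        if report.clean_segments:
            segs = [(float(a), float(b)) for a, b in report.clean_segments]
            pulse = P.extract_pulse(win.ppg_cardiac, win.fs_ppg, clean_segments=segs)
        feats = F.assemble(win, pulse, report, welch_params=welch_params)
        pulse_ok = pulse is not None and not pulse.undetectable
        row = {
            "subject_id": win.subject_id,
            "start_s": win.start_s,
            "window_s": win.window_s,
            "label_bpm": win.label_bpm,
            "straddles_boundary": win.straddles_boundary,
            "rule1_keep": report.rule1_keep,
            "rule2_keep": report.rule2_keep,
            "pulse_ok": pulse_ok,
            "bl_ppg_bpm": baseline_ppg_dominant(
                win.ppg_resp, win.fs_ppg, welch_params=welch_params
            ),
            "bl_rr_bpm": (
                baseline_rr_dominant(pulse.interp_values, welch_params=welch_params)
                if pulse_ok
                else np.nan
            ),
        }
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)


def featurize_cohort(recordings, threshold: float, **kwargs) -> pd.DataFrame:
    """Concatenated feature tables for a list of recordings."""
    frames = [featurize_recording(rec, threshold, **kwargs) for rec in recordings]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
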