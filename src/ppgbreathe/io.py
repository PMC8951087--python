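"""Delimited-text readers and writers for recordings and results.

A recording on disk is a directory with ``ppg.csv`` (time_s, ppg),
``accel.csv`` (time_s, ax, ay, az) and a ``meta.json`` sidecar holding the
subject id, generator parameters and the ground-truth breathing-rate
segments.  The loader is column-map-driven so other CSV dialects (e.g. a
public companion dataset) can be mapped onto the same schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import (
    ACCEL_FS,
    PPG_FS,
    Protocol,
    RawRecording,
    Segment,
    SynthParams,
)

DEFAULT_COLUMN_MAP = {
    "time": "time_s",
    "ppg": "ppg",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
}


def write_recording(recording: RawRecording, path) -> Path:
    """Write one recording as ppg.csv + accel.csv + meta.json under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t_ppg = np.arange(len(recording.ppg)) / recording.fs_ppg
    pd.DataFrame({"time_s": t_ppg, "ppg": recording.ppg}).to_csv(
        path / "ppg.csv", index=False, float_format="%.8g"
    )
    t_acc = np.arange(len(recording.accel)) / recording.fs_accel
    pd.DataFrame(
        {
            "time_s": t_acc,
            "ax": recording.accel[:, 0],
            "ay": recording.accel[:, 1],
            "az": recording.accel[:, 2],
        }
    ).to_csv(path / "accel.csv", index=False, float_format="%.8g")
    edges = np.cumsum([0.0] + [s.duration_s for s in recording.protocol.segments])
    meta = {
        "subject_id": recording.subject_id,
        "protocol": recording.protocol.name,
        "truth_segments": [
            {"start_s": float(edges[i]), "end_s": float(edges[i + 1]), "bpm": s.rate_bpm}
            for i, s in enumerate(recording.protocol.segments)
        ],
        "params": {
            "hr_baseline": recording.params.hr_baseline,
            "rsa_depth": recording.params.rsa_depth,
            "am_depth": recording.params.am_depth,
            "bw_amplitude": recording.params.bw_amplitude,
            "noise_sd": recording.params.noise_sd,
            "accel_noise_sd": recording.params.accel_noise_sd,
            "seed": recording.params.seed,
            "motion_bursts": [
                [b.start_s, b.duration_s, b.intensity]
                for b in recording.params.motion_bursts
            ],
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def _validate_timebase(t: np.ndarray, fs: float, what: str) -> list[tuple[float, float]]:
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{what}: non-monotone timestamps")
    dt = np.diff(t)
    nominal = 1.0 / fs
    gap_idx = np.where(dt > 1.5 * nominal)[0]
    return [(float(t[i]), float(t[i + 1])) for i in gap_idx]


def load_recording(
    path,
    column_map: dict | None = None,
    fs_ppg: float = PPG_FS,
    fs_accel: float = ACCEL_FS,
) -> RawRecording:
    """Load a recording directory back into a :class:`RawRecording`.

    Timestamps must be strictly increasing (otherwise a descriptive error is
    raised); gaps larger than one nominal sample are flagged on the returned
    recording.  Streams sampled off the nominal rate are linearly resampled
    onto the 25/50-Hz grids.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    ppg_df = pd.read_csv(path / "ppg.csv")
    acc_df = pd.read_csv(path / "accel.csv")
    for col, df, fname in (
        (cmap["time"], ppg_df, "ppg.csv"),
        (cmap["ppg"], ppg_df, "ppg.csv"),
        (cmap["time"], acc_df, "accel.csv"),
        (cmap["ax"], acc_df, "accel.csv"),
        (cmap["ay"], acc_df, "accel.csv"),
        (cmap["az"], acc_df, "accel.csv"),
    ):
        if col not in df.columns:
            raise ValueError(f"{fname}: missing required column {col!r}")

    t_ppg = ppg_df[cmap["time"]].to_numpy(dtype=float)
    t_acc = acc_df[cmap["time"]].to_numpy(dtype=float)
    gaps = _validate_timebase(t_ppg, fs_ppg, "ppg.csv") + _validate_timebase(
        t_acc, fs_accel, "accel.csv"
    )

    duration = min(t_ppg[-1] + 1.0 / fs_ppg, t_acc[-1] + 1.0 / fs_accel)
    grid_ppg = np.arange(int(round(duration * fs_ppg))) / fs_ppg
    grid_acc = np.arange(int(round(duration * fs_accel))) / fs_accel
    ppg = np.interp(grid_ppg, t_ppg, ppg_df[cmap["ppg"]].to_numpy(dtype=float))
    accel = np.column_stack(
        [
            np.interp(grid_acc, t_acc, acc_df[cmap[a]].to_numpy(dtype=float))
            for a in ("ax", "ay", "az")
        ]
    )

    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        segments = tuple(
            Segment("constant", s["end_s"] - s["start_s"], s["bpm"])
            for s in meta["truth_segments"]
        )
        protocol = Protocol(name=meta.get("protocol", "loaded"), segments=segments)
        p = meta.get("params", {})
        bursts = p.pop("motion_bursts", [])
        from .synthetic_data import MotionBurst

        params = SynthParams(
            motion_bursts=tuple(MotionBurst(*b) for b in bursts), **p
        )
        subject_id = meta.get("subject_id", path.name)
    else:
        # Unlabeled data: a flat placeholder truth of 12 bpm marks "unknown".
        protocol = Protocol(
            name="unlabeled", segments=(Segment("constant", duration, 12.0),)
        )
        params = SynthParams()
        subject_id = path.name
    truth = protocol.rate_at(grid_ppg)
    return RawRecording(
        subject_id=subject_id,
        protocol=protocol,
        params=params,
        ppg=ppg,
        accel=accel,
        truth_br=truth,
        fs_ppg=fs_ppg,
        fs_accel=fs_accel,
        gap_flags=tuple(gaps),
    )


def write_cohort(recordings, root) -> Path:
    """Write each recording to ``root/<subject_id>/`` plus a cohort manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, root / rec.subject_id)
    (root / "cohort.json").write_text(
        json.dumps({"subjects": [r.subject_id for r in recordings]}, indent=2)
    )
    return root


def load_cohort(root, column_map: dict | None = None) -> list[RawRecording]:
    root = Path(root)
    manifest = json.loads((root / "cohort.json").read_text())
    return [load_recording(root / s, column_map) for s in manifest["subjects"]]
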