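"""Protocol-driven synthetic PPG + accelerometer recordings with breathing-rate truth.

The generator emulates the three respiratory modulations of a PPG signal —
baseline wander (BW), pulse-amplitude modulation (AM) and frequency modulation
(FM, the respiratory sinus arrhythmia) — on top of a beat-by-beat two-Gaussian
pulse template, together with a gravity-plus-noise tri-axial accelerometer
stream.  Intermittent motion bursts corrupt both streams simultaneously, which
is what the accelerometer-based quality rules key on.

Sampling rates are fixed at 25 Hz (PPG) and 50 Hz (accelerometer), matching
the forehead-mounted sensor system the guided-breathing protocols were
recorded with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

PPG_FS = 25.0
ACCEL_FS = 50.0

#: beats-per-minute range accepted for breathing-rate segments
_BR_MIN, _BR_MAX = 4.0, 40.0


@dataclass(frozen=True)
class Segment:
    """One protocol segment: either a constant guided rate or repeated guided breaths.

    ``kind`` is ``"constant"`` (breathe at ``rate_bpm`` for ``duration_s``) or
    ``"guided"`` (``repetitions`` breath cycles of ``breath_s`` each followed by
    a ``pause_s`` break; nominal rate is ``60/(breath_s+pause_s)`` bpm).
    """

    kind: str
    duration_s: float
    rate_bpm: float
    breath_s: float | None = None
    pause_s: float | None = None
    repetitions: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "guided"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if not (_BR_MIN <= self.rate_bpm <= _BR_MAX):
            raise ValueError(
                f"rate {self.rate_bpm:.2f} bpm outside [{_BR_MIN}, {_BR_MAX}]"
            )


@dataclass(frozen=True)
class Protocol:
    """An ordered list of breathing segments with a name."""

    name: str
    segments: tuple[Segment, ...]

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant nominal breathing rate (bpm) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        edges = np.cumsum([0.0] + [s.duration_s for s in self.segments])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1)
        rates = np.array([s.rate_bpm for s in self.segments])
        out[:] = rates[idx]
        return out


def build_protocol(name: str, pause_s: float = 1.0) -> Protocol:
    """Return one of the named study protocols.

    ``dataset1``: guided breaths of 3 s (10 reps), 5 s (8 reps) and 8 s
    (6 reps), each cycle followed by a ``pause_s`` break.  ``dataset2a``:
    five 60-s sessions at a constant 8, 12, 18, 12, 8 bpm.  ``dataset2b``:
    five 120-s sessions at 12, 14, 16, 14, 12 bpm.

    The exact pause bookkeeping of the guided protocol is exposed as
    ``pause_s`` because the session arithmetic is under-determined; the
    default of one 1-s break per breath cycle gives a 142-s session.
    """
    if name == "dataset1":
        segs = []
        for breath_s, reps in ((3.0, 10), (5.0, 8), (8.0, 6)):
            cycle = breath_s + pause_s
            segs.append(
                Segment(
                    kind="guided",
                    duration_s=reps * cycle,
                    rate_bpm=60.0 / cycle,
                    breath_s=breath_s,
                    pause_s=pause_s,
                    repetitions=reps,
                )
            )
        return Protocol(name=name, segments=tuple(segs))
    if name == "dataset2a":
        rates = (8.0, 12.0, 18.0, 12.0, 8.0)
        return Protocol(
            name=name,
            segments=tuple(Segment("constant", 60.0, r) for r in rates),
        )
    if name == "dataset2b":
        rates = (12.0, 14.0, 16.0, 14.0, 12.0)
        return Protocol(
            name=name,
            segments=tuple(Segment("constant", 120.0, r) for r in rates),
        )
    raise ValueError(f"unknown protocol name {name!r}")


def constant_rate_protocol(rates_bpm, segment_s: float = 60.0, name: str = "custom") -> Protocol:
    """A protocol of consecutive constant-rate segments (one per entry of ``rates_bpm``)."""
    return Protocol(
        name=name,
        segments=tuple(Segment("constant", float(segment_s), float(r)) for r in rates_bpm),
    )


@dataclass(frozen=True)
class MotionBurst:
    """A motion episode: ``start_s``..``start_s+duration_s`` with amplitude ``intensity`` (g)."""

    start_s: float
    duration_s: float
    intensity: float


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters for one subject.

    hr_baseline : mean heart rate in beats/min (40–180).
    rsa_depth   : fractional FM of the instantaneous heart rate at the
                  breathing frequency (heart speeds up during inhalation).
    am_depth    : fractional modulation of the pulse amplitude.
    bw_amplitude: baseline-wander amplitude, in PPG units (pulse amplitude ~1).
    noise_sd    : additive white-noise SD on the PPG, in PPG units.
    accel_noise_sd : accelerometer noise SD in g.
    motion_bursts  : motion episodes corrupting both streams.
    seed        : fully determines the generated recording.
    """

    hr_baseline: float = 70.0
    rsa_depth: float = 0.05
    am_depth: float = 0.10
    bw_amplitude: float = 0.30
    noise_sd: float = 0.10
    accel_noise_sd: float = 0.02
    motion_bursts: tuple[MotionBurst, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr_baseline <= 180.0):
            raise ValueError("hr_baseline outside 40–180 beats/min")
        for depth, nm in ((self.rsa_depth, "rsa_depth"), (self.am_depth, "am_depth")):
            if not (0.0 <= depth < 1.0):
                raise ValueError(f"{nm} must lie in [0, 1)")
        if self.bw_amplitude < 0 or self.noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("amplitudes and noise SDs must be non-negative")


@dataclass
class RawRecording:
    """Synchronized raw streams for one subject plus ground truth.

    ``truth_br`` is the nominal breathing rate in bpm sampled on the PPG time
    axis.  ``beat_times``/``beat_phases`` are generator internals (true pulse
    onset times and the breathing phase at each beat) kept for validation.
    """

    subject_id: str
    protocol: Protocol
    params: SynthParams
    ppg: np.ndarray
    accel: np.ndarray  # (n, 3)
    truth_br: np.ndarray
    fs_ppg: float = PPG_FS
    fs_accel: float = ACCEL_FS
    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    beat_phases: np.ndarray = field(default_factory=lambda: np.empty(0))
    gap_flags: tuple = ()

    @property
    def duration_s(self) -> float:
        return len(self.ppg) / self.fs_ppg


def _pulse_template(u: np.ndarray, period: float) -> np.ndarray:
    """Two-Gaussian systolic/diastolic pulse over one beat; ``u`` in seconds from onset."""
    systole = np.exp(-0.5 * ((u - 0.30 * period) / (0.12 * period)) ** 2)
    diastole = 0.35 * np.exp(-0.5 * ((u - 0.65 * period) / (0.18 * period)) ** 2)
    return systole + diastole


def generate_recording(
    protocol: Protocol, params: SynthParams, subject_id: str = "S00"
) -> RawRecording:
    """Simulate one subject's PPG and accelerometer streams for ``protocol``.

    The breathing phase advances at the protocol's nominal rate; inhalation is
    the half-cycle where ``sin(phase) > 0``.  The instantaneous heart rate is
    ``hr_baseline * (1 + rsa_depth * sin(phase))``, so beat intervals shorten
    during inhalation.  Pulses are placed beat by beat, their amplitude is
    ``1 + am_depth * sin(phase)``, and the whole signal rides on
    ``bw_amplitude * sin(phase)`` plus white noise.  Motion bursts add
    band-limited noise to the PPG and an oscillation to every accelerometer
    axis.

    Random draw order (stable contract): beat-start offset, PPG noise,
    accelerometer noise, then per burst: oscillation frequency, three axis
    phases, PPG burst noise.
    """
    rng = np.random.default_rng(params.seed)
    duration = protocol.duration_s
    n_ppg = int(round(duration * PPG_FS))
    n_acc = int(round(duration * ACCEL_FS))
    t_ppg = np.arange(n_ppg) / PPG_FS
    t_acc = np.arange(n_acc) / ACCEL_FS

    br_inst = protocol.rate_at(t_ppg)  # bpm
    # breathing phase, radians; phase rate = 2*pi * br/60
    phase = 2.0 * np.pi * np.cumsum(br_inst / 60.0) / PPG_FS

    def phase_at(t: float) -> float:
        return float(np.interp(t, t_ppg, phase))

    # --- beat train (FM / RSA channel) -------------------------------------
    beats = []
    bphases = []
    t = float(rng.uniform(0.0, 0.5))
    while t < duration:
        ph = phase_at(t)
        hr = params.hr_baseline * (1.0 + params.rsa_depth * np.sin(ph))
        beats.append(t)
        bphases.append(ph)
        t += 60.0 / hr
    beat_times = np.asarray(beats)
    beat_phases = np.asarray(bphases)

    # --- PPG synthesis -----------------------------------------------------
    ppg = np.zeros(n_ppg)
    intervals = np.diff(beat_times)
    for k, tk in enumerate(beat_times):
        period = intervals[k] if k < len(intervals) else (
            intervals[-1] if len(intervals) else 60.0 / params.hr_baseline
        )
        amp = 1.0 + params.am_depth * np.sin(beat_phases[k])
        i0 = int(np.ceil(tk * PPG_FS))
        i1 = min(n_ppg, int(np.ceil((tk + period) * PPG_FS)))
        if i1 <= i0:
            continue
        u = t_ppg[i0:i1] - tk
        ppg[i0:i1] += amp * _pulse_template(u, period)
    ppg += params.bw_amplitude * np.sin(phase)
    ppg += rng.normal(0.0, params.noise_sd, n_ppg)

    # --- accelerometer -----------------------------------------------------
    accel = rng.normal(0.0, params.accel_noise_sd, (n_acc, 3))
    accel[:, 2] += 1.0  # gravity along z, in g

    for burst in params.motion_bursts:
        f_b = float(rng.uniform(3.0, 6.0))
        phases3 = rng.uniform(0.0, 2.0 * np.pi, 3)
        a0 = int(round(burst.start_s * ACCEL_FS))
        a1 = min(n_acc, int(round((burst.start_s + burst.duration_s) * ACCEL_FS)))
        if a1 > a0:
            tb = t_acc[a0:a1]
            for ax in range(3):
                accel[a0:a1, ax] += burst.intensity * np.sin(
                    2.0 * np.pi * f_b * tb + phases3[ax]
                )
        p0 = int(round(burst.start_s * PPG_FS))
        p1 = min(n_ppg, int(round((burst.start_s + burst.duration_s) * PPG_FS)))
        if p1 > p0:
            w = rng.standard_normal(p1 - p0)
            if p1 - p0 > 30:
                sos = signal.butter(2, [0.5, 8.0], btype="bandpass", fs=PPG_FS, output="sos")
                w = signal.sosfiltfilt(sos, w)
            ppg[p0:p1] += 3.0 * burst.intensity * w

    return RawRecording(
        subject_id=subject_id,
        protocol=protocol,
        params=params,
        ppg=ppg,
        accel=accel,
        truth_br=br_inst,
        beat_times=beat_times,
        beat_phases=beat_phases,
    )


DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "hr_baseline": (60.0, 90.0),
    "rsa_depth": (0.03, 0.08),
    "am_depth": (0.05, 0.20),
    "bw_amplitude": (0.20, 0.50),
    "noise_sd": (0.05, 0.15),
}


def generate_cohort(
    n_subjects: int,
    protocol: Protocol,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    motion_bursts_fn=None,
) -> list[RawRecording]:
    """Generate ``n_subjects`` recordings with per-subject parameters drawn from ranges.

    ``motion_bursts_fn(subject_index, rng) -> tuple[MotionBurst, ...]`` lets a
    caller inject reproducible motion episodes per subject.  At least two
    subjects are required (leave-one-subject-out needs ≥ 2 folds).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a LOSO-evaluable cohort")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    recordings = []
    for i in range(n_subjects):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        bursts = tuple(motion_bursts_fn(i, rng)) if motion_bursts_fn else ()
        params = SynthParams(
            seed=int(rng.integers(0, 2**31 - 1)),
            motion_bursts=bursts,
            **draws,
        )
        recordings.append(
            generate_recording(protocol, params, subject_id=f"S{i + 1:02d}")
        )
    return recordings


def with_bursts(recording: RawRecording, bursts: tuple[MotionBurst, ...]) -> RawRecording:
    """Re-generate ``recording`` with motion bursts injected (same seed and parameters)."""
    params = replace(recording.params, motion_bursts=tuple(bursts))
    return generate_recording(recording.protocol, params, subject_id=recording.subject_id)
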