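"""Generate a synthetic guided-breathing cohort and inspect one recording.

Builds the three named study protocols, simulates one subject, and prints the
stream shapes and the respiratory-sinus-arrhythmia signature (beat intervals
shorten during inhalation) that the estimation pipeline exploits.
"""

import numpy as np

import ppgbreathe as pb
from ppgbreathe.synthetic_data import SynthParams

for name in ("dataset1", "dataset2a", "dataset2b"):
    proto = pb.build_protocol(name)
    rates = sorted({s.rate_bpm for s in proto.segments})
    print(f"{name}: {len(proto.segments)} segments, {proto.duration_s:.0f} s, "
          f"rates {[round(r, 2) for r in rates]} bpm")

proto = pb.build_protocol("dataset2a")
rec = pb.generate_recording(proto, SynthParams(seed=42), subject_id="demo")
print(f"\nPPG: {len(rec.ppg)} samples @ {rec.fs_ppg:.0f} Hz; "
      f"accel: {rec.accel.shape} @ {rec.fs_accel:.0f} Hz")

iv = np.diff(rec.beat_times)
ph = rec.beat_phases[:-1]
print(f"mean beat interval during inhalation: {iv[np.sin(ph) > 0].mean():.3f} s")
print(f"mean beat interval during exhalation: {iv[np.sin(ph) < 0].mean():.3f} s")
print("-> the inhalation interval is shorter: that asymmetry is the FM/RSA "
      "channel carrying breathing rate into the pulse train.")
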