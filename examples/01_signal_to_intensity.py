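"""Raw acceleration to epoch intensity.

Builds a 3-minute synthetic recording: a gravity vector slowly tilting at
0.02 Hz plus a 2 Hz gait-like oscillation of 200 mg amplitude, then runs
the processing chain (0.69-10 Hz zero-phase band-pass per axis, vector
magnitude, 60 s epoch means).  The gravity component and slow tilt are
rejected by the high-pass component; the epoch intensities reflect only
the movement content in the 0.69-10 Hz band.
"""

import numpy as np

from accmet import TriaxialRecording, process_recording

fs = 100.0
t = np.arange(0, 180, 1 / fs)
tilt = 0.2 * np.sin(2 * np.pi * 0.02 * t)            # slow postural sway (rad)
gait = 0.2 * np.sin(2 * np.pi * 2.0 * t)             # 200 mg locomotor component
rec = TriaxialRecording(
    participant_id="demo",
    position="hip",
    sample_rate=fs,
    x=np.sin(tilt) + gait,
    y=np.zeros_like(t),
    z=np.cos(tilt),
)

series = process_recording(rec)

print("epoch start (s)   intensity (mg)")
for start, val in zip(series.epoch_start, series.intensity):
    print(f"{start:14.0f}   {val:10.1f}")
print()
print("The ~127 mg epochs are the mean vector magnitude of the 200 mg")
print("2 Hz oscillation (mean |sin| = 2/pi of the amplitude); the 1 g")
print("gravity vector and the slow tilt contribute nothing.")
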