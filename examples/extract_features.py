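"""From raw trials to channel cross-covariance feature matrices.

Shows the preprocessing chain (trim transitions, cut windows) and the two
feature domains.  The final block demonstrates the delay-elimination
property: circularly delaying each channel leaves the frequency-domain
matrix untouched while visibly changing the time-domain one.
"""

import numpy as np

import imspeech as im

spec = im.SynthSpec(n_classes=3, n_channels=8, fs=500.0, trial_duration=3.0,
                    trials_per_class=2, seed=2)
_, recordings, _ = im.generate_dataset(spec)

rec = im.trim_transitions(recordings[0], 0.5)          # 3 s → 2 s
windows = im.segment_windows(rec, im.WindowSpec(0.5))  # four 0.5 s windows
print(f"trial '{rec.prompt}' → {len(windows)} windows of "
      f"{windows[0].n_samples} samples")

win = windows[0]
t_mat = im.ccv_time(win)
f_mat = im.ccv_frequency(win, im.SmoothingKernel(3))   # B3 smoothing
print(f"time-domain matrix {t_mat.values.shape}, "
      f"frequency-domain (B3) matrix {f_mat.values.shape}")

# delay a copy of every channel by a random circular shift
rng = np.random.default_rng(0)
delayed = win.data.copy()
for ch in range(win.n_channels):
    delayed[ch] = np.roll(win.data[ch], int(rng.integers(1, 200)))
win_d = im.EpochWindow(data=delayed, fs=win.fs, label=win.label,
                       subject_id=win.subject_id, session_id=win.session_id,
                       recording_index=0, window_index=0)
df = np.abs(im.ccv_frequency(win_d).values - im.ccv_frequency(win).values).max()
dt = np.abs(im.ccv_time(win_d).values - im.ccv_time(win).values).max()
print(f"max |Δ| under per-channel delays: frequency {df:.2e}, time {dt:.2e}")
# frequency ≈ 0 (magnitude spectra ignore delays); time is O(matrix scale)
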