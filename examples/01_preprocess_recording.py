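"""Clean a raw motor-imagery recording and cut normalized cue epochs.

Builds a small in-memory recording (4 EEG + 1 EOG channels with four cue
annotations), writes it to disk, then runs the full preprocessing chain:
EOG exclusion, NaN mean-imputation, epoch extraction over [cue+1 s,
cue+4 s), and per-trial/channel z-scoring.
"""

import tempfile
from pathlib import Path

import mne
import numpy as np

from hafusenet import extract_epochs, impute_missing, normalize, read_recording

fs = 64.0
rng = np.random.default_rng(0)
info = mne.create_info(
    ["C3", "Cz", "C4", "Pz", "EOG1"], sfreq=fs, ch_types=["eeg"] * 4 + ["eog"]
)
raw = mne.io.RawArray(rng.standard_normal((5, int(fs * 30))) * 1e-5, info, verbose="error")
raw.set_annotations(
    mne.Annotations([2.0, 8.0, 14.0, 20.0], [0.0] * 4, ["769", "770", "771", "772"])
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo_raw.fif"
    raw.save(path, verbose="error")
    rec = read_recording(path, subject_id="demo", session="T")

print(f"channels after EOG exclusion: {rec.n_channels} ({rec.channel_labels})")
print(f"events: {rec.events}")

rec.signal[1, 100:110] = np.nan  # simulate a run gap
rec = impute_missing(rec)
print(f"NaNs after imputation: {int(np.isnan(rec.signal).sum())}")

epochs = normalize(extract_epochs(rec))
print(f"epochs: {epochs.data.shape} (trials, channels, samples), labels {epochs.labels}")
print(f"per-trial channel means ~0: {epochs.data.mean(axis=2).round(6).max():.1e}")
# Each trial is a 3 s window starting 1 s after its cue; z-scoring brings every
# trial/channel trace to zero mean and unit variance, the network's input scale.
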