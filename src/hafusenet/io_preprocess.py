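"""Reading, cleaning, epoching and normalizing motor-imagery recordings.

The target recordings follow the BCI Competition IV 2a layout: 22 EEG +
3 EOG channels at 250 Hz with cue-annotated trials; evaluation-session
class labels ship separately in a MAT file.  Only minimal cleaning is
applied — EOG channels are dropped, NaN gaps are mean-imputed per
channel, and no band-pass filtering is performed, since broad-band
content carries task information.  Epochs span 1-4 s after the cue,
skipping the cue-onset visual response and covering the window where
mu/beta event-related desynchronization is established.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import h5py
import numpy as np

from .types import N_CLASSES, EpochSet, NormalizationSpec, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "impute_missing",
    "extract_epochs",
    "load_eval_labels",
    "normalize",
    "save_epochs",
    "load_epochs",
]

#: Annotation codes of the four cue events in BCI IV 2a GDF files,
#: in class order (left hand, right hand, feet, tongue).  Overridable
#: because GDF dialects differ in their numeric codes.
DEFAULT_EVENT_CLASSES = {769: 0, 770: 1, 771: 2, 772: 3}


def read_recording(
    path: str | Path, subject_id: str = "", session: str = "T"
) -> RawRecording:
    """Read a recording file, keeping only EEG-modality channels.

    Any format mne can auto-detect is accepted (GDF for the target
    dataset; FIF/EDF for fixtures).  EOG channels are excluded; event
    annotations are returned as (onset_sample, code) in onset order with
    their original numeric codes.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"could not parse recording {path}: {exc}") from exc

    ch_types = raw.get_channel_types()
    keep = [i for i, t in enumerate(ch_types) if t != "eog"]
    if not keep:
        raise ValueError(f"{path}: no EEG channels remain after EOG exclusion")
    labels = [raw.ch_names[i] for i in keep]
    signal = raw.get_data(picks=keep) * 1e6  # mne volts -> microvolts

    events = []
    ann = raw.annotations
    sfreq = raw.info["sfreq"]
    for onset, desc in zip(ann.onset, ann.description):
        sample = int(round((onset - raw.first_time) * sfreq))
        try:
            code = int(desc)
        except ValueError:
            continue  # non-numeric annotation, not a task event
        if 0 <= sample < signal.shape[1]:
            events.append((sample, code))
    events.sort(key=lambda e: e[0])

    return RawRecording(
        signal=signal,
        sampling_rate=sfreq,
        channel_labels=labels,
        channel_types=["eeg"] * len(labels),
        events=events,
        subject_id=subject_id,
        session=session,  # type: ignore[arg-type]
    )


def impute_missing(rec: RawRecording) -> RawRecording:
    """Replace NaN gaps with each channel's mean over its non-missing samples.

    Idempotent; a channel with no finite samples has no defined mean and is
    rejected.
    """
    signal = rec.signal
    if not np.isnan(signal).any():
        return rec.copy()
    out = signal.copy()
    for c in range(out.shape[0]):
        row = out[c]
        nan = np.isnan(row)
        if not nan.any():
            continue
        if nan.all():
            raise ValueError(
                f"channel {rec.channel_labels[c]!r} is entirely missing; "
                "mean imputation is undefined"
            )
        row[nan] = row[~nan].mean()
    return replace(rec, signal=out)


def extract_epochs(
    rec: RawRecording,
    task_codes: set[int] | frozenset[int] | None = None,
    *,
    window: tuple[float, float] = (1.0, 4.0),
    event_classes: dict[int, int] | None = None,
    labels: np.ndarray | None = None,
) -> EpochSet:
    """Cut one epoch per task event over ``[cue + start, cue + end)`` seconds.

    Class labels come either from ``event_classes`` (code -> class, the
    training-session case, default BCI IV 2a cue codes) or from an explicit
    ``labels`` vector (the evaluation-session case, see
    :func:`load_eval_labels`).  Events whose window runs past the end of the
    recording are dropped with a warning.
    """
    if np.isnan(rec.signal).any():
        raise ValueError("recording contains NaNs; run impute_missing first")
    if event_classes is None and labels is None:
        event_classes = DEFAULT_EVENT_CLASSES
    if task_codes is None:
        task_codes = (
            set(event_classes) if event_classes is not None else {e for _, e in rec.events}
        )

    fs = rec.sampling_rate
    start_off = int(round(window[0] * fs))
    n_len = int(round((window[1] - window[0]) * fs))
    if n_len <= 0:
        raise ValueError("window end must exceed window start")

    task_events = [(onset, code) for onset, code in rec.events if code in task_codes]
    if labels is not None and len(labels) != len(task_events):
        raise ValueError(
            f"label vector length {len(labels)} does not match "
            f"{len(task_events)} task events"
        )

    trials, trial_labels = [], []
    n_dropped = 0
    for i, (onset, code) in enumerate(task_events):
        lo = onset + start_off
        hi = lo + n_len
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        trials.append(rec.signal[:, lo:hi])
        if labels is not None:
            trial_labels.append(int(labels[i]))
        else:
            trial_labels.append(event_classes[code])
    if n_dropped:
        logger.warning(
            "dropped %d/%d events whose epoch window exceeds the recording",
            n_dropped,
            len(task_events),
        )

    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.n_channels, n_len), dtype=np.float32)
    )
    return EpochSet(
        data=data,
        labels=np.asarray(trial_labels, dtype=np.int64),
        sampling_rate=fs,
        subject_id=rec.subject_id,
        session=rec.session,
        window_seconds=window,
    )


def load_eval_labels(path: str | Path, n_expected: int | None = None) -> np.ndarray:
    """Load the evaluation-session class vector from a MAT file, 0-based.

    The file stores 1-based classes (the A0xE.mat convention, key
    ``classlabel``); any single numeric vector variable is accepted.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    candidates = {
        k: np.asarray(v).ravel()
        for k, v in mat.items()
        if not k.startswith("__") and np.asarray(v).size >= 0 and np.issubdtype(np.asarray(v).dtype, np.number)
    }
    if "classlabel" in candidates:
        vec = candidates["classlabel"]
    elif len(candidates) == 1:
        vec = next(iter(candidates.values()))
    else:
        raise ValueError(
            f"{path}: expected a 'classlabel' variable or a single numeric vector, "
            f"found {sorted(candidates)}"
        )
    labels = vec.astype(np.int64) - 1
    if labels.size and (labels.min() < 0 or labels.max() >= N_CLASSES):
        raise ValueError(f"{path}: labels outside the {N_CLASSES}-class range")
    if n_expected is not None and len(labels) != n_expected:
        raise ValueError(
            f"{path}: {len(labels)} labels for {n_expected} task events"
        )
    return labels


def normalize(epochs: EpochSet, spec: NormalizationSpec | None = None) -> EpochSet:
    """Z-score (x - mu) / sigma or min-max (x - min) / (max - min) scaling.

    Statistics are computed over the grouping named by ``spec.scope``;
    sigma uses the population (divide-by-n) convention.  Groups with spread
    below ``epsilon`` map to zeros.
    """
    spec = spec or NormalizationSpec()
    if epochs.n_trials == 0:
        raise ValueError("cannot normalize an empty EpochSet")
    x = epochs.data.astype(np.float64)
    axis = 2 if spec.scope == "trial_channel" else (0, 2)

    if spec.method == "zscore":
        mu = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, keepdims=True)  # population convention
        out = np.where(sd < spec.epsilon, 0.0, (x - mu) / np.maximum(sd, spec.epsilon))
    else:
        lo = x.min(axis=axis, keepdims=True)
        hi = x.max(axis=axis, keepdims=True)
        rng = hi - lo
        out = np.where(rng < spec.epsilon, 0.0, (x - lo) / np.maximum(rng, spec.epsilon))
    return replace(epochs, data=out.astype(np.float32))


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write an epoch cache: datasets ``data``/``labels`` plus attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int8))
        f.attrs["subject"] = epochs.subject_id
        f.attrs["session"] = epochs.session
        f.attrs["fs"] = epochs.sampling_rate
        f.attrs["window"] = list(epochs.window_seconds)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()].astype(np.int64),
            sampling_rate=float(f.attrs["fs"]),
            subject_id=str(f.attrs["subject"]),
            session=str(f.attrs["session"]),
            window_seconds=tuple(f.attrs["window"]),
        )
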