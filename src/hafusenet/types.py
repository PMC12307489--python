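"""Domain containers shared across the package.

Conventions: continuous signals are (channels, samples) in microvolts;
epoched data are (trials, channels, time).  The four motor-imagery
classes are encoded 0-3 in the fixed order left hand, right hand, feet,
tongue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

CLASS_NAMES = ("left_hand", "right_hand", "feet", "tongue")
N_CLASSES = len(CLASS_NAMES)


@dataclass
class RawRecording:
    """Continuous multichannel EEG with event annotations."""

    signal: np.ndarray  # (channels, samples), microvolts
    sampling_rate: float  # Hz
    channel_labels: list[str]
    channel_types: list[str]  # "eeg" | "eog" per channel
    events: list[tuple[int, int]]  # (onset_sample, code), onset order
    subject_id: str = ""
    session: Literal["T", "E"] = "T"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (channels, samples)")
        n_ch, n_samp = self.signal.shape
        if len(self.channel_labels) != n_ch or len(self.channel_types) != n_ch:
            raise ValueError("channel metadata length mismatch")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for onset, _ in self.events:
            if not 0 <= onset < n_samp:
                raise ValueError(f"event onset {onset} outside [0, {n_samp})")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def copy(self) -> "RawRecording":
        return replace(
            self,
            signal=self.signal.copy(),
            channel_labels=list(self.channel_labels),
            channel_types=list(self.channel_types),
            events=list(self.events),
        )


@dataclass
class EpochSet:
    """Trials x channels x time with per-trial class labels."""

    data: np.ndarray
    labels: np.ndarray  # int in {0..3}
    sampling_rate: float
    subject_id: str = ""
    session: str = "T"
    window_seconds: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochSet":
        return replace(self, data=self.data[idx], labels=self.labels[idx])


@dataclass
class NormalizationSpec:
    """How per-group statistics for z-score / min-max scaling are formed.

    scope "trial_channel": statistics per trial and electrode over time
    (the default; robust to non-stationarity across trials).
    scope "channel_session": statistics per electrode over the whole set.
    """

    method: Literal["zscore", "minmax"] = "zscore"
    scope: Literal["trial_channel", "channel_session"] = "trial_channel"
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.method not in ("zscore", "minmax"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.scope not in ("trial_channel", "channel_session"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class MetricsReport:
    """Per-subject evaluation summary for one protocol run."""

    accuracy: dict[str, float] = field(default_factory=dict)  # fraction in [0,1]
    kappa: dict[str, float] = field(default_factory=dict)
    confusion: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracy.values())))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(list(self.kappa.values())))

    @property
    def accuracy_sd(self) -> float | None:
        """Sample SD of per-subject accuracies (absent with < 2 subjects)."""
        if len(self.accuracy) < 2:
            return None
        return float(np.std(list(self.accuracy.values()), ddof=1))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "mean_kappa": self.mean_kappa,
            "accuracy_sd": self.accuracy_sd,
            "per_subject": {
                s: {"accuracy": self.accuracy[s], "kappa": self.kappa[s]}
                for s in self.accuracy
            },
        }
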