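"""Synthetic 4-class motor-imagery EEG with class-dependent ERD.

The generator emulates the structure of a 22-channel, 250 Hz cue-based
motor-imagery session: a 1/f-shaped background, ongoing narrowband
mu/beta rhythms on class-specific electrodes, and a multiplicative
amplitude attenuation of those rhythms during each trial of the
matching class (the event-related desynchronization analogue).  The
attenuation ramps in linearly over 0.5 s starting 0.5 s after the cue
and holds until 4 s post-cue, so the 1-4 s analysis epoch sits inside
the desynchronized window.

Class identity is therefore carried by *which* electrodes lose band
power — the same cue that distinguishes left hand, right hand, feet and
tongue imagery in real sensorimotor recordings — while an attenuation
factor of 1.0 produces signal-free null data.  Per-subject variability
is modeled as random log-normal channel gains.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import extract_epochs, normalize
from .types import N_CLASSES, EpochSet, NormalizationSpec, RawRecording

__all__ = ["SynthConfig", "generate_recording", "generate_epochset"]

#: cue annotation codes in class order, matching the target dataset
CUE_CODES = (769, 770, 771, 772)


def _default_profiles() -> list[dict[int, tuple[float, float, float]]]:
    """Per-class map channel -> (band center Hz, bandwidth Hz, attenuation).

    Electrode indices approximate the contralateral-hand / midline-foot /
    fronto-lateral-tongue layout of a 22-electrode motor grid; the sets are
    disjoint so each class has its own spatial signature.  Attenuation 0.5
    is a moderate ERD depth.
    """
    bands = [(10.0, 2.0), (22.0, 4.0)]  # mu, beta
    channel_sets = [(11, 16), (7, 13), (9, 2), (5, 18)]
    profiles = []
    for chans in channel_sets:
        prof = {}
        for ch, (center, bw) in zip(chans, bands):
            prof[ch] = (center, bw, 0.5)
        profiles.append(prof)
    return profiles


@dataclass
class SynthConfig:
    n_subjects: int = 9
    n_trials_per_class: int = 20
    sampling_rate: float = 250.0
    n_channels: int = 22
    class_profiles: list[dict[int, tuple[float, float, float]]] = field(
        default_factory=_default_profiles
    )
    noise_sd: float = 1.0  # microvolts, 1/f background
    rhythm_amplitude: float = 2.0  # microvolts, ongoing mu/beta oscillation
    subject_shift_sd: float = 0.2  # log-normal per-subject channel gain scale
    trial_period: float = 8.0  # seconds between cues
    seed: int = 0

    def __post_init__(self):
        if len(self.class_profiles) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} class profiles")
        for prof in self.class_profiles:
            for ch, (_, _, att) in prof.items():
                if not 0 < att <= 1:
                    raise ValueError("attenuation factors must lie in (0, 1]")
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"profile channel {ch} out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _subject_rng(cfg: SynthConfig, subject_id: str, session: str) -> np.random.Generator:
    sid = zlib.crc32(str(subject_id).encode()) & 0x7FFFFFFF
    sess = 0 if session == "T" else 1
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(cfg.seed), sid, sess]))
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """1/f-power background noise, per-channel RMS equal to ``sd``."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms * sd


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, center: float, bw: float
) -> np.ndarray:
    """Unit-RMS stochastic narrowband oscillation (Gaussian-shaped spectrum).

    Ongoing sensorimotor rhythms are noise-driven oscillations whose phase
    decorrelates on the ~1/bandwidth timescale, so no fixed waveform template
    repeats across trials — only band power is a stable feature.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.exp(-0.5 * ((f - center) / (bw / 2.0)) ** 2)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def generate_recording(
    cfg: SynthConfig, subject_id: str, session: str = "T"
) -> RawRecording:
    """Deterministic continuous recording for one subject and session."""
    rng = _subject_rng(cfg, subject_id, session)
    fs = cfg.sampling_rate
    n_trials = cfg.n_trials_per_class * N_CLASSES
    period = int(round(cfg.trial_period * fs))
    lead = int(round(2.0 * fs))
    n_samples = lead + n_trials * period + int(round(1.0 * fs))

    # balanced, shuffled trial order
    order = np.repeat(np.arange(N_CLASSES), cfg.n_trials_per_class)
    rng.shuffle(order)
    cue_samples = lead + np.arange(n_trials) * period

    signal = _pink_noise(rng, (cfg.n_channels, n_samples), cfg.noise_sd)

    ramp = int(round(0.5 * fs))
    t_on = int(round(0.5 * fs))  # desync starts 0.5 s post-cue
    t_off = int(round(4.0 * fs))
    for cls, prof in enumerate(cfg.class_profiles):
        for ch, (center, bw, att) in prof.items():
            osc = _narrowband(rng, n_samples, fs, center, bw) * cfg.rhythm_amplitude
            env = np.ones(n_samples)
            for cue, trial_cls in zip(cue_samples, order):
                if trial_cls != cls:
                    continue
                lo, hi = cue + t_on, min(cue + t_off, n_samples)
                if lo >= n_samples:
                    continue
                n_ramp = min(ramp, hi - lo)
                env[lo : lo + n_ramp] = np.linspace(1.0, att, n_ramp)
                env[lo + n_ramp : hi] = att
            signal[ch] += osc * env

    gains = np.exp(rng.normal(0.0, cfg.subject_shift_sd, size=cfg.n_channels))
    signal *= gains[:, None]

    events = [(int(s), CUE_CODES[c]) for s, c in zip(cue_samples, order)]
    return RawRecording(
        signal=signal,
        sampling_rate=fs,
        channel_labels=[f"EEG{i:02d}" for i in range(cfg.n_channels)],
        channel_types=["eeg"] * cfg.n_channels,
        events=events,
        subject_id=str(subject_id),
        session=session,  # type: ignore[arg-type]
    )


def generate_epochset(
    cfg: SynthConfig,
    subject_id: str,
    session: str = "T",
    norm: NormalizationSpec | None = None,
    window: tuple[float, float] = (1.0, 4.0),
) -> EpochSet:
    """Recording -> epoch extraction -> normalization, balanced labels."""
    rec = generate_recording(cfg, subject_id, session)
    epochs = extract_epochs(rec, window=window)
    return normalize(epochs, norm or NormalizationSpec())
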