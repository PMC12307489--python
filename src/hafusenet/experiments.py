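"""Desk-scale study definitions: reproducible CPU-sized experiments.

The benchmark-scale model (250 Hz, 300 epochs, nine 3-second sessions)
is a GPU-days workload; these functions define the package's own
desk-scale conditions, used by the test suite, the examples and the
acceptance script alike:

* synthetic sessions at 50 Hz (mu at 10 Hz and beta at 18 Hz sit well
  below the 25 Hz Nyquist), 22 channels, 9 subjects, 80 trials each
  (20 per class), ERD attenuation 0.3 on class-specific electrodes with
  low background noise for the separable condition, attenuation 1.0
  (no modulation anywhere) for the signal-free null condition;
* a scaled-down HA-FuseNet of roughly 40k parameters with the same
  topology as the full model — smaller depths, kernels resized to the
  50 Hz sampling rate (the 5/9-sample branch kernels span 100/180 ms),
  LSTM hidden size 48 with 5x input time pooling;
* 40 training epochs at batch 32, Adam 1e-3 with weight decay 5e-3.

``run_learning_experiment`` trains on the pooled training sessions and
reports held-out accuracy on the pooled evaluation sessions.
"""

from __future__ import annotations

import numpy as np

from .metrics import accuracy, kappa
from .models import DisnetConfig, FusionConfig, HAFuseNet, LsnetConfig, ModelConfig
from .synth import SynthConfig, _default_profiles, generate_epochset
from .training import TrainConfig, concat_epochsets, evaluate, train
from .types import NormalizationSpec

__all__ = [
    "desk_synth_config",
    "desk_model_config",
    "desk_train_config",
    "build_desk_dataset",
    "run_learning_experiment",
]

DESK_FS = 50.0
DESK_N_SUBJECTS = 9
DESK_TRIALS_PER_CLASS = 20  # 80 trials per subject over 4 classes


def desk_synth_config(attenuation: float, seed: int) -> SynthConfig:
    """Desk-scale generator: 9 subjects x 80 trials at 50 Hz, 22 channels."""
    profiles = [
        {ch: (center, bw, attenuation) for ch, (center, bw, _) in prof.items()}
        for prof in _default_profiles()
    ]
    # keep beta below the 25 Hz Nyquist of the 50 Hz desk sampling rate
    for prof in profiles:
        for ch, (center, bw, att) in list(prof.items()):
            if center > 20.0:
                prof[ch] = (18.0, bw, att)
    return SynthConfig(
        n_subjects=DESK_N_SUBJECTS,
        n_trials_per_class=DESK_TRIALS_PER_CLASS,
        sampling_rate=DESK_FS,
        class_profiles=profiles,
        noise_sd=0.5,
        seed=seed,
    )


def desk_model_config(n_times: int, seed: int = 0, variant: str = "standard") -> ModelConfig:
    dcfg = DisnetConfig(
        n_channels=22,
        n_times=n_times,
        stem_depth=4,
        stem_kernel=7,
        bottleneck_expansion=2,
        bottleneck_kernel=9,
        branch_kernels=(5, 9),  # 100 / 180 ms at 50 Hz
        branch_depth=4,
        pool_size=n_times,  # global average pooling: band power is stationary
        dropout=0.25,
        svse_residual=True,  # identity path keeps low-power (ERD) channels alive
        variant=variant,
    )
    lcfg = LsnetConfig(n_layers=2, hidden=48, time_pool=5)
    return ModelConfig(
        disnet=dcfg,
        lsnet=lcfg,
        fusion=FusionConfig(target_depth=8, kernel=5),
        seed=seed,
    )


def desk_train_config(seed: int, epochs: int = 40) -> TrainConfig:
    return TrainConfig(batch_size=32, epochs=epochs, learning_rate=1e-3,
                       weight_decay=5e-3, seed=seed)


#: Desk-scale normalization: per-channel statistics over the whole session.
#: Per-trial scoping would rescale every trial/channel to unit variance and
#: erase the ERD amplitude cue itself; session scope preserves it, which is
#: why session-level standardization is the norm in EEG deep learning.
DESK_NORM = NormalizationSpec(method="zscore", scope="channel_session")


def build_desk_dataset(scfg: SynthConfig) -> dict[str, dict]:
    """Per-subject {"T": train EpochSet, "E": eval EpochSet} caches."""
    data: dict[str, dict] = {}
    for i in range(scfg.n_subjects):
        subject = f"S{i + 1:02d}"
        data[subject] = {
            "T": generate_epochset(scfg, subject, "T", norm=DESK_NORM),
            "E": generate_epochset(scfg, subject, "E", norm=DESK_NORM),
        }
    return data


def run_learning_experiment(
    seed: int,
    attenuation: float = 0.3,
    epochs: int = 40,
    variant: str = "standard",
) -> dict:
    """Train pooled across subjects, test on the held-out evaluation sessions.

    Returns held-out accuracy/kappa, the final training loss, the history
    and the parameter count.
    """
    scfg = desk_synth_config(attenuation, seed)
    data = build_desk_dataset(scfg)
    train_set = concat_epochsets([d["T"] for _, d in sorted(data.items())])
    test_set = concat_epochsets([d["E"] for _, d in sorted(data.items())])
    mcfg = desk_model_config(train_set.n_times, seed=seed, variant=variant)
    model = HAFuseNet(mcfg, rng=np.random.default_rng(seed))
    model, history = train(model, train_set, desk_train_config(seed, epochs=epochs))
    cm = evaluate(model, test_set)
    from .nn import count_parameters

    return {
        "held_out_accuracy": accuracy(cm),
        "held_out_kappa": kappa(cm),
        "final_train_loss": history["loss"][-1],
        "history": history,
        "n_parameters": count_parameters(model),
        "n_train_trials": train_set.n_trials,
        "n_test_trials": test_set.n_trials,
        "confusion": cm,
        "model": model,
    }
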