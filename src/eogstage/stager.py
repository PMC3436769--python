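"""Hierarchical decision-tree sleep stager.

Each 30-s epoch is pushed through a fixed sequence of gates over its
:class:`~eogstage.features.EpochFeatures`; the first gate whose conditions
hold assigns the stage, and N1 — the least reliably scored stage — is the
fall-through leaf:

1. **Wake** — wakeful muscle tone (EMG power and BEI above threshold), or
   blink/slow-eye-movement evidence, or a high transient index (EMI), or a
   dense run of arousals in the trailing context window.
2. **N3** — dominant slow-wave activity: DBI and the delta fraction of
   total EEG power above threshold with quiet EMG.
3. **REM** — atonia (EMG under a low ceiling), rapid eye movements, low
   sigma/beta ratio and no spindles.
4. **N2** — at least one sleep spindle, or a sigma/beta ratio above
   threshold.
5. **N1** otherwise.

Gate order is strict: the first satisfied branch wins, no scoring or
tie-breaking.  Ratio-based gates are invariant to an overall amplitude
rescaling of the record; only the absolute-power gates (EMG, eye-movement
amplitude) are amplitude dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import StagerConfig, Thresholds, adapt_thresholds
from .features import EpochFeatures, extract_features
from .io import EpochedSignal, Hypnogram, RawChannel, epoch_signal, resample_linear

__all__ = [
    "StageDecision",
    "StagerConfig",
    "Thresholds",
    "adapt_thresholds",
    "stage_epoch",
    "stage_record",
    "prepare_signal",
    "smooth_majority",
]


@dataclass(frozen=True)
class StageDecision:
    stage: str
    fired_branch: str


def stage_epoch(
    features: EpochFeatures,
    config: StagerConfig,
    context_nar: float = 0.0,
    disable_absolute: bool = False,
) -> StageDecision:
    """Classify one epoch; deterministic, exactly one stage.

    ``context_nar`` is the arousal count over the trailing context window
    (available to the wake gate).  ``disable_absolute`` bypasses every
    amplitude-dependent condition (absolute EMG power and the eye-movement
    counts, whose detector applies an absolute µV threshold), leaving only
    the scale-invariant conditions — ratios, EMI and the relative-threshold
    spindle/arousal evidence.  Used to check amplitude robustness.
    """
    t = config.thresholds
    f = features

    if not disable_absolute:
        if f.emg_power > t.wake_emg_power and f.bei > t.wake_bei:
            return StageDecision("W", "wake_emg_bei")
        if f.slow_eye >= t.wake_eye_count:
            return StageDecision("W", "wake_eye")
    if f.emi > t.wake_emi:
        return StageDecision("W", "wake_emi")
    if context_nar >= t.wake_nar:
        return StageDecision("W", "wake_arousal_context")

    n3_quiet = disable_absolute or f.emg_power < t.n3_emg_power
    if f.dbi > t.n3_dbi and f.delta_fraction > t.n3_delta_fraction and n3_quiet:
        return StageDecision("N3", "n3_slow_wave")

    rem_atonia = disable_absolute or f.emg_power < t.rem_emg_power
    rem_eyes = disable_absolute or f.rapid_eye >= t.rem_eye_count
    if rem_atonia and rem_eyes and f.sbi < t.rem_sbi and f.nsp <= t.rem_nsp:
        return StageDecision("R", "rem_eye_atonia")

    if f.nsp >= t.n2_nsp:
        return StageDecision("N2", "n2_spindle")
    if f.sbi > t.n2_sbi:
        return StageDecision("N2", "n2_sbi")

    return StageDecision("N1", "n1_fallthrough")


def smooth_majority(stages: list[str], window: int = 3) -> list[str]:
    """Majority filter over a centred odd window; ties keep the centre label."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    out = list(stages)
    for i in range(len(stages)):
        lo, hi = max(0, i - half), min(len(stages), i + half + 1)
        votes: dict[str, int] = {}
        for s in stages[lo:hi]:
            votes[s] = votes.get(s, 0) + 1
        best = max(votes.values())
        winners = [s for s, v in votes.items() if v == best]
        if len(winners) == 1:
            out[i] = winners[0]
    return out


def prepare_signal(
    staging: RawChannel, config: StagerConfig, epoch_length: float = 30.0
) -> EpochedSignal:
    """Resample the staging signal to the filter design rate, pre-filter
    and segment into epochs."""
    channel = staging
    if channel.sampling_rate != config.target_rate:
        channel = resample_linear(channel, config.target_rate)
    if config.highpass_hz:
        from scipy import signal as sps

        sos = sps.butter(
            2, config.highpass_hz, btype="highpass",
            fs=channel.sampling_rate, output="sos",
        )
        channel = RawChannel(
            label=channel.label,
            sampling_rate=channel.sampling_rate,
            samples=sps.sosfiltfilt(sos, channel.samples),
            physical_unit=channel.physical_unit,
        )
    return epoch_signal(channel, epoch_length)


def stage_record(
    epoched: EpochedSignal,
    config: StagerConfig | None = None,
    disable_absolute: bool = False,
) -> tuple[Hypnogram, list[StageDecision], list[EpochFeatures]]:
    """Stage a whole epoched record.

    Returns the hypnogram plus the per-epoch decisions and features.
    With smoothing off, an epoch's stage depends only on its own features
    and the trailing arousal-context window.
    """
    config = config or StagerConfig()
    features = extract_features(epoched, config)
    decisions: list[StageDecision] = []
    nars = np.array([f.nar for f in features], float)
    w = config.arousal_context_epochs
    for i, f in enumerate(features):
        context_nar = float(nars[max(0, i - w + 1) : i + 1].sum())
        decisions.append(stage_epoch(f, config, context_nar, disable_absolute))
    stages = [d.stage for d in decisions]
    if config.smoothing:
        stages = smooth_majority(stages, 3)
    hyp = Hypnogram(stages=stages, epoch_length=epoched.epoch_length)
    return hyp, decisions, features
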