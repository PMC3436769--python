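"""Synthetic polysomnography: truth hypnograms, two-channel EOG signals and
respiratory-event lists with the statistical structure the stager and the
agreement suite assume.

The night is modelled as a first-order Markov chain over the five stages at
epoch scale.  Severity profiles target the stage distributions and
respiratory-disturbance rates typical of increasing sleep-disordered
breathing: more wake and N1, less slow-wave and REM sleep, more events and
arousals.

The signal generator works in the *difference* domain: it builds the
REOG − LEOG target directly as a sum of band-limited Gaussian noise with
stage-specific amplitudes plus stage-specific events (spindle bursts in N2,
high-amplitude slow waves in N3, conjugate rapid deflections in REM, slow
blink-like deflections in wake, stage-modulated EMG noise), then splits it
anti-phase across the two channels around a shared in-phase cerebral
background.  A single ``contrast`` dial interpolates every stage-specific
amplitude towards the across-stage mean and scales event rates, so at
contrast 0 all stages are statistically identical and staging can only
perform at chance.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import (
    STAGES,
    Hypnogram,
    RawChannel,
    RespiratoryEventList,
    write_events,
    write_hypnogram,
)

_BANDS = ("delta", "theta", "alpha", "sigma", "beta", "emg")

_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.75, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 32.0),
    "emg": (32.0, 63.0),
}

#: Stage-specific RMS amplitude (µV) of each band in the difference signal.
DEFAULT_BAND_AMPLITUDES: dict[str, dict[str, float]] = {
    "W": {"delta": 20, "theta": 10, "alpha": 30, "sigma": 5, "beta": 15, "emg": 20},
    "N1": {"delta": 25, "theta": 30, "alpha": 8, "sigma": 5, "beta": 8, "emg": 6},
    "N2": {"delta": 45, "theta": 20, "alpha": 7, "sigma": 6, "beta": 6, "emg": 4},
    "N3": {"delta": 90, "theta": 20, "alpha": 6, "sigma": 5, "beta": 4, "emg": 4},
    "R": {"delta": 22, "theta": 25, "alpha": 6, "sigma": 3, "beta": 8, "emg": 1.0},
}


@dataclass
class HypnogramModel:
    """Markov chain over stages at epoch scale."""

    transition: np.ndarray          # 5×5, rows sum to 1
    initial: np.ndarray             # length 5
    n_epochs: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, float)
        self.initial = np.asarray(self.initial, float)
        if self.transition.shape != (5, 5):
            raise ValueError("transition matrix must be 5×5")
        if np.any(self.transition < -1e-12):
            raise ValueError("transition probabilities must be nonnegative")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass(frozen=True)
class SdbProfile:
    """Severity profile: target event rate and sleep architecture."""

    severity: str
    rdi: float                       # events per hour of sleep
    stage_fractions: tuple[float, ...]  # (W, N1, N2, N3, R), sums to 1
    arousal_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.stage_fractions) - 1.0) > 1e-6:
            raise ValueError("stage fractions must sum to 1")
        if self.rdi < 0:
            raise ValueError("RDI must be nonnegative")


# Group-level sleep architecture: the normal/mild group shares one empirical
# stage distribution, the moderate/severe group another (more wake/N1, less
# N3/REM); event rates follow typical group means.
SDB_PROFILES: dict[str, SdbProfile] = {
    "normal": SdbProfile("normal", 6.0, (0.181, 0.134, 0.447, 0.104, 0.134), 1.0),
    "mild": SdbProfile("mild", 15.0, (0.181, 0.134, 0.447, 0.104, 0.134), 1.5),
    "moderate": SdbProfile("moderate", 31.0, (0.3035, 0.2323, 0.3409, 0.0360, 0.0873), 2.5),
    "severe": SdbProfile("severe", 71.0, (0.3035, 0.2323, 0.3409, 0.0360, 0.0873), 4.0),
}

#: Default mean bout lengths per stage, in epochs.
DEFAULT_BOUT_EPOCHS: dict[str, float] = {"W": 8, "N1": 3, "N2": 12, "N3": 10, "R": 14}


@dataclass
class SynthesisParams:
    """Signal-generation knobs; defaults form the high-contrast preset."""

    sampling_rate: float = 128.0
    epoch_length: float = 30.0
    band_amplitudes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BAND_AMPLITUDES.items()}
    )
    spindle_rate: float = 3.5        # events/epoch in N2
    spindle_amplitude: float = 40.0  # µV peak of the 13.5 Hz burst
    rem_eye_rate: float = 5.0        # rapid deflections/epoch in REM
    rem_eye_amplitude: float = 150.0
    blink_rate: float = 4.0          # slow deflections/epoch in wake
    blink_amplitude: float = 110.0
    n1_slow_eye_rate: float = 0.5
    arousal_prob: float = 0.6        # arousal following a respiratory event
    arousal_duration_s: float = 5.0
    arousal_alpha_amplitude: float = 25.0
    arousal_emg_amplitude: float = 15.0
    common_background: dict[str, float] = field(
        default_factory=lambda: {"delta": 10, "theta": 8, "alpha": 6, "beta": 4}
    )
    noise_floor: float = 1.0         # per-channel white sensor noise, µV RMS
    contrast: float = 1.0            # 1 = full stage separation, 0 = none

    @classmethod
    def high_contrast(cls) -> "SynthesisParams":
        return cls()

    @classmethod
    def zero_contrast(cls) -> "SynthesisParams":
        return cls(contrast=0.0)


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution via the left eigenvector at eigenvalue 1."""
    vals, vecs = np.linalg.eig(np.asarray(transition, float).T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def profile_to_model(
    profile: SdbProfile,
    n_epochs: int = 960,
    seed: int = 0,
    bout_epochs: dict[str, float] | None = None,
) -> HypnogramModel:
    """Build a Markov chain whose stationary distribution equals the
    profile's stage fractions, with configurable mean bout lengths.

    With leave rate ``r_i = 1/L_i`` and a common landing distribution
    ``q_j ∝ π_j r_j``, the chain ``P = I − diag(r) + diag(r) q`` has
    stationary distribution exactly π and mean dwell times of order L_i.
    """
    bouts = {**DEFAULT_BOUT_EPOCHS, **(bout_epochs or {})}
    pi = np.asarray(profile.stage_fractions, float)
    r = np.array([1.0 / bouts[s] for s in STAGES])
    flow = pi * r
    if flow.sum() <= 0:
        raise ValueError("profile has no positive stage fraction")
    q = flow / flow.sum()
    P = np.diag(1.0 - r) + np.outer(r, q)
    # states with zero target mass are never entered; make their rows valid
    for i in range(5):
        if P[i].sum() <= 0:
            P[i, i] = 1.0
    P = P / P.sum(axis=1, keepdims=True)
    initial = pi if pi.sum() > 0 else np.full(5, 0.2)
    return HypnogramModel(transition=P, initial=initial, n_epochs=n_epochs, seed=seed)


def simulate_hypnogram(model: HypnogramModel) -> Hypnogram:
    """Sample a stage sequence from the Markov chain (fixed-seed reproducible)."""
    rng = np.random.default_rng(model.seed)
    state = rng.choice(5, p=model.initial / model.initial.sum())
    states = [state]
    for _ in range(model.n_epochs - 1):
        state = rng.choice(5, p=model.transition[state])
        states.append(state)
    return Hypnogram(stages=[STAGES[s] for s in states])


# ---------------------------------------------------------------------------
# Respiratory events
# ---------------------------------------------------------------------------

def simulate_respiratory_events(
    hypnogram: Hypnogram, profile: SdbProfile, seed: int = 0
) -> RespiratoryEventList:
    """Homogeneous Poisson events over sleep (non-W) epochs at RDI/hour."""
    rng = np.random.default_rng(seed)
    per_epoch_rate = profile.rdi * hypnogram.epoch_length / 3600.0
    times: list[float] = []
    for i, stage in enumerate(hypnogram.stages):
        if stage == "W":
            continue
        n = rng.poisson(per_epoch_rate)
        if n:
            offsets = np.sort(rng.uniform(0, hypnogram.epoch_length, size=n))
            times.extend(i * hypnogram.epoch_length + offsets)
    return RespiratoryEventList(event_times=np.array(times))


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _contrasted_amplitudes(params: SynthesisParams) -> dict[str, dict[str, float]]:
    c = params.contrast
    mean = {
        b: np.mean([params.band_amplitudes[s][b] for s in STAGES]) for b in _BANDS
    }
    return {
        s: {b: mean[b] + c * (params.band_amplitudes[s][b] - mean[b]) for b in _BANDS}
        for s in STAGES
    }


def _band_noise(rng: np.random.Generator, n: int, rate: float, lo: float, hi: float):
    hi = min(hi, 0.999 * rate / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_pulse(rate: float, duration_s: float) -> np.ndarray:
    """Unit-peak sin² pulse."""
    n = max(int(round(duration_s * rate)), 2)
    t = np.linspace(0, np.pi, n)
    return np.sin(t) ** 2


def synthesize_signal(
    hypnogram: Hypnogram,
    params: SynthesisParams | None = None,
    events: RespiratoryEventList | None = None,
    seed: int = 0,
) -> tuple[RawChannel, RawChannel]:
    """Generate the LEOG/REOG channel pair for a truth hypnogram.

    Eye-movement components enter anti-phase (so they add in the
    difference REOG − LEOG); the cerebral background is in-phase and
    cancels.  Optional respiratory events spawn brief alpha+EMG arousal
    bursts with probability ``params.arousal_prob``.
    """
    params = params or SynthesisParams()
    rng = np.random.default_rng(seed)
    rate = params.sampling_rate
    block = int(round(params.epoch_length * rate))
    n_epochs = len(hypnogram)
    n = n_epochs * block
    amps = _contrasted_amplitudes(params)
    c = params.contrast

    # stage-modulated band noise in the difference domain
    diff = np.zeros(n)
    for band in _BANDS:
        noise = _band_noise(rng, n, rate, *_BAND_EDGES[band])
        env = np.repeat([amps[s][band] for s in hypnogram.stages], block)
        diff += noise * env

    def add_event(t0: float, shape: np.ndarray) -> None:
        i0 = int(round(t0 * rate))
        i1 = min(i0 + shape.size, n)
        if i1 > i0:
            diff[i0:i1] += shape[: i1 - i0]

    spindle_rate = params.spindle_rate * c
    rem_rate = params.rem_eye_rate * c
    blink_rate = params.blink_rate * c
    n1_rate = params.n1_slow_eye_rate * c
    for i, stage in enumerate(hypnogram.stages):
        t_base = i * params.epoch_length
        if stage == "N2" and spindle_rate > 0:
            for _ in range(rng.poisson(spindle_rate)):
                dur = rng.uniform(0.8, 1.4)
                t0 = t_base + rng.uniform(0, params.epoch_length - dur)
                tt = np.arange(int(dur * rate)) / rate
                burst = (
                    params.spindle_amplitude
                    * np.sin(2 * np.pi * 13.5 * tt)
                    * np.hanning(tt.size)
                )
                add_event(t0, burst)
        elif stage == "R" and rem_rate > 0:
            for _ in range(rng.poisson(rem_rate)):
                t0 = t_base + rng.uniform(0, params.epoch_length - 0.6)
                sign = rng.choice([-1.0, 1.0])
                add_event(t0, sign * params.rem_eye_amplitude * _smooth_pulse(rate, 0.6))
        elif stage == "W" and blink_rate > 0:
            for _ in range(rng.poisson(blink_rate)):
                t0 = t_base + rng.uniform(0, params.epoch_length - 2.5)
                sign = rng.choice([-1.0, 1.0])
                add_event(t0, sign * params.blink_amplitude * _smooth_pulse(rate, 2.5))
        elif stage == "N1" and n1_rate > 0:
            for _ in range(rng.poisson(n1_rate)):
                t0 = t_base + rng.uniform(0, params.epoch_length - 2.5)
                sign = rng.choice([-1.0, 1.0])
                add_event(t0, sign * 100.0 * _smooth_pulse(rate, 2.5))

    # arousal bursts after a random subset of respiratory events
    if events is not None and events.event_times is not None and c > 0:
        alpha_tone = _band_noise(rng, int(params.arousal_duration_s * rate), rate, 8, 12)
        for t in events.event_times:
            if rng.uniform() < min(params.arousal_prob, 1.0):
                dur = params.arousal_duration_s
                shape = (
                    params.arousal_alpha_amplitude
                    * _band_noise(rng, int(dur * rate), rate, 8, 12)
                    + params.arousal_emg_amplitude
                    * _band_noise(rng, int(dur * rate), rate, 32, 63)
                ) * np.clip(_smooth_pulse(rate, dur) * 2, 0, 1)
                add_event(t + 1.0, shape)
        del alpha_tone

    # shared in-phase cerebral background + independent sensor noise
    common = np.zeros(n)
    for band, amp in params.common_background.items():
        common += amp * _band_noise(rng, n, rate, *_BAND_EDGES[band])
    left = common - diff / 2 + params.noise_floor * rng.standard_normal(n)
    right = common + diff / 2 + params.noise_floor * rng.standard_normal(n)
    return (
        RawChannel("LEOG", rate, left, "uV"),
        RawChannel("REOG", rate, right, "uV"),
    )


# ---------------------------------------------------------------------------
# EDF fixture writer
# ---------------------------------------------------------------------------

def write_edf(path: str | Path, channels: list[RawChannel]) -> None:
    """Write channels to a minimal EDF file (16-bit, 1-s data records).

    Intended for synthetic test fixtures, not clinical exports: every
    channel must share one sampling rate and a whole-second duration.
    """
    rates = {ch.sampling_rate for ch in channels}
    if len(rates) != 1:
        raise ValueError("all channels must share one sampling rate")
    rate = rates.pop()
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("sampling rate must be integer for the EDF fixture writer")
    spr = int(round(rate))
    n = channels[0].samples.size
    if any(ch.samples.size != n for ch in channels):
        raise ValueError("all channels must have equal length")
    n_records = n // spr
    if n_records * spr != n:
        raise ValueError("record length must be a whole number of seconds")

    ns = len(channels)
    header_bytes = 256 + ns * 256

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    digital_min, digital_max = -32768, 32767
    phys_ranges = []
    for ch in channels:
        m = float(np.max(np.abs(ch.samples))) or 1.0
        phys_ranges.append((-m, m))

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad("X X X X", 80))
        fh.write(pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(header_bytes), 8))
        fh.write(pad("", 44))
        fh.write(pad(str(n_records), 8))
        fh.write(pad("1", 8))
        fh.write(pad(str(ns), 4))
        for ch in channels:
            fh.write(pad(ch.label, 16))
        for _ in channels:
            fh.write(pad("synthetic EOG", 80))
        for ch in channels:
            fh.write(pad(ch.physical_unit, 8))
        for lo, _ in phys_ranges:
            fh.write(pad(f"{lo:.4f}"[:8], 8))
        for _, hi in phys_ranges:
            fh.write(pad(f"{hi:.4f}"[:8], 8))
        for _ in channels:
            fh.write(pad(str(digital_min), 8))
        for _ in channels:
            fh.write(pad(str(digital_max), 8))
        for _ in channels:
            fh.write(pad("", 80))
        for _ in channels:
            fh.write(pad(str(spr), 8))
        for _ in channels:
            fh.write(pad("", 32))

        digitized = []
        for ch, (lo, hi) in zip(channels, phys_ranges):
            scale = (digital_max - digital_min) / (hi - lo)
            d = np.round((ch.samples - lo) * scale + digital_min)
            digitized.append(np.clip(d, digital_min, digital_max).astype("<i2"))
        for rec in range(n_records):
            for d in digitized:
                fh.write(d[rec * spr : (rec + 1) * spr].tobytes())


def write_fixture(
    directory: str | Path,
    profile: SdbProfile | str = "normal",
    params: SynthesisParams | None = None,
    n_epochs: int = 120,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a self-contained fixture: EDF + truth hypnogram CSV + events CSV.

    Regenerating with the same seed reproduces byte-identical files.
    """
    if isinstance(profile, str):
        profile = SDB_PROFILES[profile]
    params = params or SynthesisParams()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    model = profile_to_model(profile, n_epochs=n_epochs, seed=seed)
    hyp = simulate_hypnogram(model)
    events = simulate_respiratory_events(hyp, profile, seed=seed + 1)
    left, right = synthesize_signal(hyp, params, events=events, seed=seed + 2)

    paths = {
        "edf": directory / "psg.edf",
        "hypnogram": directory / "truth_hypnogram.csv",
        "events": directory / "events.csv",
    }
    write_edf(paths["edf"], [left, right])
    write_hypnogram(paths["hypnogram"], hyp)
    write_events(paths["events"], events)
    return paths
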