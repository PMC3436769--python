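"""Signal and annotation I/O.

Reads PSG channels from EDF/EDF+, derives the differential EOG staging
signal (REOG − LEOG), resamples it by linear interpolation and segments it
into fixed-length scoring epochs.  Also reads and writes the plain-text
hypnogram and respiratory-event formats used throughout the package.

Amplitudes are carried in microvolts: EDF digital values are converted to
physical units on read, since the staging thresholds are amplitude
dependent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Canonical stage order used everywhere (rows/columns of confusion tables,
#: transition matrices, reports).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Legacy numeric hypnogram tokens (old R&K-style exports).
LEGACY_STAGE_MAP: dict[str, str] = {"0": "W", "1": "N1", "2": "N2", "3": "N3", "5": "R"}

#: Default label aliases for the two EOG channels (case-insensitive).
DEFAULT_ALIASES: dict[str, str] = {
    "LOC": "LEOG",
    "ROC": "REOG",
    "E1": "LEOG",
    "E2": "REOG",
    "EOG LEFT": "LEOG",
    "EOG RIGHT": "REOG",
    "EOG(L)": "LEOG",
    "EOG(R)": "REOG",
}


@dataclass
class RawChannel:
    """A single recorded channel: uniformly sampled values in physical units."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    physical_unit: str = "uV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 1:
            raise ValueError("channel must contain at least one sample")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class EpochedSignal:
    """A channel segmented into consecutive, equal-length scoring epochs."""

    sampling_rate: float
    epoch_length: float
    epochs: np.ndarray  # shape (n_epochs, samples_per_epoch)
    dropped_samples: int = 0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        expected = int(round(self.epoch_length * self.sampling_rate))
        if self.epochs.ndim != 2 or self.epochs.shape[1] != expected:
            raise ValueError(
                f"each epoch must hold exactly {expected} samples "
                f"({self.epoch_length} s at {self.sampling_rate} Hz)"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def continuous(self) -> np.ndarray:
        """The epochs re-joined into one continuous sample array."""
        return self.epochs.reshape(-1)


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels (W, N1, N2, N3, R)."""

    stages: list[str]
    epoch_length: float = 30.0
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        if len(self.stages) < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}; allowed: {list(STAGES)}")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return self.stages == other.stages and self.epoch_length == other.epoch_length

    def as_indices(self) -> np.ndarray:
        lut = {s: i for i, s in enumerate(STAGES)}
        return np.array([lut[s] for s in self.stages], dtype=int)


@dataclass
class RespiratoryEventList:
    """Respiratory events: onset times (s from record start) or a bare count."""

    event_times: np.ndarray | None = None
    total_count: int | None = None

    def __post_init__(self) -> None:
        if self.event_times is not None:
            self.event_times = np.asarray(self.event_times, dtype=float)
            if np.any(np.diff(self.event_times) < 0):
                raise ValueError("event times must be nondecreasing")
            if np.any(self.event_times < 0):
                raise ValueError("event times must be nonnegative")
        if self.event_times is None and self.total_count is None:
            self.total_count = 0

    @property
    def count(self) -> int:
        if self.event_times is not None:
            return int(self.event_times.size)
        return int(self.total_count or 0)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    channel_labels: Sequence[str],
    aliases: Mapping[str, str] | None = None,
) -> list[RawChannel]:
    """Read the requested channels from an EDF/EDF+ file.

    Label matching is case-insensitive and goes through an alias map
    (e.g. ``LOC`` → ``LEOG``) so that common montage names resolve to the
    channels actually present in the file.  Digital values are returned in
    physical units (µV).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    lookup = {name.strip().upper(): name for name in available}
    alias_map = {**DEFAULT_ALIASES, **{k.upper(): v for k, v in (aliases or {}).items()}}

    out: list[RawChannel] = []
    for requested in channel_labels:
        key = requested.strip().upper()
        key = alias_map.get(key, key).strip().upper()
        if key not in lookup:
            raise KeyError(
                f"channel {requested!r} not found; available channels: {available}"
            )
        name = lookup[key]
        data = raw.get_data(picks=[name])[0] * 1e6  # MNE carries volts internally
        out.append(
            RawChannel(
                label=name,
                sampling_rate=float(raw.info["sfreq"]),
                samples=data,
                physical_unit="uV",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Derivation / resampling / epoching
# ---------------------------------------------------------------------------

def derive_staging_signal(
    left: RawChannel, right: RawChannel, swap: bool = False
) -> RawChannel:
    """Differential staging signal: right EOG minus left EOG.

    The difference amplifies conjugate eye movements (anti-phase on the two
    channels) while retaining the frontal EEG picked up by both electrodes.
    ``swap`` inverts the polarity for mislabeled montages.
    """
    if left.sampling_rate != right.sampling_rate:
        raise ValueError(
            f"sampling rates differ: {left.sampling_rate} vs {right.sampling_rate}"
        )
    if left.samples.size != right.samples.size:
        raise ValueError(
            f"channel lengths differ: {left.samples.size} vs {right.samples.size}"
        )
    if swap:
        left, right = right, left
    return RawChannel(
        label="REOG-LEOG",
        sampling_rate=left.sampling_rate,
        samples=right.samples - left.samples,
        physical_unit=left.physical_unit,
    )


def resample_linear(channel: RawChannel, target_rate: float) -> RawChannel:
    """Upsample by an integer factor using linear interpolation.

    New samples sit on the finer grid between original ones; samples past
    the final original sample hold its value (no extrapolation).  The
    128 → 256 Hz case doubles the length, with interior inserted samples
    being exact midpoints of their neighbours.
    """
    ratio = target_rate / channel.sampling_rate
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} Hz is not an integer multiple of "
            f"{channel.sampling_rate} Hz (only integer upsampling supported)"
        )
    if factor == 1:
        return channel
    n = channel.samples.size
    new_positions = np.arange(n * factor) / factor  # in source-sample units
    resampled = np.interp(new_positions, np.arange(n), channel.samples)
    return RawChannel(
        label=channel.label,
        sampling_rate=float(target_rate),
        samples=resampled,
        physical_unit=channel.physical_unit,
    )


def epoch_signal(
    channel: RawChannel, epoch_length: float = 30.0, start_offset_s: float = 0.0
) -> EpochedSignal:
    """Cut a channel into consecutive, non-overlapping fixed-length epochs.

    Epoching is gap-free from ``start_offset_s``; a trailing partial epoch
    is dropped and its sample count recorded.
    """
    block = int(round(epoch_length * channel.sampling_rate))
    start = int(round(start_offset_s * channel.sampling_rate))
    usable = channel.samples[start:]
    n_epochs = usable.size // block
    if n_epochs < 1:
        raise ValueError(
            f"record holds {usable.size} samples, shorter than one "
            f"{epoch_length}-s epoch ({block} samples)"
        )
    dropped = usable.size - n_epochs * block
    epochs = usable[: n_epochs * block].reshape(n_epochs, block)
    return EpochedSignal(
        sampling_rate=channel.sampling_rate,
        epoch_length=epoch_length,
        epochs=epochs,
        dropped_samples=int(dropped),
    )


# ---------------------------------------------------------------------------
# Hypnogram / event files
# ---------------------------------------------------------------------------

def write_hypnogram(path: str | Path, hypnogram: Hypnogram) -> None:
    """Write a hypnogram as a two-column CSV: ``epoch,stage``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "stage"])
        for i, stage in enumerate(hypnogram.stages):
            writer.writerow([i, stage])


def read_hypnogram(
    path: str | Path, dialect: str = "aasm", epoch_length: float = 30.0
) -> Hypnogram:
    """Read a ``epoch,stage`` CSV hypnogram.

    ``dialect="legacy"`` additionally accepts the numeric tokens
    0/1/2/3/5 for W/N1/N2/N3/R.  Unknown tokens and non-contiguous epoch
    indices are rejected with the offending row number.
    """
    stages: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty hypnogram file")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            idx_token, token = row[0].strip(), row[1].strip()
            if int(idx_token) != len(stages):
                raise ValueError(
                    f"{path}: row {row_no}: non-contiguous epoch index "
                    f"{idx_token} (expected {len(stages)})"
                )
            if dialect == "legacy" and token in LEGACY_STAGE_MAP:
                token = LEGACY_STAGE_MAP[token]
            if token not in STAGES:
                raise ValueError(
                    f"{path}: row {row_no}: unknown stage token {token!r}"
                )
            stages.append(token)
    return Hypnogram(stages=stages, epoch_length=epoch_length)


def write_events(path: str | Path, events: RespiratoryEventList) -> None:
    """Write respiratory events as a one-column CSV of onset times."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"])
        if events.event_times is not None:
            for t in events.event_times:
                writer.writerow([f"{t:.3f}"])


def read_events(path: str | Path) -> RespiratoryEventList:
    """Read a respiratory-event file: either a ``time_s`` CSV or a bare count."""
    text = Path(path).read_text().strip()
    if not text:
        return RespiratoryEventList(event_times=np.array([]))
    lines = text.splitlines()
    if len(lines) == 1 and lines[0].strip().isdigit():
        return RespiratoryEventList(total_count=int(lines[0]))
    if lines[0].strip().lower() != "time_s":
        raise ValueError(f"{path}: expected 'time_s' header or a bare integer count")
    times = [float(line.strip()) for line in lines[1:] if line.strip()]
    return RespiratoryEventList(event_times=np.array(times))
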