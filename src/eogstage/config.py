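"""Staging configuration: frequency bands and the named decision thresholds.

The classifier is a fixed-structure decision tree whose behaviour is
entirely governed by 23 named scalar thresholds.  The original clinical
values are unpublished, so the shipped defaults were tuned once, by grid
search, on a fixed-seed synthetic training record (see docs/methods.md);
every threshold is exposed in the YAML config.

Two of the 23 thresholds depend on the width of the effective EMG band.
With the full 32–128 Hz EMG band they apply as stored; when only 32–64 Hz
is available (e.g. a 128 Hz recording upsampled to 256 Hz carries no
content above 64 Hz) the EMG power threshold is reduced to one third and
the beta/EMG ratio (BEI) threshold is tripled.  ``adapt_thresholds``
implements that adaptation; the other 21 thresholds never change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: The two supported effective EMG bands (Hz).
EMG_BAND_FULL: tuple[float, float] = (32.0, 128.0)
EMG_BAND_REDUCED: tuple[float, float] = (32.0, 64.0)


@dataclass(frozen=True)
class BandScheme:
    """Frequency intervals (Hz) for the conventional EEG bands plus EMG."""

    delta: tuple[float, float] = (0.75, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    sigma: tuple[float, float] = (12.0, 16.0)
    beta: tuple[float, float] = (16.0, 32.0)
    emg: tuple[float, float] = (32.0, 64.0)

    def __post_init__(self) -> None:
        for name in ("delta", "theta", "alpha", "sigma", "beta", "emg"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"band {name!r} has invalid interval ({lo}, {hi})")

    @property
    def eeg_bands(self) -> dict[str, tuple[float, float]]:
        return {
            "delta": self.delta,
            "theta": self.theta,
            "alpha": self.alpha,
            "sigma": self.sigma,
            "beta": self.beta,
        }

    @property
    def all_bands(self) -> dict[str, tuple[float, float]]:
        return {**self.eeg_bands, "emg": self.emg}


@dataclass(frozen=True)
class Thresholds:
    """The 23 tunable scalar thresholds of the staging tree and its detectors.

    Units: power thresholds in µV², ratios dimensionless, durations in
    seconds, amplitudes in µV, slopes in µV/s, counts in events/epoch.
    """

    # wake gate
    wake_emg_power: float = 90.0     # EMG power above -> muscle tone of wakefulness
    wake_bei: float = 0.24           # beta/EMG ratio floor accompanying the EMG gate
    wake_eye_count: float = 4.0      # slow deflections (blinks / slow pursuit) per epoch
    wake_emi: float = 12.0           # transient/artifact index ceiling before epoch -> W
    wake_nar: float = 99.0           # arousal count in trailing context window
    # N3 gate
    n3_dbi: float = 130.0            # delta/beta ratio floor
    n3_delta_fraction: float = 0.84  # delta share of summed EEG band power
    n3_emg_power: float = 60.0       # EMG ceiling (slow-wave sleep is quiet)
    # REM gate
    rem_emg_power: float = 5.0       # atonia ceiling
    rem_eye_count: float = 1.0       # rapid deflections per epoch floor
    rem_sbi: float = 0.55            # sigma/beta ceiling (REM carries no spindles)
    rem_nsp: float = 0.0             # spindle-count ceiling
    # N2 gate
    n2_nsp: float = 1.0              # spindle-count floor
    n2_sbi: float = 0.70             # sigma/beta floor when no spindle was caught
    # spindle detector
    spindle_envelope_factor: float = 2.5
    spindle_min_dur_s: float = 0.5
    spindle_max_dur_s: float = 2.0
    # arousal detector
    arousal_power_factor: float = 2.0
    arousal_emg_factor: float = 1.5
    arousal_min_dur_s: float = 3.0
    arousal_max_dur_s: float = 15.0
    # eye-movement detector
    eye_amplitude: float = 75.0
    eye_slope: float = 150.0

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]


N_THRESHOLDS = len(fields(Thresholds))
assert N_THRESHOLDS == 23


@dataclass
class StagerConfig:
    """Everything the staging pipeline needs: bands, thresholds, options."""

    scheme: BandScheme = field(default_factory=BandScheme)
    thresholds: Thresholds = field(default_factory=Thresholds)
    smoothing: bool = False          # optional 3-epoch majority filter
    highpass_hz: float | None = 0.3  # pre-filter; None disables
    welch_window_s: float = 2.0
    emi_median_s: float = 0.25
    envelope_rms_s: float = 0.25
    arousal_context_epochs: int = 3
    target_rate: float = 256.0       # staging filters are designed for 256 Hz

    @property
    def emg_band(self) -> tuple[float, float]:
        return self.scheme.emg

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = {k: list(v) for k, v in dataclasses.asdict(self.scheme).items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StagerConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scheme" in data:
            scheme_d = data["scheme"]
            extra = set(scheme_d) - {f.name for f in fields(BandScheme)}
            if extra:
                raise ValueError(f"unknown band names: {sorted(extra)}")
            data["scheme"] = BandScheme(**{k: tuple(v) for k, v in scheme_d.items()})
        if "thresholds" in data:
            thr = data["thresholds"]
            extra = set(thr) - {f.name for f in fields(Thresholds)}
            if extra:
                raise ValueError(f"unknown threshold names: {sorted(extra)}")
            missing = {f.name for f in fields(Thresholds)} - set(thr)
            if missing:
                raise ValueError(f"missing threshold names: {sorted(missing)}")
            data["thresholds"] = Thresholds(**thr)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StagerConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def adapt_thresholds(
    config: StagerConfig, emg_band: tuple[float, float]
) -> StagerConfig:
    """Adapt the config to the effective EMG band.

    Moving from the full 32–128 Hz band to the reduced 32–64 Hz band
    multiplies the wake EMG power threshold by 1/3 and the BEI threshold
    by 3; the reverse move inverts both.  All other thresholds are
    untouched.  Adapting to the band the config already uses is a no-op,
    so the operation is idempotent per band.
    """
    emg_band = (float(emg_band[0]), float(emg_band[1]))
    if emg_band not in (EMG_BAND_FULL, EMG_BAND_REDUCED):
        raise ValueError(
            f"unsupported EMG band {emg_band}; expected "
            f"{EMG_BAND_REDUCED} or {EMG_BAND_FULL}"
        )
    current = (float(config.scheme.emg[0]), float(config.scheme.emg[1]))
    if current == emg_band:
        return config
    if emg_band == EMG_BAND_REDUCED:
        emg_scale, bei_scale = 1.0 / 3.0, 3.0
    else:
        emg_scale, bei_scale = 3.0, 1.0 / 3.0
    thr = replace(
        config.thresholds,
        wake_emg_power=config.thresholds.wake_emg_power * emg_scale,
        wake_bei=config.thresholds.wake_bei * bei_scale,
    )
    scheme = replace(config.scheme, emg=emg_band)
    return replace(config, thresholds=thr, scheme=scheme)
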