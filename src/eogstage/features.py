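"""Per-epoch feature extraction for the staging tree.

From each 30-s epoch of the differential EOG signal we compute:

* power in the conventional EEG bands (delta, theta, alpha, sigma, beta)
  and in the EMG band, by integrating a Welch power spectral density over
  each band's interval;
* four dimensionless ratios — SBI (sigma/beta), DBI (delta/beta),
  BEI (beta/EMG) and EMI (delta power of the raw epoch over delta power of
  the median-filtered epoch, a transient/artifact index);
* event counts — sleep spindles (NSP), arousals (NAR, with their total
  in-epoch length LAR) and rapid/slow eye movements.

All filtering is applied epoch-wise, so features are local to their epoch;
the only cross-epoch couplings are the spindle threshold (a multiple of
the record-median sigma envelope, invariant under epoch permutation) and
the arousal detector's trailing baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import BandScheme, StagerConfig
from .io import EpochedSignal

if TYPE_CHECKING:  # pragma: no cover
    pass

#: Resolution (s) of the envelope grids used by the event detectors.
_GRID_HOP_S = 0.25


@dataclass
class EpochFeatures:
    """Everything the decision tree sees for one epoch."""

    band_power: dict[str, float]     # µV² per EEG band
    emg_power: float                 # µV²
    sbi: float                       # sigma / beta
    dbi: float                       # delta / beta
    bei: float                       # beta / EMG
    emi: float                       # delta(raw) / delta(median-filtered)
    nsp: int = 0                     # spindles in epoch
    nar: int = 0                     # arousals starting in epoch
    lar: float = 0.0                 # arousal seconds overlapping epoch
    rapid_eye: int = 0
    slow_eye: int = 0

    @property
    def delta_fraction(self) -> float:
        total = sum(self.band_power.values())
        return self.band_power["delta"] / total if total > 0 else 0.0

    @property
    def total_eeg_power(self) -> float:
        return float(sum(self.band_power.values()))


def band_powers(
    epoch: np.ndarray,
    rate: float,
    scheme: BandScheme,
    window_s: float = 2.0,
) -> dict[str, float]:
    """Integrate a Welch PSD (Hamming window, 50% overlap) over each band."""
    psd_f, psd = _welch(np.asarray(epoch, float)[None, :], rate, window_s)
    out: dict[str, float] = {}
    for name, (lo, hi) in scheme.all_bands.items():
        if hi > rate / 2 + 1e-9:
            raise ValueError(f"band {name!r} upper edge {hi} Hz above Nyquist {rate/2}")
        out[name] = float(_integrate_band(psd_f, psd, lo, hi)[0])
    return out


def _welch(epochs: np.ndarray, rate: float, window_s: float):
    nperseg = int(round(window_s * rate))
    nperseg = min(nperseg, epochs.shape[-1])
    return signal.welch(
        epochs,
        fs=rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=-1,
    )


def _integrate_band(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float):
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return psd[..., mask].sum(axis=-1) * df


def compute_ratios(
    band_power: dict[str, float],
    emg_power: float,
    delta_raw: float,
    delta_filtered: float,
    eps: float = 1e-12,
) -> tuple[float, float, float, float]:
    """SBI, DBI, BEI, EMI with guarded denominators.

    Denominators are floored at ``eps`` (µV²) so flat or near-flat epochs
    yield finite ratios instead of raising.
    """
    sbi = band_power["sigma"] / max(band_power["beta"], eps)
    dbi = band_power["delta"] / max(band_power["beta"], eps)
    bei = band_power["beta"] / max(emg_power, eps)
    emi = delta_raw / max(delta_filtered, eps)
    return sbi, dbi, bei, emi


# ---------------------------------------------------------------------------
# Event detectors
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, rate: float, lo: float, hi: float, order: int = 4):
    hi = min(hi, 0.999 * rate / 2)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _rms_envelope(x: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    """Sliding-window RMS along the last axis."""
    n = max(int(round(window_s * rate)), 1)
    power = ndimage.uniform_filter1d(x**2, size=n, axis=-1, mode="nearest")
    return np.sqrt(power)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as half-open (start, stop)."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_spindles(
    epochs: np.ndarray,
    rate: float,
    scheme: BandScheme | None = None,
    envelope_factor: float = 2.5,
    min_dur_s: float = 0.5,
    max_dur_s: float = 2.0,
    rms_window_s: float = 0.25,
    threshold: float | None = None,
) -> list[tuple[float, float]]:
    """Detect sleep spindles: sigma-band bursts of bounded duration.

    ``epochs`` is a (n_epochs, block) array.  The sigma envelope (sliding
    RMS of the band-passed signal) must exceed ``threshold`` — by default
    ``envelope_factor`` times the median envelope over the whole epoch
    sequence — for a duration within [min_dur_s, max_dur_s].  Returns
    (start_s, end_s) intervals on the record's time axis.
    """
    scheme = scheme or BandScheme()
    epochs = np.atleast_2d(np.asarray(epochs, float))
    band = _bandpass(epochs, rate, *scheme.sigma)
    env = _rms_envelope(band, rate, rms_window_s).reshape(-1)
    if threshold is None:
        threshold = envelope_factor * float(np.median(env))
    if threshold <= 0:
        return []
    events = []
    for start, stop in _runs(env > threshold):
        # the sliding RMS smears a burst by about one window length
        dur = (stop - start) / rate - rms_window_s
        if min_dur_s <= dur <= max_dur_s:
            events.append((start / rate, stop / rate))
    return events


def detect_arousals(
    epochs: np.ndarray,
    rate: float,
    scheme: BandScheme | None = None,
    power_factor: float = 2.0,
    emg_factor: float = 1.5,
    min_dur_s: float = 3.0,
    max_dur_s: float = 15.0,
    baseline_s: float = 30.0,
    merge_gap_s: float = 1.0,
) -> list[tuple[float, float]]:
    """Detect arousals: abrupt shifts to fast EEG with a concurrent EMG rise.

    The combined alpha+beta envelope and the EMG envelope (1-s sliding RMS)
    are compared to trailing medians over the preceding ``baseline_s``
    seconds; intervals where both exceed their baselines by the configured
    factors — brief sub-threshold dips up to ``merge_gap_s`` are bridged —
    lasting between min and max duration, are arousals.  Events may cross
    epoch boundaries.
    """
    scheme = scheme or BandScheme()
    epochs = np.atleast_2d(np.asarray(epochs, float))
    fast = _bandpass(epochs, rate, scheme.alpha[0], scheme.beta[1])
    emg = _bandpass(epochs, rate, *scheme.emg)
    hop = max(int(round(_GRID_HOP_S * rate)), 1)
    env_fast = _rms_envelope(fast, rate, 1.0).reshape(-1)[::hop]
    env_emg = _rms_envelope(emg, rate, 1.0).reshape(-1)[::hop]
    grid_rate = rate / hop

    base_fast = _trailing_median(env_fast, int(round(baseline_s * grid_rate)))
    base_emg = _trailing_median(env_emg, int(round(baseline_s * grid_rate)))
    mask = (env_fast > power_factor * base_fast) & (env_emg > emg_factor * base_emg)
    merged: list[list[int]] = []
    for start, stop in _runs(mask):
        if merged and start - merged[-1][1] < merge_gap_s * grid_rate:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    for start, stop in merged:
        dur = (stop - start) / grid_rate
        if min_dur_s <= dur <= max_dur_s:
            events.append((start / grid_rate, stop / grid_rate))
    return events


def _trailing_median(x: np.ndarray, window: int) -> np.ndarray:
    """Median of the preceding ``window`` points (excluding the current one)."""
    s = pd.Series(x)
    base = s.shift(1).rolling(window, min_periods=max(window // 4, 1)).median()
    fallback = float(np.median(x)) if x.size else 0.0
    return base.fillna(fallback).to_numpy()


def detect_eye_movements(
    epochs: np.ndarray,
    rate: float,
    amplitude: float = 75.0,
    slope: float = 150.0,
    lowpass_hz: float = 6.0,
    merge_gap_s: float = 0.2,
) -> list[tuple[float, float, str]]:
    """Detect eye-movement deflections and split them by peak slope.

    The signal is low-passed, excursions beyond ±``amplitude`` µV are
    grouped into deflection events (gaps shorter than ``merge_gap_s`` are
    merged), and each event is labelled ``"rapid"`` if its peak slope
    reaches ``slope`` µV/s, else ``"slow"``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, float))
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    low = signal.sosfiltfilt(sos, epochs, axis=-1).reshape(-1)
    mask = np.abs(low) > amplitude
    runs = _runs(mask)
    merged: list[list[int]] = []
    gap = merge_gap_s * rate
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    deriv = np.gradient(low) * rate
    for start, stop in merged:
        peak_slope = float(np.max(np.abs(deriv[start:stop])))
        kind = "rapid" if peak_slope >= slope else "slow"
        events.append((start / rate, stop / rate, kind))
    return events


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def extract_features(
    epoched: EpochedSignal, config: StagerConfig | None = None
) -> list[EpochFeatures]:
    """Compute one :class:`EpochFeatures` record per epoch.

    Deterministic for a fixed input; sub-detectors run over the whole
    epoch sequence so events crossing epoch boundaries are still caught
    (each event is attributed to the epoch containing its onset; arousal
    length is split over the epochs it overlaps).
    """
    config = config or StagerConfig()
    scheme = config.scheme
    thr = config.thresholds
    rate = epoched.sampling_rate
    epochs = epoched.epochs
    n_epochs, block = epochs.shape
    epoch_len = epoched.epoch_length

    freqs, psd = _welch(epochs, rate, config.welch_window_s)
    powers = {
        name: _integrate_band(freqs, psd, lo, hi)
        for name, (lo, hi) in scheme.all_bands.items()
    }

    # EMI: delta power before vs after median filtering the epoch
    k = int(round(config.emi_median_s * rate)) | 1  # odd kernel
    filtered = ndimage.median_filter(epochs, size=(1, k), mode="nearest")
    f2, psd_filt = _welch(filtered, rate, config.welch_window_s)
    delta_filt = _integrate_band(f2, psd_filt, *scheme.delta)

    spindles = detect_spindles(
        epochs,
        rate,
        scheme,
        envelope_factor=thr.spindle_envelope_factor,
        min_dur_s=thr.spindle_min_dur_s,
        max_dur_s=thr.spindle_max_dur_s,
        rms_window_s=config.envelope_rms_s,
    )
    arousals = detect_arousals(
        epochs,
        rate,
        scheme,
        power_factor=thr.arousal_power_factor,
        emg_factor=thr.arousal_emg_factor,
        min_dur_s=thr.arousal_min_dur_s,
        max_dur_s=thr.arousal_max_dur_s,
    )
    eyes = detect_eye_movements(
        epochs, rate, amplitude=thr.eye_amplitude, slope=thr.eye_slope
    )

    nsp = np.zeros(n_epochs, int)
    for start_s, _ in spindles:
        nsp[min(int(start_s // epoch_len), n_epochs - 1)] += 1
    nar = np.zeros(n_epochs, int)
    lar = np.zeros(n_epochs, float)
    for start_s, end_s in arousals:
        nar[min(int(start_s // epoch_len), n_epochs - 1)] += 1
        for e in range(int(start_s // epoch_len), min(int(end_s // epoch_len) + 1, n_epochs)):
            lar[e] += max(0.0, min(end_s, (e + 1) * epoch_len) - max(start_s, e * epoch_len))
    rapid = np.zeros(n_epochs, int)
    slow = np.zeros(n_epochs, int)
    for start_s, _, kind in eyes:
        e = min(int(start_s // epoch_len), n_epochs - 1)
        (rapid if kind == "rapid" else slow)[e] += 1

    out: list[EpochFeatures] = []
    for i in range(n_epochs):
        bp = {name: float(powers[name][i]) for name in scheme.eeg_bands}
        emg_p = float(powers["emg"][i])
        sbi, dbi, bei, emi = compute_ratios(
            bp, emg_p, bp["delta"], float(delta_filt[i])
        )
        out.append(
            EpochFeatures(
                band_power=bp,
                emg_power=emg_p,
                sbi=sbi,
                dbi=dbi,
                bei=bei,
                emi=emi,
                nsp=int(nsp[i]),
                nar=int(nar[i]),
                lar=float(min(lar[i], epoch_len)),
                rapid_eye=int(rapid[i]),
                slow_eye=int(slow[i]),
            )
        )
    return out


def features_to_frame(features: list[EpochFeatures]) -> pd.DataFrame:
    """Flatten feature records into a per-epoch DataFrame (for CSV dumps)."""
    rows = []
    for i, f in enumerate(features):
        row = {"epoch": i}
        row.update({f"power_{k}": v for k, v in f.band_power.items()})
        row.update(
            emg_power=f.emg_power,
            sbi=f.sbi,
            dbi=f.dbi,
            bei=f.bei,
            emi=f.emi,
            delta_fraction=f.delta_fraction,
            nsp=f.nsp,
            nar=f.nar,
            lar=f.lar,
            rapid_eye=f.rapid_eye,
            slow_eye=f.slow_eye,
        )
        rows.append(row)
    return pd.DataFrame(rows)
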