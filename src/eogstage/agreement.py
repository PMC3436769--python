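"""Manual-vs-automated agreement statistics.

Epoch-by-epoch cross-tabulation of two hypnograms, per-stage Cohen's kappa
(one-vs-rest collapse of the 5×5 table to 2×2), row-percentage and overall
agreement, reconstruction of counts from published percentage tables,
intraclass correlation of per-subject staged minutes, per-subject
sensitivity/PPV with a minimum-epochs inclusion rule, sleep-onset
detection (first run of three consecutive non-wake epochs), onset
difference binning, sleep summaries (TST, sleep efficiency, RDI) and
Bland–Altman bias with ±2·SD limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import STAGES, Hypnogram, RespiratoryEventList

#: Sentinel for quantities that are undefined rather than erroneous.
UNDEFINED = float("nan")


@dataclass
class ConfusionTable:
    """5×5 epoch counts; rows = manual stage, columns = automated stage."""

    counts: np.ndarray
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (5, 5):
            raise ValueError("confusion table must be 5×5")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class AgreementReport:
    kappa: dict[str, float]
    row_percent: dict[str, list[float]]
    overall_percent: float
    sensitivity: dict[str, float]
    ppv: dict[str, float]
    row_totals: dict[str, int]
    col_totals: dict[str, int]
    total_epochs: int


@dataclass
class SleepSummary:
    tst_min: float
    sleep_efficiency_pct: float
    onset_epoch: int | None
    rdi: float  # NaN when undefined (no sleep)


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    lower: float
    upper: float
    differences: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Tables and kappa
# ---------------------------------------------------------------------------

def confusion_matrix(manual: Hypnogram, auto: Hypnogram) -> ConfusionTable:
    """Cross-tabulate two equal-length hypnograms epoch by epoch."""
    if len(manual) != len(auto):
        raise ValueError(f"length mismatch: {len(manual)} vs {len(auto)}")
    counts = np.zeros((5, 5), dtype=int)
    mi, ai = manual.as_indices(), auto.as_indices()
    np.add.at(counts, (mi, ai), 1)
    return ConfusionTable(counts=counts)


def per_stage_kappa(table: ConfusionTable, stage: str) -> float:
    """Cohen's kappa for one stage after one-vs-rest collapse to 2×2.

    kappa = (Po − Pe) / (1 − Pe) with Po the observed binary accuracy and
    Pe the chance agreement expected from the collapsed margins; returns 0
    when Pe = 1 (both raters constant).
    """
    s = table.stage_order.index(stage)
    n = table.total
    tp = table.counts[s, s]
    fn = table.counts[s].sum() - tp
    fp = table.counts[:, s].sum() - tp
    tn = n - tp - fn - fp
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n**2
    if pe >= 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def percent_agreement(table: ConfusionTable) -> tuple[dict[str, list[float]], float]:
    """Row percentages (manual-stage rows, NaN for empty rows) and the
    overall percent agreement (100 × trace / total)."""
    rows: dict[str, list[float]] = {}
    for i, stage in enumerate(table.stage_order):
        total = table.counts[i].sum()
        if total == 0:
            rows[stage] = [UNDEFINED] * 5
        else:
            rows[stage] = list(100.0 * table.counts[i] / total)
    overall = 100.0 * np.trace(table.counts) / table.total
    return rows, float(overall)


def reconstruct_counts(
    row_percentages: np.ndarray, row_totals: np.ndarray, tolerance: float = 0.5
) -> ConfusionTable:
    """Rebuild integer counts from a published percentage table.

    Each entry is the row total times the printed percentage, rounded to
    the nearest integer; any rounding residual (at most ±2 epochs) is
    absorbed by the row's largest cell so row sums match the printed
    totals exactly.
    """
    pct = np.asarray(row_percentages, float)
    totals = np.asarray(row_totals, int)
    sums = pct.sum(axis=1)
    if np.any(np.abs(sums - 100.0) > tolerance):
        raise ValueError(f"row percentages sum to {sums}; expected ≈100")
    counts = np.rint(pct / 100.0 * totals[:, None]).astype(int)
    for i in range(counts.shape[0]):
        residual = totals[i] - counts[i].sum()
        counts[i, counts[i].argmax()] += residual
    return ConfusionTable(counts=counts)


def agreement_report(table: ConfusionTable) -> AgreementReport:
    """Bundle kappa, percentage agreement and pooled sensitivity/PPV."""
    rows, overall = percent_agreement(table)
    kappas = {s: per_stage_kappa(table, s) for s in table.stage_order}
    sens: dict[str, float] = {}
    ppv: dict[str, float] = {}
    for i, s in enumerate(table.stage_order):
        tp = table.counts[i, i]
        man = table.counts[i].sum()
        auto = table.counts[:, i].sum()
        sens[s] = 100.0 * tp / man if man else UNDEFINED
        ppv[s] = 100.0 * tp / auto if auto else UNDEFINED
    return AgreementReport(
        kappa=kappas,
        row_percent=rows,
        overall_percent=overall,
        sensitivity=sens,
        ppv=ppv,
        row_totals=dict(zip(table.stage_order, table.row_totals().tolist())),
        col_totals=dict(zip(table.stage_order, table.col_totals().tolist())),
        total_epochs=table.total,
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc(x: np.ndarray, y: np.ndarray, form: str = "icc2_1") -> float:
    """Intraclass correlation between two raters' per-subject values.

    Default is ICC(2,1): two-way random effects, absolute agreement,
    single measures, from the classical mean squares.  ``form="icc3_1"``
    gives the consistency variant (rater treated as fixed).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subject pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero variance in both raters")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "icc2_1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3_1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        return 0.0
    if form == "icc2_1":
        return float((msr - mse) / denom)
    return float((msr - mse) / denom)


def staged_minutes(h: Hypnogram, stage: str) -> float:
    """Minutes the hypnogram spends in one stage."""
    return sum(s == stage for s in h.stages) * h.epoch_length / 60.0


# ---------------------------------------------------------------------------
# Per-subject accuracy
# ---------------------------------------------------------------------------

def sensitivity_ppv(
    manual: Hypnogram, auto: Hypnogram, stage: str, min_manual_epochs: int = 20
) -> tuple[float, float] | None:
    """Per-subject sensitivity and PPV (%) for one stage.

    Subjects with fewer than ``min_manual_epochs`` manually scored epochs
    of the stage are excluded (returns None).  If the automated scorer
    never emits the stage, PPV is NaN and sensitivity 0.
    """
    if len(manual) != len(auto):
        raise ValueError("length mismatch")
    m = np.array([s == stage for s in manual.stages])
    a = np.array([s == stage for s in auto.stages])
    if m.sum() < min_manual_epochs:
        return None
    tp = int((m & a).sum())
    sens = 100.0 * tp / int(m.sum())
    ppv = 100.0 * tp / int(a.sum()) if a.sum() else UNDEFINED
    return sens, ppv


# ---------------------------------------------------------------------------
# Sleep onset and summaries
# ---------------------------------------------------------------------------

def sleep_onset(h: Hypnogram, run_length: int = 3) -> int | None:
    """Index of the first epoch of the earliest run of ≥3 consecutive
    non-wake epochs; None if sleep is never reached."""
    run = 0
    for i, stage in enumerate(h.stages):
        run = run + 1 if stage != "W" else 0
        if run == run_length:
            return i - run_length + 1
    return None


ONSET_BINS = ("<=3", "4-10", "11-20", ">20")


def onset_difference_bin(
    manual_onset: int | None, auto_onset: int | None, epoch_length: float = 30.0
) -> str | None:
    """Bin the absolute onset difference in minutes: (−,3], (3,10], (10,20], (20,∞)."""
    if manual_onset is None or auto_onset is None:
        return None
    diff_min = abs(manual_onset - auto_onset) * epoch_length / 60.0
    if diff_min <= 3.0:
        return "<=3"
    if diff_min <= 10.0:
        return "4-10"
    if diff_min <= 20.0:
        return "11-20"
    return ">20"


def sleep_summary(
    h: Hypnogram,
    recording_minutes: float | None = None,
    events: RespiratoryEventList | None = None,
) -> SleepSummary:
    """TST (minutes of non-wake epochs), sleep efficiency (% of recording
    time) and RDI (events per hour of sleep; NaN when TST is zero)."""
    epoch_min = h.epoch_length / 60.0
    if recording_minutes is None:
        recording_minutes = len(h) * epoch_min
    if recording_minutes < len(h) * epoch_min - 1e-9:
        raise ValueError("recording time shorter than the hypnogram span")
    tst = sum(s != "W" for s in h.stages) * epoch_min
    se = 100.0 * tst / recording_minutes if recording_minutes > 0 else UNDEFINED
    n_events = events.count if events is not None else 0
    rdi = n_events / (tst / 60.0) if tst > 0 else UNDEFINED
    return SleepSummary(
        tst_min=tst,
        sleep_efficiency_pct=se,
        onset_epoch=sleep_onset(h),
        rdi=rdi,
    )


def bland_altman(pairs: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman analysis of (manual, automated) value pairs.

    Differences are automated − manual; bias is their mean and the limits
    of agreement are bias ± 2·SD (population SD, ddof=1).
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 (manual, auto) pairs")
    diff = pairs[:, 1] - pairs[:, 0]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, lower=bias - 2 * sd, upper=bias + 2 * sd,
        differences=diff,
    )
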