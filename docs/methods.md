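# Methods

## Staging signal and preprocessing

The stager operates on a single differential channel, right EOG minus left
EOG. Conjugate eye movements are anti-phase on the two electrodes and add in
the difference; frontal EEG is picked up by both with unequal gains, so a
usable fraction survives the subtraction. Recordings at 128 Hz are upsampled
to 256 Hz by linear interpolation because the detector filters are designed
at 256 Hz; upsampling is restricted to integer factors, and the final
fractional samples hold the last value rather than extrapolate. A 2nd-order
Butterworth high-pass at 0.3 Hz (zero-phase, config: `highpass_hz`, set
`None` to disable) removes electrode drift; no notch filter is applied.
Epoching is gap-free from sample 0 in fixed 30-s blocks; a trailing partial
epoch is dropped and its sample count recorded. A `start_offset_s` parameter
allows alignment with an externally scored hypnogram, and `--swap-eog`
covers mislabeled montages. EDF digital values are converted to physical µV
on read, because several thresholds are absolute amplitudes.

## Features

Band powers integrate a Welch PSD (2-s Hamming windows, 50% overlap, hence
0.5 Hz resolution on a 30-s epoch) over δ 0.75–4, θ 4–8, α 8–12, σ 12–16,
β 16–32 and EMG 32–64 Hz. Band-integrated power (µV²) is used rather than
per-Hz density averages; the ratio features are insensitive to the
difference up to a bandwidth constant. Ratio denominators are floored at
ε = 10⁻¹² µV² so flat epochs yield finite ratios. EMI divides the epoch's
δ power by the δ power after a 0.25-s median filter: smooth slow waves pass
the filter nearly unchanged (EMI ≈ 1) while sharp transients are crushed by
it (EMI ≫ 1), making EMI an artifact/transient index.

Event detectors (all parameters among the 23 named thresholds):

* **Spindles** — σ-band (12–16 Hz) sliding-RMS envelope (0.25 s) above
  2.5 × the record-median envelope for 0.5–2.0 s. The measured crossing is
  shortened by one envelope-window length before the duration test, since
  the sliding RMS smears a burst by about that much. A relative threshold
  makes the detector amplitude-invariant but means it degrades on records
  consisting almost entirely of spindle-rich sleep, where the median itself
  rises — acceptable for whole-night records.
* **Arousals** — 1-s RMS envelopes of the 8–32 Hz and EMG bands must exceed
  2.0 × and 1.5 × their trailing 30-s medians simultaneously for 3–15 s;
  sub-threshold dips shorter than 1 s are bridged. Events may cross epoch
  boundaries; the count (NAR) goes to the epoch containing the onset and the
  length (LAR) is split over the epochs overlapped.
* **Eye movements** — excursions of the 6 Hz-low-passed signal beyond
  ±75 µV, split by peak slope at 150 µV/s into rapid (REM-like) and slow
  (blink / slow pursuit) deflections.

Filtering is applied epoch-wise, so features are local to their epoch up to
the two deliberate exceptions (spindle median threshold, arousal trailing
baseline); this is what makes the permutation-locality property exact.

## Decision tree

Strict first-match branch order: wake (EMG power > threshold ∧ BEI >
threshold, or ≥ 4 slow deflections, or EMI > 12, or a dense trailing run of
arousals) → N3 (DBI > 130 ∧ δ-fraction > 0.84 ∧ EMG below a ceiling) →
REM (EMG < 5 µV² ∧ ≥ 1 rapid eye movement ∧ SBI < 0.55 ∧ no spindles) →
N2 (≥ 1 spindle ∨ SBI > 0.7) → N1. N1 is deliberately the fall-through
leaf: it is the transitional stage human scorers agree on least, so no
positive evidence is demanded for it. Every decision records which branch
fired. Smoothing (3-epoch majority filter) is off by default; ties keep the
centre label.

The original clinical threshold values are unpublished, so the shipped
defaults were fixed once against a fixed-seed synthetic training record
(240 epochs, normal profile, seed 11) by coordinate search on the handful
of binding thresholds, and are not revisited; every value is exposed in the
YAML config and unknown keys are rejected. Threshold semantics are tied to
the effective EMG band: `adapt_thresholds` converts a config between the
full 32–128 Hz band and the reduced 32–64 Hz band by scaling exactly the
wake EMG-power threshold (× 1/3; "reduced by two thirds" is read as
*to one third*, the reading consistent with a band of half the width) and
the BEI threshold (× 3), leaving the other 21 untouched; the operation is
idempotent per band and invertible between the two bands.

## Synthetic PSG

The generator exists to make every downstream module testable with known
truth. A night is a first-order Markov chain over the five stages at epoch
scale (bout-length semi-Markov structure was considered and rejected as
unnecessary for testing; mean dwell times are controlled instead through
per-stage leave rates). `profile_to_model` builds, for a requested
stationary distribution π and mean bout lengths L, the chain
P = I − diag(r) + diag(r)·q with r_i = 1/L_i and landing weights
q_j ∝ π_j r_j, whose stationary distribution is exactly π.

Severity profiles couple sleep architecture to sleep-disordered breathing:
normal/mild share one empirical stage distribution
(W/N1/N2/N3/R = 18.1/13.4/44.7/10.4/13.4 %), moderate/severe another with
more wake and N1 and much less N3 and REM (30.3/23.2/34.1/3.6/8.7 %), with
RDI targets of 6/15/31/71 events per sleep-hour and arousal-probability
multipliers 1/1.5/2.5/4. Respiratory events are a homogeneous Poisson
process over non-wake epochs at the RDI rate; a random subset spawns 5-s
α+EMG arousal bursts, which is what degrades staging agreement in the
severe profiles the way fragmented sleep does in patients.

Signals are built in the difference domain: per-band Gaussian noise,
band-limited by zero-phase Butterworth filters and scaled per epoch by
stage-specific RMS amplitudes (e.g. δ 90 µV in N3 vs 20–25 elsewhere; EMG
20 µV in W vs 1 µV in REM), plus stage-specific events — 13.5 Hz Hann
spindle bursts in N2 (3.5/epoch, 40 µV), 0.6-s 150 µV conjugate deflections
in REM (5/epoch), 2.5-s 110 µV blink-like deflections in wake (4/epoch).
The difference target D is then split anti-phase across the channels around
a shared in-phase cerebral background C (L = C − D/2, R = C + D/2) with
1 µV independent sensor noise per channel, so deriving REOG − LEOG returns
D exactly up to noise. A single `contrast` dial interpolates all
stage-specific amplitudes toward their across-stage mean and scales event
rates; at `contrast=0` every stage is statistically identical, every epoch
falls through to N1, and recovery of W/N2/N3/R is zero — the
negative control for the recovery property.

What the simulator does **not** emulate: K-complexes, cyclic alternating
pattern, realistic spindle morphology and topography, EMG nonstationarity,
electrode artifacts, or inter-scorer ambiguity. Stage contrasts are cleaner
than in any real recording, so near-perfect recovery on synthetic data
demonstrates the pipeline's internal consistency — signal → features →
tree → agreement — not clinical accuracy; the published agreement tables
bundled in `reference_tables` show what manual-vs-automated comparison
yields on real patients (overall agreement 71%/61%, N1 κ ≈ 0.2).

## Agreement statistics

Per-stage kappa collapses the 5×5 table one-vs-rest to 2×2 and applies
Cohen's κ = (P₀ − Pₑ)/(1 − Pₑ); κ is defined as 0 when Pₑ = 1. This variant
was chosen because it reproduces, from the printed row percentages and
totals alone, all ten published per-stage kappas of the bundled reference
tables to two decimals. Count reconstruction rounds pct × row-total to the
nearest integer and absorbs the ±2-epoch rounding residual into the row's
largest cell. ICC defaults to ICC(2,1) — two-way random effects, absolute
agreement, single measures, computed from the classical mean squares — with
ICC(3,1) selectable; the choice matters when a scorer has a constant bias,
which consistency-type coefficients forgive. Bland–Altman limits use
bias ± 2·SD exactly (not 1.96·SD), differences oriented automated − manual.
Sleep onset is the first epoch of the earliest run of ≥ 3 consecutive
non-wake epochs; onset differences are binned (in minutes) into (−, 3],
(3, 10], (10, 20], (20, ∞). TST counts non-wake epochs × 0.5 min; sleep
efficiency divides by an explicitly supplied recording time (no
lights-off/on trimming is attempted); RDI divides the respiratory event
count by TST in hours and is flagged undefined when TST = 0. Per-subject
sensitivity/PPV exclude subjects with fewer than 20 manually scored epochs
of the stage.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical fixtures.
The bundled test and acceptance workloads use records of 120–960 epochs
(1–8 h), sizes at which every stage accumulates enough epochs for stable
recovery estimates while a full simulate-and-stage cycle stays in the tens
of seconds. Known numerical edge cases: all-zero records stage to N1 with
all ratios 0 by the ε-guard; empty confusion tables are rejected; zero
manual rows yield NaN row percentages rather than exceptions.

## Known limitations

The tree consults only the current epoch (plus the trailing arousal
window); REM continuity rules used by human scorers are not modelled, so
isolated REM epochs without detected eye movements fall to N1/N2. The
spindle detector's relative threshold assumes a whole-night mix of stages.
Threshold defaults are tuned to the synthetic signal model, not to any
clinical population — on real data they are a starting point for the
config-driven tuning workflow (`eogstage features` dumps per-epoch features
for exactly that purpose).
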