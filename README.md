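# eogstage

Automated five-stage sleep staging (W, N1, N2, N3, R) from a single
**differential electrooculography channel** (REOG − LEOG), together with the
full statistical toolkit used to validate automated scorers against manual
polysomnography, and a synthetic PSG generator so the whole pipeline can be
exercised without any recorded data.

It is aimed at sleep researchers and engineers working with reduced-montage
recordings (home sleep tests, forehead/EOG-only wearables), where the two EOG
electrodes are the only EEG-bearing channels available: their difference
amplifies conjugate eye movements while retaining frontal EEG, which carries
enough spectral structure to stage sleep.

## The algorithm

Each 30-second epoch of the differential signal (resampled to 256 Hz by
linear interpolation when recorded at 128 Hz) is summarised by:

* Welch band powers in the conventional bands — δ (0.75–4 Hz), θ (4–8),
  α (8–12), σ (12–16), β (16–32) — plus EMG power (32–64 Hz);
* four ratios: **SBI** = σ/β, **DBI** = δ/β, **BEI** = β/EMG, and
  **EMI** = δ(raw)/δ(median-filtered), a transient/artifact index;
* event counts: sleep spindles (**NSP**), arousals (**NAR**, length **LAR**)
  and rapid/slow eye movements.

A hierarchical decision tree with 23 named, config-exposed thresholds then
assigns the stage: a wake gate (wakeful muscle tone or blink evidence) →
N3 (slow-wave dominance: DBI and δ-fraction) → REM (atonia + rapid eye
movements + no spindles) → N2 (spindles or high SBI) → N1 as the
fall-through. When only the reduced 32–64 Hz EMG band is available, the EMG
power threshold is multiplied by 1/3 and the BEI threshold by 3; the other
21 thresholds are untouched.

The `agreement` module implements the matching validation statistics:
epoch-by-epoch confusion tables, per-stage one-vs-rest Cohen's κ,
sensitivity/PPV with a 20-epoch inclusion rule, ICC(2,1) of staged minutes,
sleep onset (first run of three consecutive non-wake epochs), TST / sleep
efficiency / RDI summaries, and Bland–Altman bias with ±2·SD limits. It can
also reconstruct integer contingency tables from published row-percentage
tables.

## Worked example

`python examples/reconstruct_published_table.py` rebuilds two bundled
reference agreement tables (printed as row percentages + row totals) and
recomputes the per-stage kappas:

```
normal_mild: 40641 epochs, overall agreement 71.3%
   W: kappa 0.67 (published 0.67)
  N1: kappa 0.21 (published 0.21)
  N2: kappa 0.60 (published 0.60)
  N3: kappa 0.76 (published 0.76)
   R: kappa 0.72 (published 0.72)
moderate_severe: 29938 epochs, overall agreement 60.8%
   W: kappa 0.60 (published 0.60)
  ...
```

All ten published kappas are reproduced to two decimals from the printed
percentages alone — note the characteristic pattern: N1 agreement is poor
(κ ≈ 0.2) while every other stage is moderate-to-substantial, and agreement
drops as sleep-disordered breathing fragments sleep.

`python examples/simulate_and_stage.py` simulates a 2-hour night and stages
it end to end:

```
staged 240 epochs; overall agreement 99.6%
   W:   29 truth epochs, recovery 100.0%
  N1:   45 truth epochs, recovery 100.0%
  N2:  110 truth epochs, recovery 100.0%
  N3:   29 truth epochs, recovery 100.0%
   R:   27 truth epochs, recovery  96.3%
```

(Recovery on clean synthetic data is far above what manual-vs-automated
comparison achieves on real recordings; see `docs/methods.md` for what the
simulator does and does not emulate.)

A CLI mirrors the library: `eogstage simulate`, `eogstage stage`,
`eogstage features`, `eogstage agree`, `eogstage cohort-agree`
(see `eogstage --help`).

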