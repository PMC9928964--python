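# earsleep

Analysis pipeline for **at-home sleep monitoring with ear-EEG**:
EEG recorded from four electrodes inside the two ear canals (EL1, EL2
left; ER1, ER2 right, all against a left-ear reference), staged
automatically without the full polysomnography (PSG) lab setup.

The package is written for sleep researchers who have (or simulate)
multi-night ear-EEG recordings and want a complete, tested path from
raw signal to study-level statistics:

1. **Artifact handling** — zero-phase 0.1–100 Hz bandpass with 50/100 Hz
   notches, then four detectors: periodic device spikes (200 ms
   repetition rate), short transient spikes, long (>30 s)
   high-frequency noise, and samples beyond ±350 µV.  Spike-type
   artifacts are repaired by interpolation; a recording is rejected
   when >30% of the signal is noisy or it is shorter than 5 h.
2. **Cross-ear channel selection** — for every 30 s epoch, the
   derivation `R − L` with the lowest RMS is kept, where
   `R ∈ {ER1, ER2, (ER1+ER2)/2}` and `L ∈ {EL1, EL2, (EL1+EL2)/2, ref}`
   (noisy channels have high RMS, so the quietest cross-ear pair wins).
3. **Staging** — 84 features per epoch (time, frequency, CWT, EMG/EOG
   proxies, sleep-event proxies, non-linear), z-scored per recording,
   classified by a 100-tree random forest into W/N1/N2/N3/REM.
   The fraction of trees voting for the winning stage is the epoch's
   **confidence**; its mean over a night predicts scoring quality for
   unlabeled recordings.  Agreement with manual scoring is measured by
   Cohen's κ under leave-one-subject-out (LOSO) cross-validation.
4. **Sleep metrics and study statistics** — per night: REM fraction,
   N3 fraction, sleep efficiency `SE = sleep epochs / epochs from sleep
   onset`, and four transition rates (NREM→NREM, NREM→REM, REM→REM,
   REM→NREM, each normalized by the source-stage epoch count).  Across
   a study each metric is modelled as
   `metric ~ 1 + subject + part + equipment + (1 | recording)`
   (linear mixed model, REML estimates, likelihood-ratio p-values).

Because real ear-EEG sleep datasets are rarely shareable, the package
ships a first-class **synthetic generator**: Markov-chain hypnograms,
stage-dependent band-limited signals with spindle and eye-movement
events, and all four artifact classes injected with exact ground-truth
masks — so every stage of the pipeline is testable end to end.

## Worked example

```python
from earsleep.pipeline import StudyDesign, simulate_study, run_study
from earsleep.preprocess import PreprocessConfig

design = StudyDesign(n_subjects=5, nights_labeled=2, nights_unlabeled=1,
                     n_epochs=60)
recordings = simulate_study(design, seed=3)
res = run_study(recordings, seed=3,
                cfg=PreprocessConfig(min_duration_h=0.0))  # short nights
print(res["table"][["subject", "part", "kappa", "confidence"]].head(6))
print("mean LOSO kappa:", round(res["table"]["kappa"].dropna().mean(), 3))
```

prints (seed 3):

```
  subject part     kappa  confidence
0     S00    A  1.000000    0.981500
1     S00    A  0.805825    0.801167
2     S00    B       NaN    0.885833
3     S01    A  0.909434    0.902333
4     S01    A  0.397715    0.794833
5     S01    B       NaN    0.849500
mean LOSO kappa: 0.829
```

Each part-A night is scored by a forest trained on the other subjects;
`kappa` is its agreement with the generator's ground-truth hypnogram
and `confidence` the mean winning-vote fraction.  Part-B nights carry
no labels, so only confidence is reported — exactly the situation the
confidence measure exists for.  `res["lmm"]` holds the mixed-model
p-values per sleep metric and `res["percentile_report"]` grades the
unlabeled nights against the labeled κ quartiles.

The same flows are available from the shell:

```bash
earsleep simulate --subjects 2 --nights 2 --epochs 120 --seed 7 --out data/
earsleep preprocess data/S00_night0.edf --report qc.json
earsleep metrics data/S00_night0_truth.csv
earsleep study --subjects 10 --epochs 120 --seed 7 --out results/
```

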