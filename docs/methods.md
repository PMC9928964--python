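# Methods

This note documents the models and procedures implemented in
`earsleep`, the parameter choices that matter, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Signal model and preprocessing

Recordings are four ear-canal electrodes (EL1, EL2, ER1, ER2) sampled
at 250 Hz against a shared left-ear reference, stored as EDF with a
fixed ±1000 µV physical range (comfortably covering the ±350 µV
rejection bound; 16-bit quantization ≈ 0.03 µV/step).

Each channel is cleaned with zero-phase IIR filters: 50 and 100 Hz
notches (2nd-order, Q = 30) followed by a 4th-order Butterworth
0.1–100 Hz bandpass, all applied forward–backward.  The notches run
first: when strong line noise is present, the bandpass's slow 0.1 Hz
edge transient would otherwise smear tone energy to where the notch
cannot remove it.  In steady state the order is immaterial.

Four artifact detectors run per channel in fixed precedence
(device-periodic → transient spike → high-frequency → amplitude; the
first to claim a sample wins):

- **Transient spikes.**  Deviation from a running-median baseline
  (0.5 s window, computed on a 50 Hz-decimated copy) is compared to
  8 robust standard deviations (1.4826·MAD).  Runs no longer than
  100 ms get a ±20 ms guard band.  A run is only a spike when it is
  *isolated*: if >20% of its 2 s neighbourhood exceeds half the
  threshold, the stretch is sustained noise and is left to the HF and
  amplitude detectors.
- **Periodic device spikes** (200 ms repetition).  The device spikes
  are ~2 samples wide and spectrally flat, so candidates are detected
  on a 20 Hz-highpassed residual (6·MAD threshold): the highpass
  removes the large low-frequency sleep EEG while keeping most of the
  spike energy, making weak spikes on deep-sleep background stand out.
  A candidate is periodic when the neighbouring candidates (±1 s)
  predominantly sit on its 200 ms grid (±2 samples of jitter, at least
  3 spikes per train, grid purity ≥ 0.35): true trains — even
  interleaved ones from overlapping bouts — have purity near 1, while
  the dense threshold crossings inside sustained HF noise are uniform
  in phase and fail the gate, so the periodic detector never swallows
  an HF segment.  Grid positions *between* two phase-consistent
  confirmed onsets are then claimed outright (the noise sits on a
  strict grid), and bout edges are extended outward along the grid
  while a weak 2.5·MAD local test still sees a spike.
- **High-frequency noise.**  40–100 Hz power in 1 s windows,
  thresholded at 5× the recording's median window power; only maximal
  runs longer than 30 s are marked (shorter bursts are normal EMG).
- **Amplitude.**  |x| strictly greater than 350 µV, evaluated on the
  DC-corrected *unfiltered* signal: the bound concerns recorded
  physical amplitude, and the highpass would shave the peaks of
  borderline excursions.

Periodic and transient spike samples are removed and linearly
interpolated from the neighbouring clean samples (edges hold the
nearest clean value); HF and amplitude samples are left in place but
stay masked.  A channel-epoch is invalid when >10% of its samples
carry non-repaired (HF/amplitude) masks or >25% carry any mask.  A
recording is rejected when the masked fraction averaged over channels
exceeds 30% or the duration is under 5 h; the repaired and rejected
fractions are reported separately because "noisy" can reasonably
include or exclude repaired samples.  For deliberately short simulated
nights the duration rule is waived (`min_duration_h=0`).

## Channel selection

For each 30 s epoch all 12 cross-ear derivations R−L are formed
(R ∈ {ER1, ER2, avg}; L ∈ {EL1, EL2, avg, ref}; re-referencing to ref
returns the recorded right channel since all channels share that
reference).  A derivation is admissible when every constituent data
channel is valid this epoch — ref carries no validity, so one valid
right-side channel suffices.  The admissible derivation with minimal
RMS wins; exact ties go to the first in the fixed enumeration order.
RMS is computed after interpolation, so repaired spikes do not inflate
it.

## Features and staging

Each accepted epoch yields 84 features in seven categories: 20 time
domain (moments, Hjorth parameters, percentiles, zero crossings, line
length), 24 frequency domain (Welch 2 s Hann windows, 50% overlap:
absolute/relative band powers for delta 0.5–4, theta 4–8, alpha 8–12,
sigma 11–16, beta 16–40 Hz, spectral edges 75/90/95%, spectral
entropy, 9 band ratios), 12 CWT (Morlet band energies on a 125 Hz
resample), 4 EMG proxies (40–100 Hz power statistics), 6 EOG proxies
(0.3–2 Hz power, deflection rate, envelope statistics — slow eye
movements are visible from ear electrodes), 8 sleep-event proxies
(11–16 Hz envelope bursts for spindles; large 0.3–2 Hz cycles for slow
oscillations; large brief biphasic deflections for K-complex-like
events), and 10 non-linear measures (sample entropy at m=2, r=0.2·sd
on a 50 Hz resample, permutation entropies of order 3/5, SVD entropy,
Higuchi/Katz/Petrosian fractal dimensions, DFA exponent, Lempel–Ziv
complexity).  The published feature set for this family of stagers is
specified only by category and total count, so this registry is a
reconstruction with the same structure; every descriptor documents its
formula.  Degenerate inputs are defined everywhere: entropies and
ratios of constant signals return 0, so no NaN ever reaches the
classifier.

Features are z-scored per recording (constant columns → 0), which
removes inter-device gain differences.  Staging uses a random forest
of 100 trees (√84 features per split, unlimited depth, bootstrap);
votes are hard per-tree predictions so every class proportion is an
exact multiple of 1/100.  The winning proportion is the epoch
confidence (range [0.2, 1] for five classes); a recording's confidence
is the mean over epochs.  Validation is leave-one-subject-out: the
model scoring a subject never saw any of that subject's recordings.
Agreement is Cohen's κ computed per recording, with UNSCORED epochs
dropped pairwise and κ ≡ 1 when both hypnograms are identical
constants.

## Sleep metrics and mixed models

Seven per-night metrics: REM fraction, N3 fraction, sleep efficiency,
and four transition rates.  Decisions worth noting: the SE denominator
starts *at* the first non-wake epoch (inclusive); self-pairs such as
N2→N2 count as NREM→NREM transitions (the metric is a per-epoch
continuation rate); UNSCORED epochs break pair adjacency; 0/0
transition rates are 0, while SE without any sleep epoch is reported
missing rather than 0.

Each metric is fitted with
`metric ~ 1 + subject + part + equipment + (1 | recording)` where
*part* distinguishes nights with/without reference PSG, *equipment*
the earpiece type, and the random intercept is the night index.
Estimates use REML; per-effect p-values come from likelihood-ratio
tests between ML refits with and without the effect (χ² with the
effect's degrees of freedom).  The optimizer is gradient-free
(Powell): the profiled likelihood has singular score matrices when the
random-effect variance collapses to zero, which derivative-based
optimizers cannot cross.  Before fitting, the fixed-effect design
matrix is checked for column rank; aliased effects (e.g. equipment
constant within subject, as in a two-cohort design) are reported NA
rather than fitted — in the motivating study design equipment never
varies within subject, so its effect is only identifiable in crossed
designs, and the simulated study crosses it deliberately.

For nights without manual scoring, the 25/50/75th percentiles of the
labeled set's κ values are mapped to confidence thresholds via the
labeled recording whose κ is nearest each percentile (ties → lower
confidence), with thresholds forced monotone so the reported
"fraction of unlabeled nights above threshold" is non-increasing by
construction.

## Synthetic generator

The generator exists so every pipeline stage has ground truth.

- **Hypnograms** are first-order Markov chains whose default
  transition matrix gives stationary stage fractions near healthy
  adult sleep (W 10%, N1 10%, N2 45%, N3 15%, REM 20%) with sticky
  N2/N3 bouts and fragile N1.
- **Signals** are sums of band-limited Gaussian noise, one carrier per
  EEG band, scaled per epoch by stage-specific band powers
  (µV²; N3 delta-dominant, W alpha/beta, N2 with a sigma bump, N1
  theta-dominant, REM low-amplitude with relatively strong beta — the
  "activated" REM EEG).  Defaults were chosen so the five stages are
  linearly separable from relative band powers alone (≥90% five-class
  accuracy), the floor the forest builds on.  Stage events: 1 s,
  13 Hz amplitude-modulated spindle bursts at 2/min in N2 and 0.5–1 Hz
  biphasic eye-movement deflections at 4/min in REM.  The common
  source projects with *opposite polarity* at the two ears (a
  tangential dipole seen from both sides of the head), which is what
  makes cross-ear derivations signal-bearing: R−L sums the
  projections while independent per-channel sensor noise (default
  3 µV) partially cancels.  Without this, minimum-RMS selection would
  systematically prefer signal-cancelling pairs.
- **Artifacts**: periodic spike bouts on an exact 0.2 s grid
  (~8 ms, 120 µV), transient ~40 ms / 300 µV spikes, >30 s bursts of
  40–100 Hz noise, and ±450 µV half-second excursions — each with an
  exact per-sample category mask.  Amplitudes are design choices
  (detectable but not dominant); no published values exist for them.

What the generator does **not** emulate: volume-conduction forward
models, within-stage spectral drift, arousals and stage-transition
dynamics inside an epoch, electrode-impedance drift over the night,
movement/sweat artifacts, or amplifier quantization.  Consequently a
high synthetic LOSO κ (typically ≳0.8) shows the pipeline is wired
correctly and the features carry stage information — it does not
predict κ on real ear-EEG, where ≈0.7 is the realistic level.

## Problem sizes and numerics

Test and validation runs use scaled-down nights as this package's
standard simulation conditions: 120-epoch (1 h) nights at 250 Hz,
10 subjects × 2 labeled + 1 unlabeled nights for the LOSO study, with
sensor noise graded 5–120 µV across recordings — emulating
electrode-contact quality from excellent to poor — so κ and
confidence spread enough to measure their correlation.  Mixed-model power uses
100 simulations of a 20-subject × 12-night table (subject sd = 3×
residual sd); type-I calibration uses 200 simulations of the same
design with a null equipment effect.  (At smaller designs — e.g.
12 subjects × 8 nights, 13 fixed-effect parameters on 96 rows — the
asymptotic χ² LRT is measurably anti-conservative, rejecting ~8% at
α = 0.05; the calibration claim therefore applies at the study-scale
design, not arbitrarily small tables.)  Sample entropy and Lempel–Ziv run on
50 Hz resamples (numba-jitted O(n²) kernels); CWT on 125 Hz resamples.
All randomness flows from explicit seeds; fixed seeds reproduce
bit-identical synthetic data and forest predictions.

## Limitations

- The 84-feature registry matches the published category structure and
  count but not necessarily the original item list.
- The forest is unweighted, so rare stages (N1) are scored worst —
  consistent with published ear-EEG stagers.
- κ values on synthetic data are optimistic (see above); headline
  numbers from real at-home studies cannot be reproduced without the
  original recordings.
- EDF writing supports integer sampling rates and drops trailing
  partial seconds; EDF+ annotations are out of scope.
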