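# Methods

This note documents the model, the evaluation statistics, the synthetic
data, and the numerical choices behind `preictal`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The prediction problem

Epileptic seizure *prediction* (as opposed to detection) asks whether the
minutes-to-hours of scalp EEG before a seizure carry a distinguishable
signature. The package formalizes the problem as patient-specific
classification of short EEG windows into brain states, followed by an
event-level alarm policy:

- **ictal** — the clinically annotated seizure, onset to offset;
- **preictal** — the hour before the onset of a *leading* seizure, the
  positive class;
- **postictal** — the hour after a seizure's offset, a transitional state
  spectrally distinct from baseline;
- **interictal** — baseline, kept at least 5 h after the previous seizure
  and 3 h before the next so the class is not contaminated by peri-ictal
  dynamics;
- **excluded** — recorded time fitting none of the above; never used.

A seizure is *leading* when its onset is more than 60 min after the
previous seizure's offset; only leading seizures are prediction targets,
though every seizure still carves ictal/postictal/excluded zones. The
first seizure of a subject is leading only when a full preictal hour of
recording precedes it (the convention had to be fixed; a shorter preictal
span would make its windows incomparable with the other seizures'). On
conflicts the stage precedence is ictal > preictal > postictal > excluded
> interictal: preictal evidence for a predictable seizure is never
sacrificed to the previous seizure's postictal window, and interictal
purity is maximal. All times live on one per-subject monotonic timeline in
seconds, with half-open `[start, end)` intervals; gaps between recording
files are represented explicitly, and a labeled interval is decided by the
stage of its interior (boundary instants are measure-zero and belong to
the interval on their right).

## Preprocessing

Recordings are split into 5-s non-overlapping windows. Five standard bands
are available — delta 0–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–128 Hz — and the gamma band is the default classifier input, where the
preictal/interictal contrast is strongest. Filters are Hamming
windowed-sinc FIRs with ≈2 Hz transition width (order ≈ 3.3·fs/transition,
423 taps at 256 Hz), applied to the *continuous* record before windowing
so no 5-s window carries filter edge artifacts. The forward-backward
(zero-phase) application is realized as a single overlap-add convolution
with the kernel's autocorrelation, which has the identical |H|² response
at O(N log N) cost; it differs from reflect-padded `filtfilt` only within
one kernel length of the record edges. The gamma band's nominal upper edge
equals Nyquist at 256 Hz, so it is realized as a 30–127.5 Hz passband; the
delta band is a 4 Hz low-pass after per-channel mean removal.

Windows contaminated by muscle (EMG) activity are removed by a
deterministic two-rule screen on the raw (broadband) window: peak absolute
amplitude above 500 µV on any channel, or more than 85% of a channel's
power above 60 Hz. The thresholds are configurable; the defaults are set
so that ordinary background EEG (tens of µV, 1/f-dominated) never
triggers them while EMG-like bursts (hundreds to thousands of µV,
broadband high-frequency) trigger both. Because the interictal class
vastly outnumbers the others, interictal windows are randomly undersampled
(seeded, without replacement) to the size of the smallest positive class
before training.

## Classifier

The classifier is a single-layer LSTM: input sequence → LSTM (128 memory
units) → dropout 0.5 → fully connected → softmax, consuming each window as
time steps × channels (1280 × 23 at the standard settings) and emitting a
probability vector over {preictal, interictal} or {preictal, interictal,
postictal}. The network, backpropagation through time, Adam (learning rate
1e-3, batch 64), inverted dropout, global-norm gradient clipping at 5, and
early stopping (patience 5 on a seeded 10% validation split) are
implemented in numpy inside the package; all randomness flows from one
`numpy.random.Generator`, so fits are exactly reproducible. Per-channel
z-score statistics are computed from the training split only and reapplied
at prediction time. Exact probability ties at prediction resolve to the
non-alarm (interictal) class.

Two training regimes are provided and never mixed in one run: a
chronological first-k-seizures split (train on the first two seizures'
data plus earlier interictal, test on the rest) mirroring clinical
deployment, and leave-one-seizure-out rounds for event-level evaluation,
where every sample is attributed to its nearest leading seizure and each
round trains on the other seizures' samples with interictal rebalanced
inside the training split (no leakage: normalization and balancing are
refit per round). A stratified k-fold mode over pooled samples exists for
segment-level evaluation.

**Reduced profile.** The full-scale architecture is expensive on one CPU,
so tests and the acceptance script use a first-class reduced profile: 32
units, ≤10 epochs, and RMS pooling of the window over non-overlapping
32-point blocks (1280 → 40 time steps). RMS pooling — unlike plain
averaging, which would cancel the oscillation — preserves exactly the
band-power envelope that distinguishes the stages, so the reduced model
tests the same signal pathway at a fraction of the cost.

## Segment-level evaluation

Per-sample labels are fused over segments of length L: a segment is called
preictal when strictly more than half its samples are preictal (binary
task) or strictly more than one third (three-class task; otherwise the
plurality of the remaining classes, ties to interictal). Sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) treat preictal as positive; the
three-class mode additionally reports each stage's true-positive rate.
The minimum time prediction window (MTPW) scan sweeps L from 5 to 150 s
(segments are consecutive runs of L/5 samples inside stretches of constant
true stage, remainders dropped) and reports the smallest L whose
sensitivity and specificity both lie within 0.01 of their maxima over all
larger L. Under an i.i.d. per-sample accuracy model the fused sensitivity
has a binomial closed form — P(X ≥ ⌊L/10⌋+1), X ~ Bin(L/5, acc) — which
the acceptance suite uses as an oracle.

## Event-level evaluation

An alarm is raised when strictly more than 70% of the samples in a
trailing 10-min window (120 samples, sliding one sample at a time; gaps in
the recording reset it) are labeled preictal. The alarm takes effect at
the first sample boundary after the completing sample is fully observed —
one sample of actuation latency — so the largest achievable warning time
is SPH + SOP minus one sample (49.92 min at the defaults), the bound that
10-min-window predictors of this design actually attain. After an alarm,
further alarms are suppressed for SPH + SOP (50 min) so one alarm covers
one prediction window.

An alarm at time t is *correct* when a leading seizure starts inside
`[t+SPH, t+SPH+SOP)`: the seizure prediction horizon SPH (30 min) is
reserved for intervention and must stay seizure-free; the seizure
occurrence period SOP (20 min) is when the seizure must arrive. A seizure
counts as predicted when at least one alarm is correct for it; every alarm
correct for no seizure is a false alarm. Event sensitivity is
predicted/total leading seizures; the false prediction rate (FPR) is false
alarms per evaluated hour, with the denominator being the evaluated
non-ictal test time (interictal in the binary task, where postictal
windows are excluded from the test stream entirely; interictal +
postictal in the three-class task). The warning time of a predicted
seizure is onset minus its first correct alarm.

Chance performance comes from the standard random-predictor argument: a
predictor raising alarms at rate FPR alarms inside one SOP with
probability P = 1 − exp(−FPR·SOP), and predicts at least m of M
independent seizures with probability p = Σ_{i≥m} C(M,i) Pⁱ(1−P)^{M−i}
(evaluated via the regularized binomial tail, exact to machine precision);
p < 0.05 declares the method better than chance.

The postictal drift profile reports, per hour since seizure offset, the
fraction of postictal samples the classifier labels preictal — the
quantity that motivates including postictal as a third class (a binary
model keeps "seeing" preictal signatures for hours after a seizure).

## Synthetic data

The generator emulates the statistical premise the method exploits without
mimicking any particular dataset: per-channel 1/f^α background noise
(α = 1, 30 µV RMS) whose band-resolved power is stage-dependent. By
default the gamma band carries ×1.5 power in preictal and ×1.25 in
postictal spans relative to interictal; seizures are large (300 µV) 5 Hz
rhythmic bursts; optional EMG-like artifacts (default 2/h, 600–2000 µV,
0.2–1 s, >60 Hz) exercise both rules of the artifact screen. Band shaping
extracts the band component with the package's own zero-phase FIR and
rescales it inside each stage span, so measured Welch power ratios track
the configured multipliers directly (within a few percent over spans of
10 min or more). Preictal gamma power builds up linearly over the first
5 min of the preictal hour rather than switching on discontinuously,
reflecting the gradual nature of preictal dynamics; a discontinuous onset
would let a near-perfect classifier alarm at exactly SPH+SOP before
onset, a knife-edge no real predictor sits on. Everything is driven by one
seed; identical seeds give bit-identical signals.

What the generator does *not* model: real electrode montage correlations,
physiologic seizure morphology, non-stationary artifacts, medication or
vigilance effects, and patient-to-patient variability. Passing the
end-to-end tests therefore shows the pipeline recovers a controlled
band-power contrast through the full method — staging, filtering,
windowing, training, fusion, alarms — not that the method attains any
particular performance on clinical EEG.

## Problem sizes used in tests and the acceptance script

End-to-end runs use synthetic subjects at 256 Hz with the standard staging
constants but 4 channels and 2–3 seizures separated by 9-h gaps (roughly
19–28 h of recording), with the reduced model profile. These sizes were
chosen as the smallest at which every stage of the method is exercised
with non-trivial sample counts (≈700 preictal windows per seizure). The
acceptance script runs the leave-one-seizure-out pipeline at the generator
defaults (preictal gamma ×1.5) and reports segment sensitivity/specificity
at 5-s and 120-s fusion, event sensitivity, FPR, mean warning time and the
random-predictor p-value, all computed at run time.

## Known limitations

- The optimizer, loss, learning rate, batch size and epoch budget are
  package choices exposed in the config; reproducibility was preferred
  over fidelity to unknown originals.
- The EDF writer targets plain 16-bit EDF with one physical range for all
  channels; EDF+ annotations, montage re-referencing and non-integer
  sampling-rate resampling are out of scope.
- Per-subject p-values on clinical data depend on the integer m and the
  effective SOP; the package exposes the chance statistics faithfully and
  does not attempt to reconstruct any published per-subject value.
- The three-class task requires sufficient postictal EEG (default ≥10 min
  after artifact rejection); subjects without it fail fast with an
  explicit error rather than silently degrading.
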