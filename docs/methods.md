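# Methods

`eegdaae` implements an EEG biometric identification pipeline built around a
domain-adaptive 3D convolutional autoencoder (DAAE). This note documents the
model, the synthetic data it is validated on, the numerical choices, and the
limits of what the test suite demonstrates.

## Problem and pipeline

Given multi-trial EEG recordings from several subjects across two recording
sessions, the task is closed-set subject identification that survives the
cross-session domain shift: classifiers are trained only on session-1 data and
tested only on session-2 data. The pipeline is

1. **Preprocessing** — notch filters at 60/120/180/240 Hz, a 0.5 Hz high-pass,
   then a band bank splitting each trial into eight analysis bands
   (Delta 1–4 Hz, Theta 4–8, Alpha 8–13, Beta 13–32, De2Be 1–32, Th2Be 4–32,
   Gamma 32–125, All >1 Hz).
2. **Target-domain generation** — per (subject, session, stimulus, band) trial
   set, build decoder targets by *uniform* weighting (the equal-weight trial
   average, one shared target) or *softmin* weighting (each trial re-weighted
   sample-wise by exp(−β·|S_i − R|) normalized over trials, with R the
   cross-trial median; one target per trial). β defaults to 0.1.
3. **Data cubes** — project the 24 electrodes (10–20/10–10 subset) onto a
   plane by a vertex-centered azimuthal equidistant projection, interpolate
   each time point onto a 32×32 grid, truncate 3000 samples to 2880, compress
   time by the median of every 10 samples, stack the 288 frames, and cut nine
   non-overlapping 32×32×32 cubes per trial.
4. **DAAE** — a 3D convolutional autoencoder (strided stride-2 conv encoder,
   mirrored transposed-conv decoder) trained with MSE to reconstruct the
   *target* cube from the *source* cube. Latent features are the per-channel
   means of the bottleneck tensor.
5. **Identification** — KNN / MLP / SVM / random-forest classifiers on the
   latent vectors (one vector per cube, 9 per trial), scored by macro
   one-vs-rest AUC and by pairwise identification accuracy, always under the
   session-1-train / session-2-test split.

## Model details and numerical choices

**Filters.** All filters are zero-phase (forward–backward second-order
sections). Notches are IIR with quality factor 30; high-pass and band-pass are
4th-order Butterworth. Orders and Q are engineering defaults, not part of the
scientific design; the contracts tested are behavioral (≥20 dB notch
rejection, <1 dB passband ripple ≥5 Hz away from a notch, zero group delay).

**Softmin weighting.** The exponent uses the absolute deviation |S−R|: the
weights express similarity to the consensus, so deviations of either sign are
penalized alike. Weights are computed independently per channel and time
sample, with a max-subtraction for numerical stability; at every (channel,
time) they form a simplex over trials (tolerance 1e-9). β = 0 recovers
uniform 1/K weights exactly. The even-K median is the midpoint of the two
central order statistics.

**Montage and rasterization.** Electrode positions are ideal-sphere 10–10
coordinates built by the textbook arc construction (outer ring 72° from the
vertex, midline at 18° steps, intermediate electrodes slerped along their
row's great circle); they are exactly midline-symmetric, and Cz projects to
the origin. Head-disk radius 1 is the outermost electrode arc + 5% margin;
the grid spans [−1.05, 1.05]², row 0 anterior, column 0 left. Interpolation
is piecewise-linear barycentric on the Delaunay triangulation, with
nearest-electrode fill between the hull and the disk edge and zeros outside
the disk; pixels that are an electrode's nearest grid point carry the
electrode value exactly. The whole map is one precomputed linear operator, so
rasterization is exactly linear in the voltages and fast. Amplitudes are not
normalized before rasterization.

**Autoencoder.** Implemented directly in numpy (forward and reverse passes
hand-written, verified against central finite differences in the test suite).
Downsampling is by stride-2 convolution rather than pooling so the decoder
mirror is exact; `n` layers give a latent grid of edge 32/2^n. The 5×5×3
kernel is oriented (time 5, row 5, col 3). The final decoder layer is linear.
Optimizers are Adam/AdamW (decoupled decay on kernels only, 1e-4). Batch size
16 and learning rate 1e-3 are library defaults; the scaled-down runs in the
tests and acceptance script use batch 8 and learning rate 3e-3, which suit
their few-hundred-step budgets. Training pairs: uniform scheme pairs the
source cube of trial i, segment j with the shared target's segment j; softmin
pairs cube (i, j) with target cube (i, j). The autoencoder is always trained
on session-1 cubes only.

A property worth knowing: at smoke scale the *softmin* objective (and the
self-referential identity objective) converge quickly — final training MSE
well under half the initial value within 8 epochs — whereas the *uniform*
objective retains a large irreducible residual, because a shallow local
convolution cannot cancel a trial's private oscillation phase to reproduce
the cross-trial average. The loss-halving smoke check therefore uses the
softmin task.

**Classifiers.** Each family sits behind a standardizing pipeline fitted on
training data only. Multiclass AUC is macro-averaged one-vs-rest on
predicted probabilities (SVM via its built-in calibrated probabilities). The
classification unit is one cube's feature vector; an optional trial-level
majority vote is provided but off by default. Cross-validated model selection
uses folds grouped by trial so a trial's nine cubes never straddle a fold
boundary; the search space mirrors the declared per-family grids, explored
exhaustively or by seeded subsampling. The MLP grid offers relu and logistic
activations (the activations its backend supports). Identifiability is the
row mean of a subject's off-diagonal pairwise accuracies, ranked ascending
with lexicographic tie-break; the least-identifiable subjects can be dropped
and the evaluation re-run (`drop_and_retrain`).

**Leakage guard.** Every scoring path calls an assertion that training rows
are session 1 only and test rows session 2 only; violating inputs raise.

**Seeding.** A single experiment seed is fanned out per stage through a CRC32
hash of the stage name (`stage_seed`), keeping all derived seeds below 2^31.
Identical configuration + data + seed reproduce identical loss histories,
features, and scores.

## Synthetic data

The generator reproduces the study geometry — 7 subjects, 2 sessions 10 days
apart, 24 channels at 1 kHz, 3 s trials, 35 resting + 10 auditory + 10
cognitive trials per subject and session — with a signal model of pink (1/f)
noise, per-band sinusoids at subject-specific peak frequencies with random
phase per trial, a Gaussian-windowed evoked burst at 0.5 s for auditory and
cognitive stimuli, and 60 Hz line interference with harmonics. Subject
identity lives in the band-power topographies and peak frequencies; the
`separation` knob scales how far subjects are spread around the population
mean (the real magnitude of inter-subject EEG differences is unknown, so this
is a free parameter, not an estimate). Session 2 perturbs amplitudes and
frequencies by the profile's `session_drift` fraction (default 5%),
supplying a genuine cross-session domain shift.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction from a realistic forward model, non-stationarity within a trial,
or electrode impedance drift. Consequently, passing tests demonstrate that
the pipeline's machinery is correct and that it recovers identity when a
spectral signature exists and degrades gracefully as it disappears — they do
not certify identification rates on real EEG.

## Problem sizes

The test suite and acceptance script run scaled-down experiments chosen to
exercise every stage at desk scale: 2 subjects, 4–6 trials per session and
stimulus, one band (Alpha), a 1-layer 16-unit autoencoder trained 2–8 epochs.
The high-separation recovery run uses `separation=1.5`, the chance-level
control `separation=0` averaged over 20 seeds. Full-study geometry (7
subjects, 48 configurations) is exercised for enumeration and counting, and
is available end to end through `eegdaae run-all` for users with time to
spend.

## Known limitations

* The uniform-target objective's loss floor (above) means reconstruction
  loss alone is a poor progress signal for that scheme at small capacity.
* The numpy autoencoder is CPU-bound and intended for desk-scale experiments;
  it favors correctness and determinism over throughput.
* AUC on 9-cube units treats cubes from one trial as independent test items;
  the optional majority vote addresses this but is off by default.
* With only two sessions, "longitudinal" means one temporal gap; no
  multi-month stability claim is possible.
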