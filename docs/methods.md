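# Methods

This note documents the models, conventions and design choices behind
`speechrsa`, in the order data flows through the pipeline.

## Noise-band vocoder

A waveform is split by a contiguous band-pass filterbank, each band's
amplitude envelope is extracted by half-wave rectification followed by a
zero-phase low-pass at `env_smooth_hz` (default 400 Hz, which leaves
intelligibility untouched), optionally smoothed again at
`temp_cutoff_hz` (2/4/8 Hz — the temporal degradation axis), and imposed
on band-limited Gaussian white noise carriers filtered with the *same*
filterbank. Band signals are summed and the output is rescaled to the
input RMS (relative error < 1e-6).

Choices the vocoding literature leaves open, fixed here:

- **Band spacing** — edges equidistant along the Greenwood
  position–frequency map, f(x) = 165.4·(10^(2.1·x) − 0.88) Hz for
  relative cochlear position x ∈ [0, 1], between 200 and 7000 Hz. This is
  the standard choice for CI-simulation vocoders because it matches the
  tonotopic sampling of an electrode array.
- **Filters** — 4th-order Butterworth, applied forward-backward
  (`sosfiltfilt`), hence zero phase. Zero-phase filtering matters because
  the 2–8 Hz temporal-degradation axis manipulates envelope *timing*;
  group-delay differences between bands would confound it.
- **Carriers** — seeded per `VocoderSpec`, so a stimulus is a pure
  function of (waveform, spec).

Known deviation from linear-filter intuition: deep in the stopband the
measured envelope modulation is dominated by rectification distortion
products rather than the direct low-passed component, so quantitative
gain predictions are only asserted at moderate attenuation (8 vs 4 Hz
cutoffs at a 5 Hz modulation rate).

## Synthetic study generator

`SynthConfig` defaults describe the emulated study: 2 groups × 10
subjects, 128 channels at 500 Hz, epochs −1…1.5 s around word onset,
4 ordered comprehension conditions × 48 trials, and condition-specific
signal confined to 600–1200 ms post-onset. Every recording is a pure
function of the master seed via a `SeedSequence` hierarchy keyed by
(group, subject, session, ear), so any single recording can be
regenerated without materializing the study.

**Signal model.** Each condition k has a static zero-mean, unit-norm
channel topography; within a trial the pattern is topography ×
`effect_scale` × a Hann bump spanning the signal window. Static
topographies are the minimal structure that time-resolved decoding and
RSA can detect; they do not model travelling or rotating patterns.

**Cross-group similarity.** Implanted-group topographies are
`rho·T_control + sqrt(1−rho²)·T_idio` with `T_idio` orthogonalized
against `T_control`, so the pattern correlation equals `rho` *exactly*
(dot products of zero-mean unit vectors are Pearson correlations). Two
deliberate design choices:

- The idiosyncratic component `T_idio` is drawn once per ear/condition
  and shared across sessions. The implanted group's "own" representation
  is treated as a stable trait; sessions differ only through `rho`.
  Redrawing it each session would make longitudinal change reflect fresh
  random RDM geometry (only 6 informative entries) instead of the
  similarity parameter, and the session ordering would be statistically
  unrecoverable at any practical simulation size.
- Default session values are ρ = 0, 0.45, 0.7, 0.9. RDM entries are
  (monotone functions of) squared pattern distances, so RDM-level
  similarity scales roughly with ρ²; these defaults are equidistant on
  the ρ² scale and model a steady normalization of representational
  geometry.

**Noise.** Per trial and channel, 1/f^α-shaped Gaussian noise (α = 1,
+1 Hz floor to tame DC), mixed across channels by a fixed random
Gaussian-smoothed kernel (realistic spatial covariance without a head
model), plus independent white sensor noise (SD 1 µV). There are no
ocular or cardiac sources: the generic component-removal mechanics are
exercised by the implant artefact instead.

**Implant artefact.** A rank-1 component: fixed random topography ×
sharp Gaussian-derivative transients at stimulus onset and offset
(width 4 ms), added identically to every trial of implanted-ear
recordings when `artefact_amplitude > 0`.

**Ratings.** Ordinal 1–4 comprehension ratings from a proportional-odds
model with equidistant thresholds (±1.5) and latent mean
1.2·(log₂ bands − 3) + 0.6·(log₂ cutoff − 2): comprehension rises with
spectral and temporal fidelity, centred on the middle cell.

What passing tests on this generator do *not* show about real data:
no realistic ERP morphology, volume conduction, inter-subject
variability in channel geometry, non-stationary artefacts, or behavioural
reaction times. The generator validates the *machinery* — estimator
identities, calibration of error rates, parameter recovery — not
clinical effect sizes.

## Preprocessing

- **Band-pass / notch** — zero-phase 4th-order Butterworth band-pass
  plus an IIR notch (Q = 30) at the line frequency. Filter family is a
  package choice; the contracts tested are DC removal, ≥ 20 dB line
  suppression, and < 5% in-band amplitude error.
- **z-value trial rejection** — per channel, every sample is z-scored
  against that channel's mean/SD pooled over all trials; z-values are
  summed over channels, normalized by √C, and a trial's score is the max
  over its samples (the Fieldtrip convention). Trials with score >
  threshold are dropped; zero-variance channels contribute 0 with a
  warning. Thresholds 100 (pre-ICA) and 50 (post-ICA) are the
  conventional two-pass values.
- **SOBI** — data are whitened (PCA, reduced to numerical rank if
  needed), symmetrized lagged covariances are averaged over trials at
  lags 1–50 samples (2–100 ms at 500 Hz, spanning EEG autocorrelation
  structure), and jointly diagonalized by iterated Jacobi rotations with
  the closed-form Cardoso–Souloumiac angle; sweeps stop when every
  rotation angle < 1e-10 or after 100 sweeps. With a single lag this
  reduces exactly to the eigendecomposition of the whitened lagged
  covariance (tested). Unmixing rows are unit-norm; the mixing matrix is
  the pseudo-inverse; components are ordered by data variance.
- **Spike-component detection** — a component is flagged when the peak
  of its trial-averaged absolute activation inside the onset (±20 ms) or
  offset (±20 ms) window strictly exceeds 5× its RMS outside both
  windows. Averaging over trials first exploits the phase-locked nature
  of implant transients; the strict inequality makes the boundary case
  well-defined.
- **Removal** — data minus the flagged components' back-projection;
  an empty flag set is the exact identity.

## Decoding

Feature vectors are the raw channel values at a single time point — no
baseline correction or scaling (applying any monotone channel-wise
scaling is untested territory; the SVM is not scale-invariant).
4 pseudo-trials per condition (random near-equal binning; the
count-weighted pseudo-trial mean equals the raw mean exactly), 4 folds
(hold out the i-th pseudo-trial of each class), linear SVM with C = 1
and no further hyperparameters, ties counted as incorrect. The analysis
grid is −500…1500 ms at Δt = 20 ms (101 points); accuracies are averaged
over `n_iter` binning iterations (1000 in the emulated design; tests and
the demo run 2–100 with correspondingly widened tolerances, chosen purely
as simulation sizes).

The SVM itself is a compact SMO (sequential minimal optimization) dual
solver, JIT-compiled with numba, written for this workload: ~10⁵–10⁶
six-sample fits per recording, ~14 µs each. It is verified in the test
suite against scikit-learn's libsvm-backed `SVC` on hundreds of random
tiny problems (decision values agree to < 5e-3) and against a hand-solved
1-D hard-margin separator.

## RSA

Spearman's ρ between two RDMs is the Pearson correlation of
average-tie ranks of their 6 below-diagonal entries; zero-variance
vectors yield a missing value with a warning (a deliberate convention:
saturated, all-equal RDMs carry no ordinal information, so analyses must
be parameterized below decoding saturation). The time-generalization
matrix is computed via rank transform + normalized matrix products
(float guard: values clipped to [−1, 1]) and matches the scalar
definition cell-by-cell (tested). Fisher-z is artanh with |r| clamped at
1 − 1e-7; no small-sample variance correction. The window statistic is
the mean over all cells whose *both* coordinates lie in the closed
600–1200 ms window — 31 × 31 = 961 cells at Δt = 20 ms.

## Permutation statistics

- Cluster statistic: **cluster size** (count of supra-threshold
  points/cells), not mass. Cluster-forming threshold: the parametric
  one-sided t critical value at `cluster_alpha` with n−1 df.
- Sign-flip unit: the whole subject curve/matrix. Exhaustive enumeration
  (all 2ⁿ flips) is auto-selected when 2ⁿ ≤ 4096, otherwise seeded
  random flips with the observed assignment counted into the null, so
  p ≥ 1/(n_perm+1) always.
- 2D connectivity: 4-neighbour (corner-touching blocks stay separate) —
  the most conservative standard choice.
- A noteworthy property of constant effects: for n = 10 subjects, a
  single sign flip of an arbitrarily strong constant effect still yields
  t = 4.0 at every point (the flip inflates the sample SD in proportion
  to the mean), so at cluster_alpha = 0.05 many flips tie the maximum
  cluster size and the cluster p is 56/1024, not 1/1024; only a
  threshold above t = 4 isolates the identity assignment. Both regimes
  are pinned against exhaustive enumeration in the tests.
- RM-ANOVA: classical between-session MS over subject × session residual
  MS; null by permuting session labels independently within subjects.
  Paired t: sign flips of differences, two-sided. Cohen's d: mean
  difference over SD of differences (n−1). Bonferroni: α/m.

## Pipeline and containers

Epochs live in HDF5 (`/data`, `/time`, `/channels`, `/trials`, root
attributes), with SHA-256 content hashes recorded in a JSON manifest;
re-running a config reproduces byte-identical CSV/JSON outputs. Configs
are YAML validated against an explicit schema — unknown keys are errors.
The reference side of the cross-group comparison averages the implanted
subjects' RDM series per session and ear; per-subject matrices are
computed first and Fisher-z transformed before any averaging or testing.

## Simulation sizes

Chance calibration uses one 128-channel no-signal subject with 24 trials
per condition and 100 binning iterations; FWE calibration uses 200 null
datasets of 10 × 101 Gaussian curves with 512 sampled flips; the session-
recovery experiment uses 20 replicate studies of 6 subjects per group,
24 channels, 24 trials per condition, effect scale 1.3 and 32 iterations,
decoding restricted to the 600–1200 ms window that the statistic reads.
These sizes were chosen as the smallest at which the respective checks
are statistically decisive (adjacent-session gaps ≳ 2–3 SEs in the
recovery design), with decoding kept below saturation so RDM ranks stay
informative.

## Limitations

- Static topographies mean time-generalization matrices are blocky by
  construction; temporal dynamics of real representations (diagonal
  ridges, transient codes) are not modelled.
- The generator's ρ controls *pattern* correlation; the induced RDM
  correlation is a nonlinear (≈ quadratic) function of it, so recovered
  window-z values order sessions but do not estimate ρ itself.
- SOBI assumes stationary source autocorrelations within the epoch;
  strongly non-stationary artefacts would call for time-windowed
  extensions.
- The ordinal ratings model ignores subject and item random effects, so
  behavioural mixed-model analyses are out of scope.
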