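# Methods

This note documents the models, numerical choices and limitations behind
`livesort`. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and simulator

A recording is modeled as a linear superposition of unit waveforms plus
noise, sampled at 30 kHz and quantized to int16:

    x[t, c] = Σ_k Σ_{s in spikes(k)} a_s · T_k[t - s + h, c] + ε[t, c]

where `T_k` is an M x C template (M = 61 samples, odd, trough at the
center sample h = (M-1)/2), `a_s` is a per-spike amplitude jitter and ε is
i.i.d. Gaussian channel noise (an optional spatially correlated mode
exercises whitening). The simulator's defaults define the package's study
conditions:

- probe: dense two-column layout, 20 µm pitch;
- temporal kernel: difference-of-Gaussians biphasic waveform, trough-first;
  the trough-to-peak width is controllable so both fast-spiking (< 200 µs)
  and regular-spiking classes can be produced;
- spatial spread: exponential amplitude decay with distance from the peak
  channel, length constant 25 µm — a compact single-unit footprint typical
  of dense probes;
- peak amplitudes 60–150 µV, baseline rates 5–15 Hz, absolute refractory
  2 ms (enforced by deletion), amplitude jitter ±10%;
- noise: 10 µV SD per channel by default — a documented choice rather
  than a measurement; at 60–150 µV peak amplitudes it corresponds to
  peak SNR ≈ 6–15, a mid-range value for dense-probe units;
- stimuli: 0.25 s drifting-grating presentations, three per trial with
  0.15 s gaps, twelve directions in 30° steps; during a presentation the
  rate is `baseline · (1 + depth · exp(κ(cos(θ−pref)−1)))` (von Mises
  modulation, defaults depth 2, κ 2);
- state sessions: a two-state telegraph gain (dwell ~ Exp(0.4 s), gains
  1x / 2.5x) multiplying the baseline rate of every fast-spiking unit, for
  the closed-loop benchmark;
- int16 gain: the largest template uses ~25% of the int16 range; clipping
  raises an error rather than saturating silently.

Spike generation is inhomogeneous-Poisson thinning followed by
refractory deletion; all draws derive from explicit seeds. Spikes too
close to the recording edge for a full template are dropped and counted.

What the simulator does *not* emulate: electrode drift, bursting with
amplitude adaptation, spatially overlapping units on the same channel,
non-Gaussian or non-stationary noise, and line artifacts. Tests passing
on this generator therefore validate the pipeline's algebra and its
behavior under collision, noise and state fluctuation — not robustness to
drift or waveform non-stationarity on real tissue.

## Preprocessing

Each batch passes, in order: (1) per-channel mean subtraction, (2)
per-sample common median referencing across channels, (3) FFT-domain
high-pass at 300 Hz, (4) left-multiplication by the whitening matrix, (5)
left-multiplication by the drift matrix (identity by default; live drift
estimation is out of scope). The high-pass uses a zero-phase raised-cosine
transition band of 300 ± 75 Hz on a reflect-padded batch — the transition
shape and padding are this package's choices and are pinned by tests.
Whitening is symmetric (ZCA) with eigenvalue regularization
`eps = 1e-6 x` mean diagonal by default, optionally restricted to channel
neighborhoods.

**Common-mode rejection and linearity.** The median reference is
nonlinear: when several spikes superpose, the median shifts by more than
the sum of the shifts each spike causes alone, leaving a residual "ghost"
that is equal on every channel and that no sum of templates can explain.
The matcher therefore operates in the common-mode-rejected subspace: the
per-sample cross-channel mean is projected out of the batch, and
templates (which are learned from the same projected signal) live in that
subspace. Within it, superposition is exactly linear, which is what makes
zero-noise recovery exact and the incremental convolution-trace updates
consistent with brute-force recomputation to machine precision.

During learning, whitening falls back to identity when the measured noise
floor is within 5x the quantization step — a covariance estimated from
quantization residue would wildly amplify silent channels.

## Template learning

The learner is deliberately simple and is *not* a reimplementation of any
production offline sorter; only the resulting bank interface matters to
the online engine. Pipeline: robust per-channel detection (5x MAD, with a
floor at 2% of the 99.99th absolute-amplitude percentile so filter
ringing around large spikes is not detected); trough alignment and
cross-channel consolidation; temporal PCA (6 components, uncentered SVD —
rank-deficient snippet sets are completed orthonormally rather than
rejected); snippets masked to channels within 100 µm of their peak
channel for clustering only; k-means within peak-channel groups with a
silhouette criterion (split only above 0.6) and cross-channel merging of
near-duplicate templates (cosine > 0.95).

Clusters are dropped when undersized (< 30 events), weak (< 1% of the
maximum cluster energy) or composed of subtraction dust — identified by
adjacency: a cluster whose members almost all (> 75%) sit within one
template length of a larger event is leftover, not a unit.

Templates are element-wise **medians** of the snippets: the median is
exactly the clean waveform on noiseless data and robust to the minority
of collision-contaminated snippets, where the mean inherits a measurable
bias. One matching-pursuit refinement pass then re-extracts
collision-cleaned snippets (final residual plus each event's own template
contribution, with weak events' contributions restored so that the new
templates do not inherit the previous generation's shape bias) and
re-clusters; only confident events (amplitude ≥ 0.6) seed templates.

The online detection threshold is the 0.999 quantile of the normalized
detection statistic on spike-free stretches of the training signal (a
noise-calibrated stand-in for a learned threshold), floored at 5% of the
smallest template energy so that residual dust can never trigger on
noiseless data. Events additionally require amplitude ≥ 0.2 in
template-normalized units.

## The streaming engine

Windows of `batch_len` samples overlap by exactly 2M; window k starts at
`k (batch_len - 2M)`; emit ranges `[start+M, end-M)` (extended to the
recording edges at the ends) partition the samples, so every event is
emitted exactly once. Detections are suppressed only where the template
lacks full support ((M-1)/2 samples per window end): any spike owned by a
neighboring window's emit range is therefore still detectable — and
subtractable — in the current window, which keeps emit ranges clean and
makes streaming output equal single-batch output event for event.
Preprocessing is applied with 256 samples of context beyond each window
so filter edge transients do not depend on the batching.

The matching-pursuit loop (≤ 50 passes) scores candidates by the squared
ReLU of the l2-normalized template correlation (so the threshold is
template-scale-free), takes per-template temporal local maxima via
max-pooling with window 2M+1, re-validates candidates strongest-first
against the updated traces, computes least-squares amplitudes, and
subtracts each accepted event from the residual and — via the
precomputed pair cross-correlations — from every correlation trace.

**Pileup polish.** Greedy pursuit mis-times and mis-scales overlapping
spikes. After the loop: (i) coordinate-descent sweeps re-place each event
at the best time within ±2 samples with its exact LS amplitude; (ii)
overlapping pairs are jointly re-placed on a ±8 sample offset grid with
exact 2x2 joint LS amplitudes (template correlations are blind to the
common-mode ghost, so this scoring is unaffected by the median
nonlinearity); (iii) backward elimination, weakest first and iterated to
a fixed point, deletes any event whose removal (after re-fitting its
neighbors) costs less common-mode-free residual energy than the detection
threshold — i.e. events that explain less than a detectable spike. All
three phases update the residual and the correlation traces incrementally
and exactly.

Localization is the mass-weighted mean of channel positions, mass =
PCA-feature energy per channel within 100 µm of the template peak
(falling back to the peak-channel position on zero mass); cluster
assignment is nearest centroid in flattened feature space, ties to the
lowest id. Duplicates within a template closer than 15 samples (0.5 ms)
keep the larger amplitude. The adaptive skip policy drops pending windows
oldest-first once the simulated processing clock falls more than one
window behind acquisition; skipped spans are reported, never silently
lost.

## Validation suite

- Train matching: greedy one-to-one nearest pairing within ±15 samples
  (0.5 ms; the tolerance is this package's choice). FP is measured
  against the test train, FM against the reference; score = 1 − FP − FM,
  matched at ≥ 0.8. Units across two sorts are paired greedily by
  descending score.
- PSTH: trial-averaged sliding rate, 100 ms bins stepped 10 ms over
  −500..+1500 ms; Pearson correlation; zero-variance PSTHs yield a
  missing value, never 0 or 1.
- Tuning: mean rate ± SEM per direction in a 50–250 ms response window;
  von Mises fit initialized at the argmax direction, κ ≥ 0, r² on the 12
  points; r² ≤ 0.6, fit failure, or zero modulation flag not-well-fit.
- Decoding: per-bin multinomial logistic regression (lbfgs, C = 1,
  max_iter = 1000), 5-fold stratified shuffled CV, per-fold class
  balancing by downsampling to the smallest class, per-feature
  standardization fit on the training fold only; fold-mean accuracy and
  across-fold SEM. Chance for 12 classes is 1/12.
- Dropping curves: unit subsets in increments of 10 (5 seeded draws
  each), per-unit z-scoring across trials, 20-fold stratified CV with
  balanced training folds.
- Asymptote fit: weighted nonlinear least squares of the two-term
  saturating exponential with chance c = 1/12 fixed, initial values
  (max accuracy, 0.5, 10, 200), bounds A ∈ [c, 1], w ∈ [0, 1],
  τ ∈ [1e-6, 1e6], SEMs as inverse weights (unweighted when any SEM is
  zero); on failure the asymptote falls back to the mean of the last 3
  points. Paired comparisons use the two-sided Wilcoxon signed-rank test
  (all-zero differences report p = 1, flagged).

One caveat discovered while testing: duplicating every trial does *not*
leave cross-validated accuracy unchanged — duplicates leak between
training and validation folds and inflate accuracy. The suite instead
checks the true resampling invariance (permuting trial order).

## Closed-loop paradigm

FS/RS classification uses the trough-to-peak time of each template's
maximum-amplitude channel, strictly below 200 µs = FS; monophasic
templates are RS with a warning. Baseline statistics are computed on a
dedicated epoch before the first trial in 100 ms windows; the "~50 ms"
evaluation cadence is implemented as exact, non-overlapping 50 ms
windows; a trial triggers at the end of the first window whose
FS-population mean rate exceeds mean + 2 SD. Control trials bypass the
rule with a conventional onset drawn uniformly within the fixation
period. The evoked-response window is 50–250 ms post-onset (the stimulus
lasts 0.25 s); the pre-stimulus window is −100..0 ms. Normalized
responses (evoked / pre-stimulus) exclude units with zero pre-stimulus
rate from the normalized summary only.

The trigger's selection effect orders the pre-stimulus rate
*distributions* (triggered above control), so the triggered exceedance
curve should lie above the control curve at every threshold. With tens of
control trials, however, a single control trial landing in the extreme
tail crosses the empirical curves by less than one trial's worth of
probability mass; the benchmark therefore scores dominance at one-trial
resolution (tolerance 1/n_control).

The closed-loop simulation is two-phase: the state-fluctuating recording
is rendered spontaneous-only, the trigger rule runs on its live-sorted
spikes, and evoked responses can be appended afterwards at the decided
onsets (`simulate.add_evoked_spikes`). Pre-stimulus quantities — what the
trigger benchmark measures — are independent of evoked rendering because
stimulus activity strictly follows each onset.

## Benchmark scales

The bundled scenarios use desk-scale problem sizes chosen to exercise
every code path with tight statistics: 60 s / 16-channel / 10-unit
sessions for recovery; 480 presentations x 50 untuned units for
chance-level decoding; 12 s sessions plus a ±2M boundary sweep for
streaming equivalence; 3-template / 3000-sample instances for the
subtraction oracle; 200-trial state sessions on 8 channels for the
closed-loop paradigm.

## Known limitations

- The learner assumes units with distinct peak channels; two units whose
  waveforms differ only sub-sample on the same channel will merge.
- At the default SNR a small number of low-amplitude spurious events can
  collect in the weakest unit's cluster (visible as FP on that unit while
  all median scores stay at 1.0); they originate from sub-sample timing
  misfit of real spikes under noise.
- No drift estimation or template updating during a session; the drift
  matrix is identity unless supplied.
- The real-time budget is simulated (a processing-speed ratio), not
  measured wall-clock scheduling.
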