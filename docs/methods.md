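# Methods

This note documents the models implemented in `erflnp`, the conventions
and parameter choices they rest on, and what the synthetic-data tests do
and do not establish about recorded data.

## Stimulus model

The electrical stimulus is smooth Gaussian noise delivered as a
capacitive voltage command. Generation follows the physical chain:

1. Draw `f_s · T` standard-normal steps (defaults `f_s = 10 kHz`,
   `T = 5 s`) and accumulate them into a random walk. To bound drift, any
   step that would push the cumulative sum beyond the reflection limit
   `L_reflect = 10` (arbitrary units) has its sign inverted before being
   added; if, pathologically, the inverted step would also violate the
   limit, the sum is clamped to `±L_reflect`, which keeps the bound exact
   and testable.
2. Low-pass the walk at 100 Hz with a 5th-order Butterworth filter,
   applied as a single causal pass — the stimulus was physically delivered,
   so an acausal (filtfilt) smoothing would be wrong.
3. Rescale affinely into the stimulator's safe command range
   `0 V ≤ V ≤ 2.5 V`.

The current-proportional stimulus trace is the discrete first difference
of the command times the sampling rate (electrode capacitance is treated
as a unit constant; absolute current scale is a hardware property). The
trace is standardized to zero mean and unit SD, with the affine constants
stored on the object, so filter amplitudes are comparable across seeds and
the voltage command remains exactly recoverable (cumulative-sum identity,
verified to < 1e−9 V).

Reflection is applied to the walk *before* filtering, matching the
generation order of the physical stimulus; reflecting after filtering
would slightly alter the low-frequency power. The resulting power
spectral density is flat up to ~100 Hz and falls steeply above it
(median PSD in 110–500 Hz is < 10⁻⁴ of the 10–90 Hz level); the derivative
step shapes the tail to roughly `f^(−8)`.

## Spike and filter conventions

- Spikes are binned at 1 ms; bin `t` covers `[t, t+1) ms` and a spike on
  the edge belongs to the later bin. Sample indexing is 0-based.
- A temporal filter has 300 taps spanning −20 ms … +9.9 ms relative to
  the spike in 0.1 ms steps. The snippet paired with spike sample `a` is
  `stimulus[a−200 : a+100]`; any bin whose window exits the trace is
  excluded everywhere (simulation, STA, GLM, prediction), never padded.
- Acausal taps (the +10 ms "future") are retained in both estimators;
  with a whitened but band-limited stimulus some estimated filters show
  small acausal components from residual correlations.

## Synthetic ground truth

`make_template_filter` builds parametric stand-ins for the three filter
archetypes of sighted retina: monophasic negative (Gaussian trough,
default peak −3.7 ms before the spike), monophasic positive (peak
−4.7 ms), and biphasic (positive lobe at −5.2 ms followed by a negative
lobe at +0.2 ms). Lobe widths default to a 2 ms Gaussian sigma — the
scale of the lobes visible in recorded filters — which also keeps most
template energy inside the ~560 Hz band the stimulus can actually probe;
a much narrower template would be partly unidentifiable by construction.

`make_archetype_neuron` wraps a template in a saturating sigmoid
nonlinearity (`y_max = 0.3` per 1 ms bin, gain 2 per projection-SD) and
places the threshold `x0` by bisection so the mean Bernoulli probability
matches a target firing rate (default 40 spikes/s). Spike generation is
one Bernoulli draw per 1 ms bin per repetition with
`μ_t = N(kᵀ s_t)`.

Raw-trace synthesis reproduces the artefact-dominated regime: trace =
50 × stimulus + a 1 ms biphasic spike waveform at each spike time +
Gaussian noise (SD 0.05), putting the artefact RMS ≳ 34 dB above the
spike peak. Light-flash responses are inhomogeneous Poisson trains over
1 s ON/OFF cycles whose 10-bin rate profile is chosen in closed form so
the expected Transiency Index equals the requested value: first bin
weight 1, remaining nine `c = (10(1−TI) − 1)/9`.

What the generator does *not* emulate: spatial structure (electrode
geometry, current spread, eRF extent), bursting or refractory dynamics
beyond the 1 ms bin, spike-sorting errors, electrode drift, and
non-stationary artefacts. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to every property of recorded data.

## Artefact removal

Raw traces are band-pass filtered (1000–9500 Hz, 2nd-order Bessel,
causal, digital design matched to the analog prototype). At the 10 kHz
synthetic sampling rate the upper edge reaches Nyquist, so the equivalent
passband is realized as a high-pass at 1000 Hz. The artefact factor
`f = rᵀS / SᵀS` is then estimated with trace and stimulus in the *same*
passband — the projection is only meaningful when both signals live in the
same band — and `f·S` is subtracted. Estimating `f` on unfiltered signals
first is available via `filter_first=False`. The residual is orthogonal
to the stimulus by construction; on synthetic raws the gain is recovered
to well under 1% and stimulus-band power drops by ≥ 20 dB.

Spike detection (a deliberately simple stand-in for a spike sorter)
thresholds the absolute signal at `k·SD` with the noise SD estimated as
`MAD/0.6745` (insensitive to the spikes themselves), a 1 ms peak-search
window and a refractory gap between detections.

## Response metrics

- **Reliability Index**: responses are binned at 2 ms; for each
  leave-one-out split the pooled histogram of the remaining repetitions
  (`H`, summed — the Pearson correlation is scale-invariant, so summing
  vs averaging is immaterial) is correlated with the held-out histogram
  `h`; RI is the mean over all splits, generalized to any repetition
  count. Any zero-variance histogram makes the result NaN with a
  degeneracy flag. The responsiveness criterion is strict: RI > 0.15.
- **Bias Index**: spike counts in the 300 ms after light onset vs offset,
  summed over repetitions; classes OFF (BI < −0.25), ON-OFF
  (−0.25 ≤ BI ≤ 0.5, boundaries inclusive), ON (BI > 0.5).
- **Transiency Index**: the trial-summed histogram (10 × 50 ms bins over
  the 500 ms after the preferred phase) is normalized by its maximum bin —
  the only normalization under which the printed extremes 0 (uniform) and
  0.9 (single-bin) both hold — and TI = 1 − mean. ON-OFF cells average
  the ON-phase and OFF-phase TIs.

## Whitened spike-triggered averaging

The stimulus ensemble is every 300-sample snippet taken 10 samples (1 ms)
apart — 4971 snippets for the 50 000-sample stimulus. The whitening
operator is `C^(−1/2) = Σ_{i≤L} λ_i^(−1/2) e_i e_iᵀ` from the
eigendecomposition of the snippet covariance, retaining eigenvalues
`≥ 10⁻⁷ · λ_max`. The retention floor is deliberately deep: the
stimulus's `f^(−8)` spectral tail means modes out to ~560 Hz carry real
(if small) power, and only when they are rescaled does whitening flatten
the spectrum (110–500 Hz within a factor 3 of the passband) and collapse
the autocorrelation (max |acf| over 1–20 ms lags < 0.2, vs > 0.9 at 1 ms
before whitening). A shallower floor (e.g. 10⁻⁴) truncates at ~316 Hz and
leaves both contracts badly violated. STA sampling noise is isotropic
across retained modes, so the deep floor costs little variance. The rule
is recorded on the operator and configurable.

The whitened continuous stimulus is rebuilt by overlap-adding the
whitened snippets with strictly positive Hann tapers, normalized so the
weights sum to one at every sample (an identity operator reproduces the
input to machine precision). The STA is the mean whitened snippet around
every usable spike.

The nonlinearity estimate projects the full ensemble (at 1 ms stride) and
the spike-triggered ensemble onto the filter, histograms both over 25
equal-width bins spanning the central 99% of full-ensemble projections
(bins with fewer than 5 ensemble counts masked), and takes the ratio —
directly a spike probability per 1 ms bin once divided by the repetition
count. Sigmoid and exponential forms are fit by least squares from five
deterministic data-driven starts; when the form is unspecified the lower
residual wins.

## Elastic-net GLM

Design rows are raw (unwhitened) stimulus snippets at 1 ms stride —
maximum likelihood corrects for stimulus correlations intrinsically —
with binary labels (multiple spikes in a bin clip to 1, per the Bernoulli
model). The loss is the average negative log-likelihood plus
`λ[(1−α)·½‖β‖² + α‖β‖₁]`, intercept unpenalized, features standardized
internally and coefficients back-transformed. The likelihood is
normalized by the number of binned observations: this is the conventional
per-observation scale on which the λ grid `[10⁻⁴, 10⁻²]` is a sensible
operating range (normalizing by spike count instead would weaken every
grid value ~25-fold, leaving the near-null high-frequency stimulus
directions unregularized and the filter estimate dominated by their
noise).

Optimization is delegated to scikit-learn's `LogisticRegression` via the
exact correspondence `C = 1/(Nλ)` (lbfgs for pure L2, SAGA otherwise);
the package's own loss/gradient implementation is the contract the solver
is verified against (finite-difference gradient check, stationarity of
the returned solution). Hyperparameters come from a cross-validated grid
search with contiguous, unshuffled time folds — respecting temporal
correlation, matching the outer 4 s/1 s scheme — scored by held-out mean
log-likelihood; singleton grids skip the search.

For the parameter-recovery benchmarks the hyperparameters are fixed at
the grid's strongest point (λ = 10⁻², α = 0): cross-validated selection
optimizes *prediction* and may choose a weaker λ than filter *denoising*
wants, and the benchmark measures the latter. The search machinery is
exercised separately.

## Prediction and evaluation

A fitted model predicts `rate_t = N(vᵀ s_t)` per 1 ms bin — STA models on
the whitened stimulus they were fit on, MLE models on the raw stimulus;
boundary bins are NaN and excluded pairwise. Performance `P` is the
Pearson correlation with the true rate (1 ms spike counts summed across
repetitions of the test block; single-repetition scoring is a switch).
Cross-validation uses the five contiguous 1 s test blocks; models are fit
on spikes from the four training seconds only. The whitening operator is
computed from the full stimulus — a stimulus-only statistic known before
any recording — so no response information leaks; a dedicated test
corrupts test-period spikes and verifies the predictions do not change.
The linear-stage variant scores `vᵀ s_t` without the nonlinearity.

## Filter population analysis

PCA is mean-centered, keeping the fewest components reaching 90%
cumulative explained variance; each component is oriented so its
largest-magnitude loading is positive (deterministic projections).
Filters enter unnormalized (per-filter L2 normalization is an off-by-
default option). Clustering is average-linkage on euclidean distances
between PC projections, optionally restricted to selected PCs; a per-PC
between/within-session variance ratio is provided to flag components
dominated by recording-session differences as exclusion candidates.

The automatic cluster count automates reading the dendrogram by eye:
among the last 10 merges, every merge whose height jumps above its
predecessor by an outlying factor (≥ 8× the median recent jump excess,
and at least 20%) marks a cluster boundary, and the tree is cut just
below the deepest such merge. A single dominant split whose branch
itself splits prominently therefore yields three clusters — the
structure archetype populations actually have — while a clean two-blob
population yields two and duplicated points one. The count is always
overridable.

Peak latencies are the tap times of the global minimum and maximum
(raw argmin/argmax at full 0.1 ms resolution, no smoothing); a filter is
biphasic when the secondary extremum reaches 30% of the primary's
magnitude, else monophasic with the primary's sign.

## Problem sizes and numerical choices

- Recovery benchmarks: 5 s stimulus × 5 repetitions at ~40 Hz (≈1000
  spikes), 20 seeds per archetype; the long-recording condition is 25 s ×
  1 repetition at 3 seeds. Cosine similarity with the planted filter
  exceeds 0.8 (5 s) and 0.9 (25 s) for both estimators.
- The prediction–reliability relationship is measured across 50 simulated
  cells spanning nonlinearity gains 0.3–3.
- Tolerances: STA equals its scalar double-loop oracle to < 1e−12;
  GLM gradients match central finite differences to < 1e−5 relative;
  partition-of-unity and projection identities hold to machine precision.
- All randomness flows through integer seeds; one master seed expands to
  per-component children via `numpy.random.SeedSequence`. The full demo
  pipeline is bit-reproducible (SHA-256-identical outputs across reruns;
  HDF5 datasets are written without modification timestamps).

## Known limitations

- Temporal-only filters: no spatial or spatiotemporal receptive-field
  estimation, electrode-geometry or current-spread modelling.
- The spike detector is a threshold stand-in, not a spike sorter; it is
  adequate for the synthetic single-cell traces it is applied to.
- The Bernoulli likelihood is the only spiking model; no Poisson-process
  or history-dependent (refractory, bursting) variants.
- The histogram-ratio nonlinearity is noisy in sparsely populated
  projection bins; the parametric fit, not the raw ratio, should be used
  for prediction.
- Statistical comparisons between groups of cells (e.g. paired signed-rank
  tests on prediction performance) are left to standard libraries.
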