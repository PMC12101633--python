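# Methods

`trfseg` studies a single question: when a continuous stimulus-response
recording is re-sliced into non-overlapping segments of duration *d* before a
temporal response function (TRF) is fitted, how does prediction accuracy
depend on *d*?  The package contains the estimator, a generative simulation
with a known ground truth, a synthetic multichannel EEG-study generator, and
the sweep/post-hoc analyses that put them together.

## The TRF model and its estimator

The response is modeled as a linear time-invariant (LTI) mapping from
stimulus features to each recording channel:

    r(t) = sum_n sum_tau w(tau, n) s(t - tau, n) + eps(t)

with lags tau on a window `[tmin, tmax]` (default 0–400 ms, covering the
simulated kernel's support and typical auditory cortical latencies; the
window is a free parameter of every entry point).  Estimation is ridge
(Tikhonov) regression on the lagged design matrix S:

    w = (S^T S + lambda M)^{-1} S^T r

where M is the identity over stimulus-lag rows and zero on the intercept row,
so constant offsets are absorbed without shrinkage.  Each segment is treated
as an isolated record: its lagged design is zero-padded at the boundaries,
and its covariance matrices S^T S and S^T r are divided by its own sample
count before being averaged across segments.  Per-sample normalization keeps
lambda's meaning independent of segment duration and handles unequal segment
lengths; for equal-length segments it coincides with plain averaging.
Exactly singular systems (possible at lambda = 0 on very short segments)
fall back to the pseudo-inverse with a warning rather than aborting a sweep.

The regularization strength is selected from nine log-spaced candidates
spanning 1e-5–1e3 by k-fold cross-validation (default k = 5): segments are
partitioned uniformly at random once per call (caller-supplied seed, folds
shared across all lambdas), accuracy is the Pearson correlation between the
predicted and observed response averaged over channels and held-out
segments, and ties break toward the smaller lambda.  The public modeling
surface is scikit-learn shaped (`TRFRidge`, `TRFRidgeCV`), so models compose
with sklearn pipelines; the underlying steps remain available as functions.

## Segment normalization

Before fitting, every segment is z-scored — each stimulus band and each
response channel has its within-segment mean removed and is divided by its
within-segment standard deviation (`normalize_segments`, on by default in
both sweeps).  This step carries most of segmentation's effect and is worth
spelling out:

* Removing per-segment means high-passes the data at the segmentation scale
  1/d, deleting noise drift slower than the segment length.
* Dividing by the per-segment standard deviation down-weights high-noise
  epochs in the covariance average — an implicit, local inverse-variance
  weighting that pays off when the noise level wanders (non-stationary 1/f
  noise) and only injects estimation noise when it does not (stationary
  Gaussian noise).
* A constant stimulus band inside a segment is left centered but unscaled;
  a constant response channel raises an error, since its correlation score
  would be undefined anyway.

Without this step, averaging per-sample-normalized covariances of
equal-length segments is — apart from boundary zero-padding terms —
independent of the segment duration, and the duration sweeps become
flat: the segmentation phenomena this package exists to study are
properties of the *normalized*-segment protocol.

## Generative simulation

The ground-truth transfer function is a Gabor wavelet, a cosine carrier
modulated by a Gaussian envelope, `w(t) = exp(-(t-mu)^2/(2 sigma^2))
cos(2 pi f t)`, with defaults mu = 0.1 s, sigma = 0.01 s, f = 4 Hz sampled
at 128 Hz (sigma is resolved with >1 sample at this rate; the rate is
configurable).  The stimulus is a train of randomly spaced square pulses:
amplitudes U(0.5, 1.5), widths U(0.02, 0.1) s, gaps U(0.2, 1.5) s, giving
roughly 1.1 events/s — a word-scale event rate at which most samples of the
convolved response are exactly zero, so the average signal power and hence
the absolute SNR are very low.  The maximum gap deliberately exceeds 1 s so
that at the shortest sweep durations some segments contain no stimulus
event at all; those segments are what expresses the short-duration accuracy
collapse.

Noise is either white Gaussian or 1/f ("pink"): the Fourier spectrum of
white noise is multiplied by f^(-beta/2) (power ∝ 1/f^beta, default
beta = 1), the diverging DC bin is zeroed, and the result is
inverse-transformed and standardized.  Pink noise concentrates power in
slow components, producing the wandering local mean and variance that make
a recording effectively non-stationary at the segment scale.  Noise is
scaled to a target SNR, defined as the total-power ratio
10 log10(P_signal/P_noise) over the full record and calibrated exactly on
every realization.  The default SNR grid is (-25, -30, -35) dB for both
noise kinds, spanning the transition from near-saturated kernel recovery to
the noise-dominated regime; the values are low in absolute terms because
the sparse response depresses the average signal power.

A sweep repetition fits the full protocol (segment → normalize →
cross-validate lambda → refit) on 1000 s of training data for each duration
in {200, 100, 50, 25, 10, 5, 2, 1} s, then evaluates on a further 1000 s of
freshly generated *noisy* test data that is segmented and normalized exactly
like the training data; accuracy is the Pearson r between predicted and
observed test response, averaged over channels and test segments.  A
separate `recovery` column records how well the fitted kernel reproduces the
true kernel's noiseless response to the test stimulus — a ground-truth
diagnostic the held-out metric cannot provide.  The default repetition count
is 50 (the sweep is a stochastic process and the defaults are desk-scale;
the full-scale 1000 repetitions are a config change).

Under Gaussian noise, accuracy falls monotonically as segments shorten:
nothing is gained (the data are already stationary) while per-segment
normalization noise, boundary zero-padding, and empty short segments all
cost.  Under 1/f noise at sufficiently low SNR the curve is non-monotone
with an interior optimum (typically 2–10 s): drift inflates within-segment
variance at long durations and depresses correlation there, while the
short-segment penalties still apply at 1 s.

## Synthetic EEG study

The cohort generator emulates a listening study: 8 participants x 20 trials
x 120 s at 64 Hz (totals divisible by every sweep duration), 16 channels,
16 stimulus bands.  Band features are rectified low-pass-filtered (8 Hz)
noise mixing a shared broadband component with band-private components, so
bands are non-negative, temporally smooth, and positively correlated, like
multiband speech envelopes; trial stimuli are shared across the cohort (a
common "story") while noise is participant-specific.  Each channel's clean
response is the channel's band-gain-weighted feature mix convolved with a
channel-specific Gabor kernel; kernels share a shape with smoothly varying
latency and gain across the array, and band tuning drifts across channels —
a crude scalp topography.  Pink noise is added per channel at a
participant-level SNR (default -10 dB, spread ±3 dB across participants so
baseline accuracy varies).  Two artifact mechanisms are off by default and
used by the robustness analyses: outlier trials whose noise is multiplied
by 10 over a random 20–50% sub-interval, and a slow sinusoidal gain drift
on the noise envelope.

The cohort sweep refits each participant at 1, 8 and 16 spectral bands
(coarser bands are adjacent-band sums of the 16-band features) for every
duration in {120, 60, 40, 30, 15, 10, 5, 2, 1} s, records the
cross-validated accuracy at the selected lambda, normalizes accuracy within
participant x model by its maximum across durations, and excludes
participants whose best accuracy falls below r = 0.01.  What passing these
analyses shows — and does not show — about real recordings: the generator
reproduces the *structure* of the phenomenon (non-stationary noise, shared
stimulus, band-limited features, trial layout), but not volume-conducted
channel correlations, physiological artifact morphology, or real speech
statistics, so effect sizes on real data will differ; the directional
claims (intermediate durations win under non-stationary noise; lambda need
not grow when many segments already average the covariance) are what
transfer.

## Audio features

For real audio, `compute_spectral_envelopes` band-passes the waveform into
log-spaced bands over 20–9000 Hz (1, 8 or 16 bands; 8th-order zero-phase
Butterworth), takes the magnitude of the analytic (Hilbert) signal per
band, and resamples to the analysis rate (negative resampling ripples are
clipped at zero).  Audio must be sampled above 18 kHz to represent the
9 kHz band edge.

## Post-hoc analyses

*Improvement regression.*  Per participant, x = the maximum accuracy over
all cells and y = accuracy(10 s) − accuracy(120 s) averaged over band
models; the analysis reports the Pearson r of (x, y) with a two-sided p
from the t-transform (the conventional test for a single correlation).

*Outlier robustness.*  With a fixed lambda, a TRF is fitted to every
segment individually; segments are ranked by mean absolute weight and the
top 5% (ceiling count) are flagged.  The pooled TRF is then fitted with and
without the flagged segments and the percent change in mean absolute weight
reported.  Identification runs on raw (un-normalized) segments, where an
amplitude artifact directly inflates the per-segment fit; z-scoring first
would mask exactly what the analysis looks for.  The pooled fits can run on
normalized segments (`normalize_pooled=True`), matching the main protocol.
The bundled benchmark (`outlier_burst_experiment`) plants a x10 noise burst
one fine-segment long inside one coarse segment of a Gaussian-noise record
and compares trimming at coarse (120 s) versus 8x finer (15 s)
segmentation.  The asymmetry is a direct consequence of per-segment
normalization: at fine segmentation the burst fills its own segment, is
flattened to unit variance by z-scoring, and barely perturbs the pooled
covariance average, whereas at coarse segmentation it rides inside a
mostly-clean segment, passes through normalization largely intact, and its
removal moves the pooled TRF more — segmentation regularizes the effect of
outliers.  The pct-change magnitudes are stochastic run to run (trimming
5% of clean data is itself a perturbation), so the benchmark reports
per-run values and the analyses compare means over 20 seeded runs.

## Numerical and design choices

* Lag windows, kernels and segment grids are specified in seconds and
  rounded to samples (`round(t * fs)`); lag counts are inclusive of both
  endpoints.
* Ridge solves use a symmetric solver; at lambda = 0 a condition-number
  check (>1e12) reroutes to the pseudo-inverse with a warning.
* Degenerate (zero-variance) channels score Pearson r = 0 inside
  cross-validation scoring, where an exception would abort a sweep; the
  public `pearson_r` raises instead, because silent zeros there would mask
  user error.
* All stochastic components are pure functions of (configuration, seed);
  sweeps derive per-repetition, per-condition child seeds from the master
  seed, so any result table is bit-reproducible.
* Sweep tables are TSV with a provenance header (package version, config
  hash, seed); containers are HDF5.
* Desk-scale defaults (50 repetitions, 8 participants, 16 channels) were
  chosen so the full test battery and the acceptance analyses complete on a
  single CPU; paper-scale values (1000 repetitions, 128 channels) are
  configuration changes, not code changes.

## Known limitations

* The simulated kernel is time-invariant; a drifting generative kernel
  (which would amplify the segmentation effect) is not modeled.
* The synthetic cohort has no volume conduction, eye/muscle artifacts, or
  channel-dependent noise spectra; its outlier and drift mechanisms are
  deliberately simple.
* Real-recording support assumes already-preprocessed input (filtered,
  downsampled, re-referenced); bad-channel detection and interpolation are
  out of scope (a variance-based screen can be applied upstream).
* Segmentation uses equal-length slices only; adaptive, statistics-driven
  segmentation is out of scope.
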