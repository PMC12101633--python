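# trfseg

Temporal response function (TRF) estimation with a systematic treatment of
**data segmentation**: how slicing a continuous neural recording into
segments of duration *d* before model fitting changes prediction accuracy,
and why the answer depends on whether the recording is stationary.

Linear encoding models such as TRFs treat the brain as a linear
time-invariant system and implicitly assume the modeled signal is
stationary.  Long continuous recordings of, say, EEG responses to narrated
speech violate that assumption: their 1/f-like spectra imply slow drifts in
mean and variance.  `trfseg` is for researchers who fit such models and
want to choose — or audit — the segmentation of their data.  It provides:

* a from-scratch ridge-deconvolution TRF estimator with per-segment
  covariance averaging, sklearn-style estimator classes, and k-fold
  cross-validated selection of the regularization strength;
* a generative simulation (Gabor-wavelet kernel, random pulse stimulus,
  Gaussian vs 1/f noise at exact SNR) with a known ground truth;
* a synthetic multichannel EEG-study generator (trials, band features,
  non-stationary noise, planted artifacts) so every analysis runs with no
  data download;
* segmentation-duration sweeps and the post-hoc analyses (per-participant
  normalization and exclusion, improvement-vs-baseline regression,
  outlier-trimming robustness).

## Model

The response at channel *c* is a lagged linear function of stimulus
features *s*:

    r_c(t) = Σ_n Σ_τ w_c(τ, n) · s(t − τ, n) + ε(t)

with the TRF `w` estimated by ridge regression on the lagged design matrix,

    w = (SᵀS + λM)⁻¹ Sᵀr,

where the covariances SᵀS and Sᵀr are averaged across data segments (each
normalized by its own sample count) and M leaves the intercept unpenalized.
λ is chosen from nine log-spaced values in 10⁻⁵…10³ by 5-fold
cross-validation over segments; accuracy is the Pearson r between the
predicted and observed response, averaged over channels and held-out
segments.  Each segment is z-scored before fitting; `docs/methods.md`
explains why that normalization is where most of segmentation's effect
lives.

## Worked example

```python
import numpy as np
from trfseg import (GaborKernel, NoiseModel, PulseStimulusConfig,
                    SimulationConfig, SweepConfig, run_simulation_sweep)

cfg = SweepConfig(n_reps=10, durations_sim=(200, 50, 10, 2, 1), seed=0)
sim = SimulationConfig(noise_models=(NoiseModel("gaussian", -30.0),
                                     NoiseModel("one_over_f", -30.0)))
result = run_simulation_sweep(cfg, sim)
print(result.groupby(["noise_kind", "duration"])["accuracy"].mean().round(4))
```

prints (≈90 s on one core):

```
noise_kind  duration
gaussian    1           0.0219
            2           0.0259
            10          0.0283
            50          0.0289
            200         0.0286
one_over_f  1           0.0317
            2           0.0327
            10          0.0332
            50          0.0327
            200         0.0309
Name: accuracy, dtype: float64
```

Read this as the two regimes of the segmentation question.  Under
stationary Gaussian noise, accuracy only falls as segments shorten —
segmentation has nothing to offer and per-segment normalization just adds
noise.  Under non-stationary 1/f noise at the same SNR, accuracy *peaks at
an intermediate duration* (here 2–10 s): short segments approximate
stationarity, deleting slow noise drift, until very short segments (1 s)
start to cost more than they remove.  The absolute r values are small
because the SNR is deliberately very low; the shape of the curve, not its
level, is the result.  A fitted `TRFRidgeCV` estimator exposes the selected
`lam_` and the full accuracy-per-λ table, and the same sweep over the
synthetic EEG cohort (`run_eeg_segment_sweep`) shows the analogous
intermediate-duration optimum together with the tendency of the optimal λ
not to grow when many short segments already average the covariance.

A command-line interface wraps the main workflows:

```
trfseg simulate-sweep -c config.yaml -o results/
trfseg eeg-sweep --bands 1,8,16 -o results/
trfseg synth-study -o data/
trfseg features story.wav -n 8 -o envelopes.tsv
trfseg outliers data/sub-00.h5 --lam 1.0
```

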