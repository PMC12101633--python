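"""Generative simulation of stimulus-response recordings.

The generative model: a known transfer function (a Gabor wavelet — a
sinusoid modulated by a Gaussian envelope) is convolved with a sparse
stimulus of randomly spaced square pulses, and noise is added at a
controlled signal-to-noise ratio.  The noise is either Gaussian
(stationary) or spectrally shaped 1/f "pink" noise, whose power
concentrates at the lowest frequencies and therefore produces slow,
non-stationary excursions — the scenario in which segmenting a recording
before TRF fitting is expected to help.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import InvalidInputError, UndefinedSNRError
from .trf import LagWindow, TRFModel, pearson_r, predict

__all__ = [
    "GaborKernel",
    "PulseStimulusConfig",
    "NoiseModel",
    "SimulationConfig",
    "gabor_wavelet",
    "kernel_to_model",
    "generate_pulse_stimulus",
    "generate_noise",
    "simulate_response",
    "evaluate_recovery",
]


@dataclasses.dataclass(frozen=True)
class GaborKernel:
    """Gabor-wavelet transfer function w(t) = exp(-(t-mu)^2 / (2 sigma^2)) cos(2 pi f t).

    ``mu`` and ``sigma`` position and scale the Gaussian envelope (seconds),
    ``freq`` is the carrier frequency in Hz, and the kernel is sampled on
    t = 0 .. duration at rate ``fs``.
    """

    mu: float = 0.1
    sigma: float = 0.01
    freq: float = 4.0
    duration: float = 0.4
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidInputError("sigma must be positive")
        if self.duration < self.mu + 5 * self.sigma:
            raise InvalidInputError(
                "kernel duration must cover mu + 5 sigma so the support is fully sampled"
            )
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")


def gabor_wavelet(k: GaborKernel) -> np.ndarray:
    """Sample the Gabor wavelet on its causal lag grid t = i / fs."""
    t = np.arange(int(round(k.duration * k.fs)) + 1) / k.fs
    return np.exp(-((t - k.mu) ** 2) / (2 * k.sigma**2)) * np.cos(2 * np.pi * k.freq * t)


def kernel_to_model(k: GaborKernel, gains: np.ndarray | None = None) -> TRFModel:
    """Package a ground-truth kernel as a single-band TRFModel.

    ``gains`` (per channel) broadcasts the kernel across channels; default a
    single unit-gain channel.
    """
    w = gabor_wavelet(k)
    gains = np.atleast_1d(np.asarray(gains if gains is not None else [1.0], dtype=float))
    weights = w[:, None, None] * gains[None, None, :]
    return TRFModel(
        weights=weights,
        bias=np.zeros(len(gains)),
        lag_window=LagWindow(0.0, k.duration, k.fs),
        lam=0.0,
    )


@dataclasses.dataclass(frozen=True)
class PulseStimulusConfig:
    """Randomly spaced square pulses: uniform amplitude, width and gap ranges.

    Defaults give a sparse pulse train (~1.1 events/s, duty cycle ~0.07),
    comparable to word-scale event rates in running speech, so the large
    majority of samples in the convolved response are exactly zero and the
    average signal power — hence the absolute SNR — is very low.
    """

    amp_range: tuple[float, float] = (0.5, 1.5)
    width_range: tuple[float, float] = (0.02, 0.1)
    gap_range: tuple[float, float] = (0.2, 1.5)
    fs: float = 128.0

    def __post_init__(self) -> None:
        for name in ("amp_range", "width_range", "gap_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidInputError(f"{name} must satisfy 0 < low <= high")
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Additive noise: 'gaussian' (white) or 'one_over_f' (power ~ 1/f^beta).

    ``snr_db`` is the target 10 log10(P_signal / P_noise) over the full
    record, calibrated exactly on each realization.
    """

    kind: str = "one_over_f"
    snr_db: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "one_over_f"):
            raise InvalidInputError(f"unknown noise kind {self.kind!r}")


def generate_pulse_stimulus(
    cfg: PulseStimulusConfig, duration: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw a pulse-train stimulus of ``duration`` seconds (truncated exactly)."""
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * cfg.fs))
    out = np.zeros(n)
    pos = 0
    while pos < n:
        pos += max(1, int(round(rng.uniform(*cfg.gap_range) * cfg.fs)))
        if pos >= n:
            break
        width = max(1, int(round(rng.uniform(*cfg.width_range) * cfg.fs)))
        out[pos : pos + width] = rng.uniform(*cfg.amp_range)
        pos += width
    return out


def generate_noise(
    kind: str,
    n_samples: int,
    fs: float = 128.0,
    beta: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate standardized (zero-mean, unit-variance) noise.

    'gaussian' draws i.i.d. normal samples.  'one_over_f' shapes the spectrum
    of white noise: the Fourier amplitudes are multiplied by f^(-beta/2)
    (power ~ 1/f^beta), the diverging DC bin is zeroed, and the shaped
    spectrum is inverse-transformed back to a real signal.
    """
    if n_samples < 16:
        raise InvalidInputError("need at least 16 samples of noise")
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        x = rng.standard_normal(n_samples)
    elif kind == "one_over_f":
        white = rng.standard_normal(n_samples)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-beta / 2.0)
        x = np.fft.irfft(spec * shape, n=n_samples)
    else:
        raise InvalidInputError(f"unknown noise kind {kind!r}")
    x = x - x.mean()
    sd = x.std()
    if sd == 0:  # pragma: no cover - measure-zero event
        raise InvalidInputError("degenerate noise realization")
    return x / sd


def simulate_response(
    stimulus: np.ndarray,
    kernel: GaborKernel,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Convolve stimulus with the kernel and add SNR-calibrated noise.

    The convolution is causal FIR, truncated to the stimulus length.  Noise
    is standardized then scaled so that 10 log10(P_signal / P_noise) equals
    ``noise.snr_db`` exactly for this realization; ``noise=None`` returns the
    clean response.
    """
    stimulus = np.asarray(stimulus, dtype=float).ravel()
    if len(stimulus) == 0:
        raise InvalidInputError("stimulus is empty")
    clean = np.convolve(stimulus, gabor_wavelet(kernel))[: len(stimulus)]
    if noise is None:
        return clean
    p_signal = float(np.mean(clean**2))
    if p_signal == 0.0:
        raise UndefinedSNRError("SNR undefined: noiseless response has zero power")
    z = generate_noise(noise.kind, len(stimulus), kernel.fs, noise.beta, seed)
    scale = np.sqrt(p_signal * 10.0 ** (-noise.snr_db / 10.0))
    return clean + scale * z


def evaluate_recovery(
    true_kernel: GaborKernel,
    est: TRFModel,
    test_duration: float,
    cfg: PulseStimulusConfig,
    seed: int | np.random.Generator = 0,
) -> float:
    """Correlate the responses of the true and the estimated TRF to a fresh stimulus.

    Draws a new pulse stimulus, convolves it (noiselessly) with both the
    ground-truth kernel and the estimated model, and returns the Pearson r of
    the two responses (averaged over channels for multichannel estimates).
    """
    if est.fs != true_kernel.fs:
        raise InvalidInputError("estimated model and true kernel sampling rates differ")
    stim = generate_pulse_stimulus(cfg, test_duration, seed)
    ref = np.convolve(stim, gabor_wavelet(true_kernel))[: len(stim)]
    if est.n_bands != 1:
        raise InvalidInputError("recovery evaluation expects a single-band model")
    pred = predict(est, stim[:, None])
    return float(np.mean([pearson_r(ref, pred[:, c]) for c in range(pred.shape[1])]))


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the simulation study: kernel, stimulus and noise models.

    The default noise grid crosses both noise kinds with SNRs of -25, -30
    and -35 dB.  The absolute values are very low because the sparse pulse
    response leaves most samples at zero, depressing the average signal
    power; the grid spans the transition from near-saturated recovery to the
    noise-dominated regime where non-stationarity matters most.  Segment
    durations, repetition count and train/test lengths live in
    :class:`trfseg.study.SweepConfig`.
    """

    kernel: GaborKernel = GaborKernel()
    pulse: PulseStimulusConfig = PulseStimulusConfig()
    noise_models: tuple[NoiseModel, ...] = tuple(
        NoiseModel(kind, snr)
        for kind in ("gaussian", "one_over_f")
        for snr in (-25.0, -30.0, -35.0)
    )
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.kernel.fs != self.fs or self.pulse.fs != self.fs:
            raise InvalidInputError("kernel, pulse and simulation sampling rates must agree")
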