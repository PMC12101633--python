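"""Synthetic multichannel EEG-like study generator.

Stands in for a real speech-listening EEG experiment: a cohort of
participants, each with ~20 two-minute trials in which every channel's
clean response is a sum over spectral bands of envelope-like features
convolved with a channel-specific Gabor kernel, buried in non-stationary
1/f noise.  Trial stimuli (the "story") are shared across the cohort;
noise, per-participant SNR, and planted artifacts are participant-specific.

Two artifact mechanisms exist for robustness analyses and are off by
default: outlier trials, whose noise is multiplied by a burst factor over a
random sub-interval, and a slow sinusoidal gain drift on the noise
envelope.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
from scipy import signal as sp_signal

from .exceptions import InvalidInputError
from .simulation import GaborKernel, gabor_wavelet, generate_noise
from .trf import SegmentPair

__all__ = [
    "SyntheticStudyConfig",
    "ParticipantData",
    "generate_band_features",
    "generate_participant",
    "generate_study",
]

#: Default segment-duration sweep the trial layout must support (seconds).
_EEG_DURATIONS = (120, 60, 40, 30, 15, 10, 5, 2, 1)


@dataclasses.dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level conditions for the synthetic cohort.

    Defaults emulate a 20-trial, 120 s/trial listening study sampled at
    64 Hz with 16 channels and a 16-band stimulus representation, under
    1/f noise at a mean SNR of -10 dB (spread +/- ``snr_spread_db`` across
    participants so that baseline accuracy varies over the cohort).
    """

    n_participants: int = 8
    n_channels: int = 16
    n_bands: int = 16
    n_trials: int = 20
    trial_duration: float = 120.0
    fs: float = 64.0
    kernel_mu: float = 0.11
    kernel_sigma: float = 0.03
    kernel_freq: float = 3.0
    kernel_duration: float = 0.35
    noise_kind: str = "one_over_f"
    snr_db: float = -10.0
    snr_spread_db: float = 6.0
    noise_beta: float = 1.0
    outlier_rate: float = 0.0
    outlier_burst: float = 10.0
    drift_amp: float = 0.0
    drift_period: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands not in (1, 8, 16):
            raise InvalidInputError("n_bands must be one of 1, 8, 16")
        total = self.n_trials * self.trial_duration
        for d in _EEG_DURATIONS:
            if round(total) % d:
                raise InvalidInputError(
                    f"total duration {total} s is not divisible by sweep duration {d} s"
                )
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise InvalidInputError("outlier_rate must lie in [0, 1]")


@dataclasses.dataclass
class ParticipantData:
    """One synthetic participant: trials plus the generative ground truth."""

    participant_id: str
    trials: list[SegmentPair]
    kernels: list[GaborKernel]  # per channel
    band_gains: np.ndarray  # (n_channels, n_bands)
    snr_db: float
    outlier_trials: list[int]


def generate_band_features(
    n_bands: int, duration: float, fs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Envelope-like stimulus features: non-negative, smooth, inter-band correlated.

    Each band is a rectified low-pass-filtered (8 Hz) noise process mixing a
    shared broadband component with a band-private one, which yields the
    positive pairwise correlations characteristic of multiband speech
    envelopes.
    """
    if n_bands < 1:
        raise InvalidInputError("n_bands must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    sos = sp_signal.butter(4, 8.0, btype="low", fs=fs, output="sos")
    shared = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    shared /= shared.std()
    feats = np.empty((n, n_bands))
    for b in range(n_bands):
        own = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        own /= own.std()
        feats[:, b] = np.clip(0.7 * shared + np.sqrt(1 - 0.49) * own, 0.0, None)
    return feats


def _kernel_bank(cfg: SyntheticStudyConfig) -> tuple[list[GaborKernel], np.ndarray, np.ndarray]:
    """Per-channel kernels and (channel, band) gains, smooth across the array.

    Channels share the kernel shape with smoothly varying latency and gain
    (a crude stand-in for scalp topography); band gains follow a Gaussian
    tuning profile whose preferred band drifts across channels.
    """
    nc, nb = cfg.n_channels, cfg.n_bands
    c = np.arange(nc)
    latency = cfg.kernel_mu + 0.02 * np.sin(2 * np.pi * c / max(nc, 1))
    chan_gain = 0.6 + 0.8 * np.exp(-((c - nc / 2.0) ** 2) / (2 * (nc / 4.0) ** 2))
    kernels = [
        GaborKernel(
            mu=float(latency[i]),
            sigma=cfg.kernel_sigma,
            freq=cfg.kernel_freq,
            duration=cfg.kernel_duration,
            fs=cfg.fs,
        )
        for i in range(nc)
    ]
    b = np.arange(nb)
    center = (c / max(nc - 1, 1)) * max(nb - 1, 1)
    band_gains = np.exp(-((b[None, :] - center[:, None]) ** 2) / (2 * (max(nb, 2) / 3.0) ** 2))
    band_gains /= band_gains.sum(axis=1, keepdims=True)
    return kernels, chan_gain, band_gains


def generate_participant(
    cfg: SyntheticStudyConfig, participant_idx: int
) -> ParticipantData:
    """Generate one participant's trials with known ground truth.

    Trial stimulus features are derived from ``cfg.seed`` alone (shared
    across the cohort, like a common story); noise and artifacts are drawn
    per participant.  Each channel's noise is scaled to the participant's
    SNR against that channel's clean-response power.
    """
    kernels, chan_gain, band_gains = _kernel_bank(cfg)
    n = int(round(cfg.trial_duration * cfg.fs))
    part_rng = np.random.default_rng([cfg.seed, 101, participant_idx])
    snr_db = cfg.snr_db + cfg.snr_spread_db * (part_rng.uniform() - 0.5)

    n_outliers = int(round(cfg.outlier_rate * cfg.n_trials))
    outlier_trials = sorted(
        part_rng.choice(cfg.n_trials, size=n_outliers, replace=False).tolist()
    )

    kernel_samples = [gabor_wavelet(k) for k in kernels]
    trials: list[SegmentPair] = []
    for t in range(cfg.n_trials):
        feats = generate_band_features(
            cfg.n_bands, cfg.trial_duration, cfg.fs, seed=[cfg.seed, 901, t]
        )
        clean = np.empty((n, cfg.n_channels))
        for c in range(cfg.n_channels):
            mix = feats @ band_gains[c]
            clean[:, c] = chan_gain[c] * np.convolve(mix, kernel_samples[c])[:n]

        noise = np.empty_like(clean)
        for c in range(cfg.n_channels):
            z = generate_noise(
                cfg.noise_kind, n, cfg.fs, cfg.noise_beta,
                seed=[cfg.seed, 11, participant_idx, t, c],
            )
            noise[:, c] = z * np.sqrt(np.mean(clean[:, c] ** 2) * 10.0 ** (-snr_db / 10.0))

        if cfg.drift_amp > 0:
            tt = np.arange(n) / cfg.fs + t * cfg.trial_duration
            phase = part_rng.uniform(0, 2 * np.pi)
            noise *= (1.0 + cfg.drift_amp * np.sin(2 * np.pi * tt / cfg.drift_period + phase))[:, None]

        if t in outlier_trials:
            burst_rng = np.random.default_rng([cfg.seed, 77, participant_idx, t])
            length = int(n * burst_rng.uniform(0.2, 0.5))
            start = burst_rng.integers(0, n - length)
            noise[start : start + length] *= cfg.outlier_burst

        trials.append(SegmentPair(feats, clean + noise, cfg.fs))

    return ParticipantData(
        participant_id=f"sub-{participant_idx:02d}",
        trials=trials,
        kernels=kernels,
        band_gains=chan_gain[:, None] * band_gains,
        snr_db=float(snr_db),
        outlier_trials=outlier_trials,
    )


def generate_study(cfg: SyntheticStudyConfig) -> Iterator[ParticipantData]:
    """Yield every participant of the synthetic cohort."""
    for i in range(cfg.n_participants):
        yield generate_participant(cfg, i)
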