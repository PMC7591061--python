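"""Spectral-gating noise reduction.

Given a noisy recording and a clip containing only background noise, the
gate estimates a per-frequency threshold from the noise clip's log-magnitude
STFT statistics (mean + n_std * std), builds a binary keep/suppress mask over
the signal's STFT, smooths the mask over frequency and time, scales the
suppression by ``prop_decrease``, multiplies the signal magnitude by the
mask (keeping the noisy phase), and inverts.

The threshold statistic is computed in the dB (log-magnitude) domain, which
makes the gate invariant to the absolute amplitude scale.  The smoothing
kernel is a normalized separable triangular window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d, istft, stft
from scipy.signal.windows import triang

from .audio import SpectrogramParams, TooShortError, Waveform

_DB_FLOOR = -200.0  # log floor for exact zeros in magnitude spectra


@dataclass(frozen=True)
class GateConfig:
    n_std: float = 1.5
    smooth_freq_bins: int = 4
    smooth_time_frames: int = 4
    prop_decrease: float = 1.0
    confirm_neighbors: int = 4  # 8-neighborhood support required for a hard keep

    def __post_init__(self):
        if self.n_std < 0:
            raise ValueError("n_std must be >= 0")
        if self.smooth_freq_bins < 1 or self.smooth_time_frames < 1:
            raise ValueError("smoothing widths must be >= 1")
        if not 0 <= self.prop_decrease <= 1:
            raise ValueError("prop_decrease must be in [0, 1]")


@dataclass(frozen=True)
class NoiseProfile:
    """Per-frequency mean/std of the noise clip's log-magnitude STFT."""

    mean_db: np.ndarray
    std_db: np.ndarray
    n_fft: int
    hop: int
    sample_rate_hz: float


def _stft_mag_phase(w: Waveform, n_fft: int, hop: int):
    f, t, Z = stft(w.samples, fs=w.sample_rate_hz, window="hann",
                   nperseg=n_fft, noverlap=n_fft - hop, boundary="zeros",
                   padded=True)
    return np.abs(Z), np.angle(Z)


def _to_db(mag: np.ndarray) -> np.ndarray:
    return 20.0 * np.log10(np.maximum(mag, 10.0 ** (_DB_FLOOR / 20.0)))


def estimate_noise_profile(noise: Waveform, stft_params: SpectrogramParams | None = None,
                           ) -> NoiseProfile:
    """Mean and standard deviation of the noise log-magnitude per frequency bin."""
    if stft_params is None:
        stft_params = SpectrogramParams()
    hop = stft_params.hop_samples(noise.sample_rate_hz)
    if len(noise) < stft_params.n_fft:
        raise TooShortError("noise clip shorter than one STFT frame")
    mag, _ = _stft_mag_phase(noise, stft_params.n_fft, hop)
    db = _to_db(mag)  # (freq, time)
    return NoiseProfile(mean_db=db.mean(axis=1), std_db=db.std(axis=1),
                        n_fft=stft_params.n_fft, hop=hop,
                        sample_rate_hz=noise.sample_rate_hz)


def compute_mask(spec_s_db: np.ndarray, profile: NoiseProfile,
                 cfg: GateConfig | None = None) -> np.ndarray:
    """Smoothed gate mask in [0, 1] over a (time, freq) dB spectrogram.

    Raw mask: 1 where the signal exceeds mean + n_std * std of the noise at
    that frequency, else 0; smoothed over frequency and time; then
    suppression scaled so that prop_decrease=0 leaves everything untouched.

    Smoothing alone would scale an isolated narrowband peak by the kernel's
    center weight on every application, making the gate non-idempotent and
    eroding tonal signal.  The final mask is therefore floored at the
    *confirmed* raw mask: a raw keep-decision becomes a hard keep when at
    least ``confirm_neighbors`` of its 8-neighborhood are also above
    threshold (coherent spectrotemporal structure, which sustained signal
    always has), while unsupported exceedances — isolated noise pops — fall
    back to the smoothed value and stay suppressed.
    """
    if cfg is None:
        cfg = GateConfig()
    spec_s_db = np.asarray(spec_s_db, dtype=float)
    if spec_s_db.ndim != 2 or spec_s_db.shape[1] != len(profile.mean_db):
        raise ValueError(
            f"spectrogram frequency dimension {spec_s_db.shape} does not match "
            f"profile length {len(profile.mean_db)}"
        )
    thresh = profile.mean_db + cfg.n_std * profile.std_db
    raw = (spec_s_db > thresh[None, :]).astype(float)
    neighbor_count = convolve2d(raw, np.ones((3, 3)), mode="same") - raw
    confirmed = raw * (neighbor_count >= cfg.confirm_neighbors)
    smoothed = np.maximum(confirmed, smooth_mask(raw, cfg))
    return 1.0 - cfg.prop_decrease * (1.0 - smoothed)


def smooth_mask(mask: np.ndarray, cfg: GateConfig) -> np.ndarray:
    """Separable triangular smoothing over (time, freq); width 1 is identity."""
    def kernel(width: int) -> np.ndarray:
        k = triang(2 * width - 1)
        return k / k.sum()

    kt = kernel(cfg.smooth_time_frames)[:, None]
    kf = kernel(cfg.smooth_freq_bins)[None, :]
    out = convolve2d(mask, kt, mode="same", boundary="symm")
    out = convolve2d(out, kf, mode="same", boundary="symm")
    return np.clip(out, 0.0, 1.0)


def reduce_noise(signal: Waveform, noise: Waveform,
                 stft_params: SpectrogramParams | None = None,
                 cfg: GateConfig | None = None) -> Waveform:
    """Full spectral gate: profile -> mask -> masked magnitude -> inverse STFT.

    The noisy signal's phase is reused at inversion; output length equals
    input length.
    """
    if stft_params is None:
        stft_params = SpectrogramParams()
    if cfg is None:
        cfg = GateConfig()
    if signal.sample_rate_hz != noise.sample_rate_hz:
        raise ValueError("signal and noise clips must share a sample rate")
    profile = estimate_noise_profile(noise, stft_params)
    hop = profile.hop
    n_fft = profile.n_fft
    if len(signal) < n_fft:
        raise TooShortError("signal shorter than one STFT frame")
    mag, phase = _stft_mag_phase(signal, n_fft, hop)  # (freq, time)
    mask = compute_mask(_to_db(mag).T, profile, cfg).T
    Z = mag * mask * np.exp(1j * phase)
    _, x = istft(Z, fs=signal.sample_rate_hz, window="hann",
                 nperseg=n_fft, noverlap=n_fft - hop)
    n = len(signal)
    if len(x) < n:
        x = np.pad(x, (0, n - len(x)))
    return Waveform(x[:n], signal.sample_rate_hz)
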