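"""Audio I/O, band-pass filtering, spectrograms, and the amplitude envelope.

The spectrogram here is the substrate for everything downstream: magnitude
STFT of a Butterworth band-pass filtered waveform, optionally collapsed onto
a mel filterbank, log-scaled relative to the per-recording maximum, floored,
and rescaled to [0, 1].  The amplitude envelope used for segmentation is, per
time frame, the maximum power across frequency times the square root of the
mean power across frequency.

Conventions (fixed and tested):
  * matrices are (time, frequency); flattening is time-major
  * STFT frames lie fully inside the signal (no padding), so
    n_frames = 1 + floor((n_samples - n_fft) / hop)
  * dB reference is the spectrogram maximum of the recording
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, get_window, sosfiltfilt


class FormatError(ValueError):
    """Unreadable or ambiguous audio file."""


class TooShortError(ValueError):
    """Waveform shorter than a single analysis frame."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: samples (float, |x| nominally <= 1) and sample rate."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise FormatError("Waveform requires a 1-D mono sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SpectrogramParams:
    """Parameters of the spectrogram computation.

    ``db_floor`` is the minimum log power retained, in dB relative to the
    recording maximum; values below it are clipped before rescaling to [0, 1],
    which zeroes low-level background in the normalized spectrogram.
    """

    n_fft: int = 512
    hop_s: float = 128 / 22050
    window: str = "hann"
    fmin_hz: float = 500.0
    fmax_hz: float = 8000.0
    n_mel: int = 32
    db_floor: float = -40.0
    scale: str = "mel"

    def __post_init__(self):
        if self.n_fft < 2:
            raise ValueError("n_fft must be >= 2")
        if self.hop_s <= 0:
            raise ValueError("hop_s must be positive")
        if not 0 <= self.fmin_hz < self.fmax_hz:
            raise ValueError("need 0 <= fmin_hz < fmax_hz")
        if self.n_mel < 2:
            raise ValueError("n_mel must be >= 2")
        if self.db_floor >= 0:
            raise ValueError("db_floor must be negative (dB re max)")
        if self.scale not in ("mel", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def hop_samples(self, sample_rate_hz: float) -> int:
        hop = int(round(self.hop_s * sample_rate_hz))
        return max(1, hop)


@dataclass(frozen=True)
class Spectrogram:
    """Normalized (time, frequency) power matrix with frame center times."""

    S: np.ndarray
    frame_times_s: np.ndarray
    params: SpectrogramParams
    sample_rate_hz: float
    freqs_hz: np.ndarray = field(default=None)  # band centers (mel) or bin freqs

    @property
    def n_frames(self) -> int:
        return self.S.shape[0]

    @property
    def n_bins(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class Envelope:
    """Per-frame envelope E(t) = sqrt(mean_f S) * max_f S, and its ingredients.

    ``E`` is rescaled to max 1 when ``rescaled`` is True (the form used for
    dynamic thresholding); ``E_raw`` is the un-rescaled statistic.
    """

    mu: np.ndarray
    E: np.ndarray
    E_raw: np.ndarray
    frame_times_s: np.ndarray
    rescaled: bool


def read_wav(path, mixdown: bool = False) -> Waveform:
    """Read a WAV file into a float Waveform in [-1, 1].

    Integer PCM is scaled by its type maximum.  Multi-channel audio raises a
    FormatError unless ``mixdown`` is set, in which case channels are averaged.
    """
    try:
        sr, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on junk input
        raise FormatError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"empty WAV file: {path}")
    if data.ndim == 2:
        if not mixdown:
            raise FormatError(
                f"{path} has {data.shape[1]} channels; pass mixdown=True to average"
            )
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return Waveform(samples=data, sample_rate_hz=float(sr))


def write_wav(path, w: Waveform, dtype: str = "int16") -> None:
    """Write a Waveform as PCM 16-bit (default) or float32 WAV."""
    if dtype == "int16":
        clipped = np.clip(w.samples, -1.0, 1.0)
        data = (clipped * np.iinfo(np.int16).max).round().astype(np.int16)
    elif dtype == "float32":
        data = w.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    wavfile.write(path, int(round(w.sample_rate_hz)), data)


def bandpass(w: Waveform, fmin_hz: float, fmax_hz: float, order: int = 5) -> Waveform:
    """Zero-phase Butterworth band-pass filter (forward-backward, length preserving)."""
    nyquist = w.sample_rate_hz / 2.0
    if not 0 < fmin_hz < fmax_hz < nyquist:
        raise ValueError(
            f"band [{fmin_hz}, {fmax_hz}] Hz invalid for Nyquist {nyquist} Hz"
        )
    sos = butter(order, [fmin_hz, fmax_hz], btype="bandpass", fs=w.sample_rate_hz,
                 output="sos")
    return Waveform(sosfiltfilt(sos, w.samples), w.sample_rate_hz)


def frame_signal(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Frames fully inside the signal, shape (n_frames, n_fft)."""
    n = len(x)
    if n < n_fft:
        raise TooShortError(f"signal of {n} samples shorter than one {n_fft} frame")
    n_frames = 1 + (n - n_fft) // hop
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mel: int, n_fft: int, sample_rate_hz: float,
                   fmin_hz: float, fmax_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank, shape (n_fft//2 + 1, n_mel), plus band centers.

    Standard construction: band edges equally spaced on the mel scale between
    fmin and fmax; each filter rises and falls linearly in Hz between adjacent
    edges.  Filters are peak-normalized so that a pure tone keeps comparable
    magnitude across bands.
    """
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_mel + 2))
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    fb = np.zeros((len(fft_freqs), n_mel))
    for j in range(n_mel):
        lo, center, hi = edges_hz[j], edges_hz[j + 1], edges_hz[j + 2]
        rising = (fft_freqs - lo) / max(center - lo, 1e-12)
        falling = (hi - fft_freqs) / max(hi - center, 1e-12)
        fb[:, j] = np.clip(np.minimum(rising, falling), 0.0, None)
        peak = fb[:, j].max()
        if peak > 0:
            fb[:, j] /= peak
    return fb, edges_hz[1:-1]


def spectrogram(w: Waveform, p: SpectrogramParams | None = None) -> Spectrogram:
    """Magnitude STFT -> (mel) -> dB re max -> floor -> [0, 1] rescale.

    An all-silent recording (max magnitude 0) maps to an all-zero spectrogram.
    """
    if p is None:
        p = SpectrogramParams()
    hop = p.hop_samples(w.sample_rate_hz)
    frames = frame_signal(w.samples, p.n_fft, hop)
    win = get_window(p.window, p.n_fft, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    fft_freqs = np.fft.rfftfreq(p.n_fft, d=1.0 / w.sample_rate_hz)

    if p.scale == "mel":
        fb, centers = mel_filterbank(p.n_mel, p.n_fft, w.sample_rate_hz,
                                     p.fmin_hz, p.fmax_hz)
        mag = mag @ fb
        freqs = centers
    else:
        keep = (fft_freqs >= p.fmin_hz) & (fft_freqs <= p.fmax_hz)
        mag = mag[:, keep]
        freqs = fft_freqs[keep]

    peak = mag.max()
    if peak == 0:
        S = np.zeros_like(mag)
    else:
        db = 20.0 * np.log10(np.maximum(mag, 1e-12 * peak) / peak)
        db = np.maximum(db, p.db_floor)
        S = (db - p.db_floor) / (-p.db_floor)

    n_frames = mag.shape[0]
    frame_times = (np.arange(n_frames) * hop + p.n_fft / 2.0) / w.sample_rate_hz
    return Spectrogram(S=S, frame_times_s=frame_times, params=p,
                       sample_rate_hz=w.sample_rate_hz, freqs_hz=freqs)


def envelope(spec: Spectrogram, rescale: bool = True) -> Envelope:
    """Amplitude envelope of a normalized spectrogram.

    mu(t) is the mean power over frequency; the envelope is
    E(t) = sqrt(mu(t)) * max_f S(t, f), optionally rescaled by its own
    maximum so thresholds can be expressed as fractions of the peak.
    """
    S = spec.S
    if S.size == 0:
        raise ValueError("empty spectrogram")
    mu = S.mean(axis=1)
    e_raw = np.sqrt(mu) * S.max(axis=1)
    peak = e_raw.max()
    e = e_raw / peak if (rescale and peak > 0) else e_raw.copy()
    return Envelope(mu=mu, E=e, E_raw=e_raw, frame_times_s=spec.frame_times_s,
                    rescaled=rescale and peak > 0)


def waveform_rms(w: Waveform) -> float:
    return float(np.sqrt(np.mean(np.square(w.samples)))) if len(w) else 0.0
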