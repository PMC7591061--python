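"""Dynamic-threshold segmentation and uniform syllable spectrogram preparation.

Vocal units (syllables) are defined as regions of continuous vocalization
surrounded by silent pauses.  Silence versus vocalization is decided by a
threshold on the spectrogram amplitude envelope; the threshold is set
dynamically, starting sensitive and rising multiplicatively until the
segmentation satisfies prior expectations about the signal (enough silence,
no over-long vocal runs).  Recordings that never satisfy them are rejected
as too low SNR.

Boundary convention: an STFT frame starting at sample i*hop spans
[i*hop, i*hop + n_fft).  A frame's envelope responds as soon as its window
overlaps a syllable, so the detected run over-covers the syllable by up to a
window length on each side.  Onsets are therefore reported at the *end* of
the window where the envelope first crosses the threshold, and offsets at
the *start* of the window where it last does, with linear sub-frame
interpolation of the crossing; this cancels the window-length smear.  The
window's taper still delays detectability by a few milliseconds each side,
so by default each boundary is then refined in the time domain: within one
window length of the coarse boundary, the boundary is moved to the edge of
the sustained region where a short-window RMS envelope exceeds a fraction
of the segment's own RMS.  Time-domain RMS has no STFT smear, leaving
boundaries accurate to a millisecond or two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import (Envelope, Spectrogram, SpectrogramParams, Waveform,
                    envelope, spectrogram)

SEGMENT_COLUMNS = ["bout_id", "onset_s", "offset_s", "label"]


class LowSNRError(RuntimeError):
    """The threshold schedule was exhausted without a valid segmentation."""


@dataclass(frozen=True)
class SegmentationConfig:
    min_silence_s: float = 0.03
    max_vocal_s: float = 0.4
    min_segment_s: float = 0.04
    min_silence_fraction: float = 0.4
    threshold_start: float = 0.05
    threshold_step: float = 1.5
    threshold_max: float = 0.5
    refine_boundaries: bool = True
    refine_level: float = 0.25          # RMS fraction of the segment's own RMS
    refine_rms_window_s: float = 0.0015
    spectrogram_params: SpectrogramParams = field(
        default_factory=lambda: SpectrogramParams(scale="linear", db_floor=-30.0))

    def __post_init__(self):
        if not 0 < self.threshold_start < self.threshold_max <= 1:
            raise ValueError("need 0 < threshold_start < threshold_max <= 1")
        if self.threshold_step <= 1:
            raise ValueError("threshold_step must be > 1")
        if not self.min_segment_s < self.max_vocal_s:
            raise ValueError("min_segment_s must be < max_vocal_s")
        if not 0 <= self.min_silence_fraction < 1:
            raise ValueError("min_silence_fraction must be in [0, 1)")


@dataclass
class SyllableDataset:
    """Uniformly sized, log-time-rescaled, zero-padded syllable spectrograms.

    ``X`` rows are flattened time-major: row = concat over t of the n_mel
    frequency values of frame t.
    """

    X: np.ndarray
    pad_frames: int
    n_bins: int
    durations_s: np.ndarray
    source: pd.DataFrame          # columns bout_id, index
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return self.X.shape[0]

    def spectrogram_of(self, i: int) -> np.ndarray:
        return self.X[i].reshape(self.pad_frames, self.n_bins)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts, ends))


def _interp_boundaries(env: np.ndarray, run: tuple[int, int], thr: float,
                       hop: int, n_fft: int, sr: float) -> tuple[float, float]:
    i0, i1 = run
    if i0 > 0 and env[i0] > env[i0 - 1]:
        frac = (thr - env[i0 - 1]) / (env[i0] - env[i0 - 1])
        onset = ((i0 - 1 + frac) * hop + n_fft) / sr
    else:
        onset = i0 * hop / sr
    n = len(env)
    if i1 < n - 1 and env[i1] > env[i1 + 1]:
        frac = (env[i1] - thr) / (env[i1] - env[i1 + 1])
        offset = (i1 + frac) * hop / sr
    else:
        offset = (i1 * hop + n_fft) / sr
    if offset <= onset:  # degenerate narrow run; fall back to frame times
        onset, offset = i0 * hop / sr, (i1 * hop + n_fft) / sr
    return onset, offset


def _segments_at_threshold(env: Envelope, thr: float, cfg: SegmentationConfig,
                           hop: int, n_fft: int, sr: float):
    vocal = env.E >= thr
    runs = _runs(vocal)
    bounds = [_interp_boundaries(env.E, r, thr, hop, n_fft, sr) for r in runs]
    # merge runs separated by silences shorter than min_silence_s
    merged: list[list[float]] = []
    for on, off in bounds:
        if merged and on - merged[-1][1] < cfg.min_silence_s:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    kept = [(on, off) for on, off in merged if off - on >= cfg.min_segment_s]
    silent_fraction = 1.0 - float(vocal.mean())
    return kept, silent_fraction


def _rms_envelope(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving RMS with an odd window of ``win`` samples."""
    win = max(1, win | 1)
    kernel = np.ones(win) / win
    return np.sqrt(np.convolve(np.square(x), kernel, mode="same"))


def _refine_segments(w: Waveform, segments: list[list[float]], n_fft: int,
                     cfg: SegmentationConfig) -> list[tuple[float, float]]:
    """Snap coarse boundaries to time-domain RMS crossings.

    Each boundary may move by at most one STFT window; the target is the
    edge of the sustained region where the moving RMS exceeds
    refine_level * the segment's core RMS (90th percentile).  Search ranges
    are clamped at the midpoint to neighboring segments so refinement can
    never create overlaps.
    """
    sr = w.sample_rate_hz
    rms = _rms_envelope(w.samples, int(round(cfg.refine_rms_window_s * sr)))
    n = len(w.samples)
    out = []
    for i, (on, off) in enumerate(segments):
        a, b = int(round(on * sr)), int(round(off * sr))
        core = rms[a:b]
        if core.size == 0:
            out.append((on, off))
            continue
        level = cfg.refine_level * np.percentile(core, 90)
        lo = 0 if i == 0 else int(round((segments[i - 1][1] + on) / 2 * sr))
        hi = n if i == len(segments) - 1 else int(round((off + segments[i + 1][0]) / 2 * sr))
        lo = max(lo, a - n_fft)
        hi = min(hi, b + n_fft)
        above = rms[lo:hi] >= level
        runs = _runs(above)
        # the run overlapping the coarse segment is the syllable
        best = None
        for r0, r1 in runs:
            if lo + r1 >= a and lo + r0 <= b:
                best = (r0, r1) if best is None else (min(best[0], r0), max(best[1], r1))
        if best is None:
            out.append((on, off))
            continue
        out.append(((lo + best[0]) / sr, (lo + best[1] + 1) / sr))
    return out


def dynamic_threshold_segment(w: Waveform, cfg: SegmentationConfig | None = None,
                              bout_id: int = 0) -> pd.DataFrame:
    """Segment a recording into vocal units by dynamic envelope thresholding.

    Returns a segment table (bout_id, onset_s, offset_s, label=NA) with
    half-open, non-overlapping intervals sorted by onset.  Raises
    LowSNRError when no threshold in the schedule yields a segmentation with
    at least one unit, sufficient silence, and no over-long vocal run.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    p = cfg.spectrogram_params
    spec = spectrogram(w, p)
    env = envelope(spec, rescale=True)
    hop = p.hop_samples(w.sample_rate_hz)
    thr = cfg.threshold_start
    while thr <= cfg.threshold_max + 1e-12:
        kept, silent_fraction = _segments_at_threshold(
            env, thr, cfg, hop, p.n_fft, w.sample_rate_hz)
        if kept:
            longest = max(off - on for on, off in kept)
            if silent_fraction >= cfg.min_silence_fraction and longest <= cfg.max_vocal_s:
                if cfg.refine_boundaries:
                    kept = _refine_segments(w, [list(s) for s in kept],
                                            p.n_fft, cfg)
                return pd.DataFrame({
                    "bout_id": bout_id,
                    "onset_s": [on for on, _ in kept],
                    "offset_s": [off for _, off in kept],
                    "label": pd.Series([pd.NA] * len(kept), dtype="object"),
                })
        thr *= cfg.threshold_step
    raise LowSNRError(
        "threshold schedule exhausted: recording rejected as too low SNR"
    )


def extract_syllables(spec: Spectrogram, seg: pd.DataFrame) -> list[np.ndarray]:
    """Per-segment column slices of a spectrogram.

    Frame mapping is floor(onset/hop) to ceil(offset/hop), half-open, so
    abutting segments partition the covered columns without overlap.
    """
    hop_s = spec.params.hop_samples(spec.sample_rate_hz) / spec.sample_rate_hz
    span = spec.n_frames * hop_s + spec.params.n_fft / spec.sample_rate_hz
    out = []
    for _, row in seg.iterrows():
        if row.onset_s < 0 or row.offset_s > span:
            raise ValueError(
                f"segment [{row.onset_s}, {row.offset_s}) outside spectrogram span {span:.3f}s"
            )
        a = int(np.floor(row.onset_s / hop_s))
        b = int(np.ceil(row.offset_s / hop_s))
        b = min(b, spec.n_frames)
        a = min(a, b - 1) if b > 0 else 0
        out.append(spec.S[a:b])
    return out


def log_rescale_pad(syllables: list[np.ndarray], pad_frames: int,
                    d_ref_s: float, durations_s=None,
                    hop_s: float | None = None,
                    source: pd.DataFrame | None = None,
                    labels=None, fractional: bool = True) -> SyllableDataset:
    """Log-rescale syllable spectrograms in time and zero-pad to a common length.

    Each syllable's time axis is linearly resampled to
    L_i = pad_frames * ln(1 + d_i/d_ref) / ln(1 + d_max/d_ref)
    frames, where d_max is the longest duration in the batch, then padded
    with zeros on the right; the frequency axis is untouched.  Rows of the
    returned matrix are flattened time-major.

    With ``fractional`` (default), L_i is treated as real-valued: the frame
    straddling the cut boundary is weighted by the fractional part, so the
    padded representation varies continuously with duration.  Rounding L_i
    to an integer instead (``fractional=False``) quantizes duration into
    discrete pad lengths, which puts artificial density valleys between
    syllables of neighboring lengths and fragments latent projections.
    """
    if pad_frames < 1:
        raise ValueError("pad_frames must be >= 1")
    if len(syllables) == 0:
        raise ValueError("empty syllable batch")
    if any(s.shape[0] == 0 for s in syllables):
        raise ValueError("syllables must be non-empty")
    if durations_s is None:
        if hop_s is None:
            raise ValueError("pass durations_s or hop_s to infer durations")
        durations_s = np.array([s.shape[0] * hop_s for s in syllables], dtype=float)
    else:
        durations_s = np.asarray(durations_s, dtype=float)
    if d_ref_s <= 0:
        raise ValueError("d_ref_s must be positive")
    d_max = durations_s.max()
    denom = np.log1p(d_max / d_ref_s)
    n_bins = syllables[0].shape[1]
    if any(s.shape[1] != n_bins for s in syllables):
        raise ValueError("syllables must share a frequency axis")

    X = np.zeros((len(syllables), pad_frames * n_bins))
    for i, (syl, d) in enumerate(zip(syllables, durations_s)):
        L_real = (pad_frames * np.log1p(d / d_ref_s) / denom if denom > 0
                  else float(pad_frames))
        L_real = min(L_real, float(pad_frames))
        if fractional:
            L_floor = int(np.floor(L_real))
            frac = L_real - L_floor
            L = max(1, L_floor + (1 if frac > 0 else 0))
        else:
            L = max(1, min(int(round(L_real)), pad_frames))
            frac = 0.0
        t_in = np.linspace(0.0, 1.0, syl.shape[0])
        t_out = np.linspace(0.0, 1.0, L)
        resampled = np.empty((L, n_bins))
        for f in range(n_bins):
            resampled[:, f] = np.interp(t_out, t_in, syl[:, f])
        if fractional and frac > 0 and L > int(np.floor(L_real)):
            resampled[-1] *= frac
        padded = np.zeros((pad_frames, n_bins))
        padded[:L] = resampled
        X[i] = padded.reshape(-1)

    if source is None:
        source = pd.DataFrame({"bout_id": 0, "index": np.arange(len(syllables))})
    return SyllableDataset(X=X, pad_frames=pad_frames, n_bins=n_bins,
                           durations_s=durations_s, source=source.reset_index(drop=True),
                           labels=None if labels is None else np.asarray(labels))


def syllable_dataset_from_bouts(waveforms, segment_tables, params=None,
                                pad_frames: int = 32, d_ref_s: float | None = None,
                                ) -> SyllableDataset:
    """Segment tables + recordings -> uniform syllable dataset.

    Convenience composition of spectrogram, extract_syllables, and
    log_rescale_pad across bouts; labels are carried through when present.
    """
    if params is None:
        params = SpectrogramParams()
    all_syl, durations, rows, labels = [], [], [], []
    have_labels = True
    for w, seg in zip(waveforms, segment_tables):
        if len(seg) == 0:
            continue
        spec = spectrogram(w, params)
        syls = extract_syllables(spec, seg)
        for j, (syl, (_, row)) in enumerate(zip(syls, seg.iterrows())):
            all_syl.append(syl)
            durations.append(row.offset_s - row.onset_s)
            rows.append({"bout_id": row.bout_id, "index": j})
            lab = row.get("label", pd.NA)
            if pd.isna(lab):
                have_labels = False
            labels.append(lab)
    if not all_syl:
        raise ValueError("no syllables found in any bout")
    if d_ref_s is None:
        d_ref_s = 0.02
    ds = log_rescale_pad(all_syl, pad_frames, d_ref_s,
                         durations_s=np.array(durations),
                         source=pd.DataFrame(rows))
    if have_labels:
        ds.labels = np.asarray(labels)
    return ds


def write_segments_csv(path, seg: pd.DataFrame) -> None:
    seg.to_csv(path, index=False)


def read_segments_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment CSV missing columns: {missing}")
    return df
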