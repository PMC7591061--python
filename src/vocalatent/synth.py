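"""Synthetic vocal repertoires with known ground truth.

Every downstream stage — denoising, segmentation, embedding, clustering,
syntax models — is validated against audio generated here, where syllable
categories, boundaries, the Markov syntax and the signal-to-noise ratio are
all known by construction.

A repertoire is a set of bouts.  Each bout is a sequence of syllables drawn
from K parametric spectrotemporal categories (pure tones, linear chirps,
harmonic stacks, noise bursts), sequenced by a first-order Markov chain and
separated by silent gaps, with stationary white Gaussian noise added at a
controlled SNR.  Categories are kept separable by requiring template
parameters to differ by more than their jitter half-widths.

Reproducibility: one master seed; every bout and the noise stream use
deterministically derived substreams, so identical specs give bit-identical
audio regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import Waveform, write_wav

_KINDS = ("pure_tone", "linear_chirp", "harmonic_stack", "noise_burst")


class UnsupportedTemplateError(ValueError):
    pass


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyllableTemplate:
    category_id: str
    kind: str = "pure_tone"
    f0_hz: float = 2000.0
    f0_jitter_hz: float = 0.0
    chirp_slope_hz_per_s: float = 0.0
    n_harmonics: int = 1
    duration_s: float = 0.1
    duration_jitter_s: float = 0.0
    amplitude: float = 0.8

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise UnsupportedTemplateError(f"unknown syllable kind {self.kind!r}")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    def max_frequency_hz(self) -> float:
        f = self.f0_hz + self.f0_jitter_hz
        if self.kind == "linear_chirp":
            dur = self.duration_s + self.duration_jitter_s
            f = max(f, f + self.chirp_slope_hz_per_s * dur)
        if self.kind == "harmonic_stack":
            f *= self.n_harmonics
        return f


def _templates_separable(a: SyllableTemplate, b: SyllableTemplate) -> bool:
    if a.kind != b.kind:
        return True
    jitter_f = a.f0_jitter_hz + b.f0_jitter_hz
    if abs(a.f0_hz - b.f0_hz) > jitter_f:
        return True
    if abs(a.chirp_slope_hz_per_s - b.chirp_slope_hz_per_s) > 0:
        return True
    jitter_d = a.duration_jitter_s + b.duration_jitter_s
    if abs(a.duration_s - b.duration_s) > jitter_d:
        return True
    return False


@dataclass(frozen=True)
class SyntheticSpec:
    templates: tuple
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    n_syllables_per_bout: int = 8
    n_bouts: int = 20
    gap_s: float = 0.2
    gap_jitter_s: float = 0.05
    sample_rate_hz: float = 22050.0
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self):
        templates = tuple(self.templates)
        object.__setattr__(self, "templates", templates)
        k = len(templates)
        if k == 0:
            raise InvalidSpecError("need at least one template")
        tm = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.initial_distribution, dtype=float)
        if tm.shape != (k, k):
            raise InvalidSpecError(f"transition matrix must be {k}x{k}")
        if np.any(tm.sum(axis=1) == 0):
            raise InvalidSpecError("transition matrix has an all-zero row")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidSpecError("transition rows must sum to 1")
        if pi.shape != (k,) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise InvalidSpecError("initial distribution must be a length-K stochastic vector")
        if self.gap_s <= 0:
            raise InvalidSpecError("gap_s must be positive")
        if self.gap_jitter_s >= self.gap_s:
            raise InvalidSpecError("gap_jitter_s must be smaller than gap_s")
        fmax = max(t.max_frequency_hz() for t in templates)
        if self.sample_rate_hz < 4 * fmax:
            raise InvalidSpecError(
                f"sample rate {self.sample_rate_hz} < 4x max rendered frequency {fmax}"
            )
        for i, a in enumerate(templates):
            for b in templates[i + 1:]:
                if not _templates_separable(a, b):
                    raise InvalidSpecError(
                        f"templates {a.category_id!r} and {b.category_id!r} are not "
                        "separable beyond their jitter"
                    )
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "initial_distribution", pi)


@dataclass
class GroundTruth:
    """Per-bout segment tables and label sequences plus the true syntax."""

    segments: list  # list of DataFrame(bout_id, onset_s, offset_s, label)
    labels: list    # list of list of category_id
    true_transition_matrix: np.ndarray
    true_initial: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        if not self.segments:
            return pd.DataFrame(columns=["bout_id", "onset_s", "offset_s", "label"])
        return pd.concat(self.segments, ignore_index=True)


def _ramp(n_ramp: int, n_total: int) -> np.ndarray:
    n_ramp = min(n_ramp, n_total // 2)
    env = np.ones(n_total)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def render_syllable(template: SyllableTemplate, rng: np.random.Generator,
                    sample_rate_hz: float = 22050.0) -> Waveform:
    """Render one jittered instance of a syllable template.

    All kinds get >= 5 ms raised-cosine on/off amplitude ramps to avoid
    clicks at segment boundaries.
    """
    dur = template.duration_s
    if template.duration_jitter_s > 0:
        dur += rng.uniform(-template.duration_jitter_s, template.duration_jitter_s)
    dur = max(dur, 0.005)
    f0 = template.f0_hz
    if template.f0_jitter_hz > 0:
        f0 += rng.uniform(-template.f0_jitter_hz, template.f0_jitter_hz)
    n = max(1, int(round(dur * sample_rate_hz)))
    t = np.arange(n) / sample_rate_hz
    phase = rng.uniform(0, 2 * np.pi)

    if template.kind == "pure_tone":
        x = np.sin(2 * np.pi * f0 * t + phase)
    elif template.kind == "linear_chirp":
        inst_phase = 2 * np.pi * (f0 * t + 0.5 * template.chirp_slope_hz_per_s * t ** 2)
        x = np.sin(inst_phase + phase)
    elif template.kind == "harmonic_stack":
        # 1/k rolloff gives monotonically decreasing harmonic magnitudes
        x = np.zeros(n)
        for k in range(1, template.n_harmonics + 1):
            x += np.sin(2 * np.pi * k * f0 * t + phase * k) / k
        x /= np.abs(x).max()
    elif template.kind == "noise_burst":
        x = rng.standard_normal(n)
        x /= max(np.abs(x).max(), 1e-12)
    else:  # pragma: no cover - guarded in the dataclass
        raise UnsupportedTemplateError(template.kind)

    ramp_samples = int(round(0.005 * sample_rate_hz))
    x = x * _ramp(ramp_samples, n) * template.amplitude
    return Waveform(x, sample_rate_hz)


def _sample_chain(tm: np.ndarray, pi: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(pi), p=pi)
    for i in range(1, n):
        states[i] = rng.choice(tm.shape[0], p=tm[states[i - 1]])
    return states


def _bout_rng(seed: int, bout: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(bout,)))


def _noise_rng(seed: int) -> np.random.Generator:
    # dedicated substream, shared by bout noise and generate_noise_clip
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10 ** 6,)))


def generate_repertoire(spec: SyntheticSpec) -> tuple[list[Waveform], GroundTruth]:
    """Generate one waveform per bout plus exact ground truth.

    Noise is white Gaussian, calibrated so that
    10*log10(clean power over vocal segments / noise power) == snr_db.
    ``snr_db=inf`` disables noise entirely.
    """
    sr = spec.sample_rate_hz
    waveforms, seg_tables, label_seqs = [], [], []
    noise_rng = _noise_rng(spec.seed)
    names = [t.category_id for t in spec.templates]

    for b in range(spec.n_bouts):
        rng = _bout_rng(spec.seed, b)
        states = _sample_chain(spec.transition_matrix, spec.initial_distribution,
                               spec.n_syllables_per_bout, rng)
        pieces, onsets, offsets = [], [], []
        cursor = 0
        lead = spec.gap_s + (rng.uniform(-spec.gap_jitter_s, spec.gap_jitter_s)
                             if spec.gap_jitter_s > 0 else 0.0)
        pieces.append(np.zeros(int(round(lead * sr))))
        cursor += len(pieces[-1])
        for i, s in enumerate(states):
            syl = render_syllable(spec.templates[s], rng, sr)
            onsets.append(cursor / sr)
            offsets.append((cursor + len(syl)) / sr)
            pieces.append(syl.samples)
            cursor += len(syl)
            gap = spec.gap_s + (rng.uniform(-spec.gap_jitter_s, spec.gap_jitter_s)
                                if spec.gap_jitter_s > 0 else 0.0)
            pieces.append(np.zeros(int(round(gap * sr))))
            cursor += len(pieces[-1])
        x = np.concatenate(pieces)

        if np.isfinite(spec.snr_db):
            seg_mask = np.zeros(len(x), dtype=bool)
            for on, off in zip(onsets, offsets):
                seg_mask[int(round(on * sr)):int(round(off * sr))] = True
            p_signal = float(np.mean(np.square(x[seg_mask])))
            p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
            x = x + noise_rng.standard_normal(len(x)) * np.sqrt(p_noise)

        waveforms.append(Waveform(x, sr))
        seg_tables.append(pd.DataFrame({
            "bout_id": b,
            "onset_s": onsets,
            "offset_s": offsets,
            "label": [names[s] for s in states],
        }))
        label_seqs.append([names[s] for s in states])

    gt = GroundTruth(segments=seg_tables, labels=label_seqs,
                     true_transition_matrix=spec.transition_matrix.copy(),
                     true_initial=spec.initial_distribution.copy())
    return waveforms, gt


def generate_noise_clip(spec: SyntheticSpec, duration_s: float) -> Waveform:
    """A noise-only clip from the same stationary process as the repertoire noise.

    Uses the same seed-derived stream, so two calls with the same spec are
    identical; with snr_db=inf the clip is all zeros.  The noise amplitude is
    calibrated against the first bout's clean segment power, exactly as in
    generate_repertoire.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * spec.sample_rate_hz))
    if not np.isfinite(spec.snr_db):
        return Waveform(np.zeros(n), spec.sample_rate_hz)
    p_signal = _clean_segment_power(spec)
    p_noise = p_signal / 10.0 ** (spec.snr_db / 10.0)
    rng = _noise_rng(spec.seed)
    return Waveform(rng.standard_normal(n) * np.sqrt(p_noise), spec.sample_rate_hz)


def _clean_segment_power(spec: SyntheticSpec) -> float:
    rng = _bout_rng(spec.seed, 0)
    states = _sample_chain(spec.transition_matrix, spec.initial_distribution,
                           spec.n_syllables_per_bout, rng)
    # skip the leading-gap draw so the jitter stream matches generate_repertoire
    if spec.gap_jitter_s > 0:
        rng.uniform(-spec.gap_jitter_s, spec.gap_jitter_s)
    total, count = 0.0, 0
    for s in states:
        syl = render_syllable(spec.templates[s], rng, spec.sample_rate_hz)
        total += float(np.sum(np.square(syl.samples)))
        count += len(syl)
        if spec.gap_jitter_s > 0:
            rng.uniform(-spec.gap_jitter_s, spec.gap_jitter_s)
    return total / count


def measured_snr_db(bout: Waveform, gt_segments: pd.DataFrame,
                    noise_clip: Waveform) -> float:
    """Estimated segment SNR: (segment power - noise power) vs noise power.

    Subtracting the noise-clip power from the within-segment power of the
    mixture recovers an estimate of the clean signal power, the standard
    field estimate when only noisy recordings and a noise sample exist.
    """
    sr = bout.sample_rate_hz
    mask = np.zeros(len(bout), dtype=bool)
    for _, row in gt_segments.iterrows():
        mask[int(round(row.onset_s * sr)):int(round(row.offset_s * sr))] = True
    p_seg = float(np.mean(np.square(bout.samples[mask])))
    p_noise = float(np.mean(np.square(noise_clip.samples)))
    if p_noise == 0:
        return np.inf
    return 10.0 * np.log10(max(p_seg - p_noise, 1e-300) / p_noise)


def default_templates(k: int = 5) -> tuple[SyllableTemplate, ...]:
    """A separable bank of K <= 6 spectrotemporally distinct categories.

    Frequencies sit inside the default 500-8000 Hz analysis band; durations
    and frequencies carry mild jitter so within-category variation exists
    without breaking separability.
    """
    bank = (
        SyllableTemplate("A", "pure_tone", f0_hz=1500, f0_jitter_hz=60,
                         duration_s=0.09, duration_jitter_s=0.01),
        SyllableTemplate("B", "pure_tone", f0_hz=4200, f0_jitter_hz=80,
                         duration_s=0.12, duration_jitter_s=0.015),
        SyllableTemplate("C", "linear_chirp", f0_hz=2000, f0_jitter_hz=60,
                         chirp_slope_hz_per_s=12000, duration_s=0.15,
                         duration_jitter_s=0.015),
        SyllableTemplate("D", "harmonic_stack", f0_hz=900, f0_jitter_hz=40,
                         n_harmonics=4, duration_s=0.11, duration_jitter_s=0.01),
        SyllableTemplate("E", "linear_chirp", f0_hz=5200, f0_jitter_hz=80,
                         chirp_slope_hz_per_s=-15000, duration_s=0.08,
                         duration_jitter_s=0.01),
        SyllableTemplate("F", "noise_burst", f0_hz=3000, duration_s=0.06,
                         duration_jitter_s=0.008, amplitude=0.6),
    )
    if not 1 <= k <= len(bank):
        raise ValueError(f"k must be in [1, {len(bank)}]")
    return bank[:k]


def default_spec(k: int = 5, n_bouts: int = 20, n_syllables_per_bout: int = 8,
                 snr_db: float = 20.0, seed: int = 0,
                 transition_matrix: np.ndarray | None = None) -> SyntheticSpec:
    """Study-condition defaults: K separable categories, 200 ms gaps, 20 dB SNR."""
    templates = default_templates(k)
    if transition_matrix is None:
        # sticky-ish chain: structured but ergodic syntax
        tm = np.full((k, k), 1.0 / k) if k == 1 else (
            0.5 * np.eye(k) + 0.5 / (k - 1) * (1 - np.eye(k)))
    else:
        tm = np.asarray(transition_matrix, dtype=float)
    pi = np.full(k, 1.0 / k)
    return SyntheticSpec(templates=templates, transition_matrix=tm,
                         initial_distribution=pi, n_bouts=n_bouts,
                         n_syllables_per_bout=n_syllables_per_bout,
                         snr_db=snr_db, seed=seed)


def generate_subclass_corpus(n_classes: int = 3, n_bouts: int = 40,
                             bout_length: int = 25, seed: int = 0,
                             fidelity: float = 0.85,
                             ) -> tuple[list[list[str]], list[list[str]]]:
    """Label corpora whose true dynamics depend on hidden sub-classes.

    Returns (visible_bouts, subclass_bouts).  Each visible class c has two
    sub-classes with *different* successor classes by construction:
    sub-class (c, 0) moves to class c+1 with probability ``fidelity`` (else
    c+2), sub-class (c, 1) the reverse; the landing sub-class is (c + j)
    mod 2 of the target class, so the sub-class is itself a deterministic
    function of recent history.  The visible process is therefore a
    second-order Markov chain over classes: class-level (first-order)
    models provably miss structure that sub-class-aware models capture,
    regardless of seed.
    """
    if n_classes < 3:
        raise ValueError("need at least 3 classes for distinct successor classes")
    if not 0.5 < fidelity < 1:
        raise ValueError("fidelity must be in (0.5, 1)")
    s = 2 * n_classes
    tm = np.zeros((s, s))
    for c in range(n_classes):
        for j in (0, 1):
            src = 2 * c + j
            hi = (c + 1 + j) % n_classes     # preferred successor class
            lo = (c + 2 - j) % n_classes     # dispreferred successor class
            land = (c + j) % 2               # landing sub-class index
            tm[src, 2 * hi + land] = fidelity
            tm[src, 2 * lo + land] = 1.0 - fidelity
    pi = np.full(s, 1.0 / s)
    rng = np.random.default_rng(seed)
    visible, hidden = [], []
    for _ in range(n_bouts):
        states = _sample_chain(tm, pi, bout_length, rng)
        hidden.append([f"s{q}" for q in states])
        visible.append([f"c{q // 2}" for q in states])
    return visible, hidden


def write_repertoire(out_dir, waveforms: list[Waveform], gt: GroundTruth,
                     spec: SyntheticSpec) -> None:
    """Write per-bout WAVs, a ground-truth CSV, and a JSON spec echo."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b, w in enumerate(waveforms):
        write_wav(out / f"bout_{b:04d}.wav", w, dtype="float32")
    gt.as_frame().to_csv(out / "ground_truth.csv", index=False)
    echo = {
        "transition_matrix": gt.true_transition_matrix.tolist(),
        "initial_distribution": gt.true_initial.tolist(),
        "categories": [t.category_id for t in spec.templates],
        "sample_rate_hz": spec.sample_rate_hz,
        "snr_db": spec.snr_db,
        "seed": spec.seed,
        "n_bouts": spec.n_bouts,
        "n_syllables_per_bout": spec.n_syllables_per_bout,
    }
    (out / "spec.json").write_text(json.dumps(echo, indent=2))
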