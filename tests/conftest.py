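import numpy as np
import pytest

from vocalatent.audio import Waveform
from vocalatent.synth import default_spec, generate_repertoire


@pytest.fixture(scope="session")
def small_repertoire():
    """20 bouts x 8 syllables, 5 categories, 20 dB SNR, fixed seed."""
    spec = default_spec(k=5, n_bouts=20, n_syllables_per_bout=8,
                        snr_db=20.0, seed=3)
    waveforms, gt = generate_repertoire(spec)
    return spec, waveforms, gt


@pytest.fixture
def tone():
    """One-second 2 kHz tone at 22.05 kHz."""
    sr = 22050.0
    t = np.arange(int(sr)) / sr
    return Waveform(0.8 * np.sin(2 * np.pi * 2000.0 * t), sr)


def two_tone_bout(sr=22050.0, tone_s=0.1, gap_s=0.3, lead_s=0.25, f=2000.0,
                  snr_db=30.0, seed=0):
    """Two tones separated by silence, plus white noise at a given SNR."""
    rng = np.random.default_rng(seed)

    def ramped_tone(n):
        x = np.sin(2 * np.pi * f * np.arange(n) / sr)
        n_ramp = int(0.005 * sr)
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= r
        x[-n_ramp:] *= r[::-1]
        return x

    n_tone, n_gap, n_lead = (int(round(s * sr)) for s in (tone_s, gap_s, lead_s))
    x = np.concatenate([np.zeros(n_lead), ramped_tone(n_tone), np.zeros(n_gap),
                        ramped_tone(n_tone), np.zeros(n_lead)])
    truth = [(n_lead / sr, (n_lead + n_tone) / sr),
             ((n_lead + n_tone + n_gap) / sr, (n_lead + 2 * n_tone + n_gap) / sr)]
    if np.isfinite(snr_db):
        p_sig = 0.5
        x = x + rng.standard_normal(len(x)) * np.sqrt(p_sig / 10 ** (snr_db / 10))
    return Waveform(x, sr), truth
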