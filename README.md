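# vocalatent

Latent-space analysis of animal vocal repertoires.

Bioacousticians and computational ethologists studying how animals structure
their vocalizations — birdsong syllables, rodent ultrasonic calls, primate
call types — face the same chain of chores before any biology happens:
clean noisy field recordings, cut the sound stream into discrete vocal
units, turn each unit into a comparable numerical representation, ask
whether those representations fall into categories, and ask how the
categories are sequenced.  `vocalatent` implements that chain end to end,
without requiring hand labels at any stage, together with a synthetic
repertoire generator that makes every stage verifiable against known ground
truth.

## The method

1. **Spectral gating** removes stationary background noise.  From a
   noise-only clip *N*, the per-frequency mean μ_f and standard deviation
   σ_f of the log-magnitude STFT are estimated; STFT bins of the signal
   below μ_f + n·σ_f (default n = 1.5) are suppressed by a smoothed mask,
   and the masked spectrum is inverted with the noisy phase.

2. **Dynamic-threshold segmentation** finds syllables as regions of
   continuous vocalization between silent pauses.  The amplitude envelope
   of the normalized spectrogram *S* is

   μ_S(t) = (1/n) Σ_f S(t, f),  E(t) = √μ_S(t) · max_f S(t, f),

   and frames with E(t) above a threshold are vocal.  The threshold starts
   sensitive and is raised multiplicatively until the segmentation matches
   prior expectations (a minimum fraction of silence, no over-long vocal
   run); recordings that never comply are rejected as too low SNR.
   Boundaries are refined in the time domain to a short-window RMS
   crossing, giving millisecond accuracy.

3. **Uniform syllable spectrograms**: each syllable's mel spectrogram
   (32 bands) is resampled in time to a length proportional to
   ln(1 + d/d_ref) — so duration differences compress logarithmically —
   then zero-padded to a common length and flattened.

4. **Latent projection**: syllables are embedded with UMAP (PCA, t-SNE and
   MDS are also available), each time-frequency bin an independent
   dimension.  Continuous **trajectories** embed rolling windows over a
   bout spectrogram, one latent point per spectrogram frame; 2-D latent
   coordinates can be rendered as RGB colors for sequence visualization.

5. **Clustering and scores**: HDBSCAN with minimum cluster size 1% of the
   dataset (plus k-means and Gaussian-mixture baselines);
   the **Hopkins statistic** Σw_i^d / (Σu_i^d + Σw_i^d) for label-free
   clusterability (≈ 0 clustered, ≈ 0.5 uniform, reference points sampled
   uniformly over the data's convex hull); the **silhouette score**;
   **homogeneity / completeness / V-measure** between two labelings, with
   a 10,000-permutation chance level; Kruskal–Wallis comparison of
   silhouette coefficient groups.

6. **Vocal syntax**: labeled segment tables become corpora of symbol
   sequences; first-order Markov chains, fixed-hidden-state discrete HMMs
   (hidden states pinned to hand or cluster labels) and free Baum–Welch
   HMMs are fit and compared by AIC = 2k − 2 log L, with ΔAIC > 2 flagged
   decisive.

The synthetic generator renders bouts of parametric syllables (tones,
chirps, harmonic stacks, noise bursts) sequenced by a known Markov chain,
separated by silent gaps, at a calibrated SNR — so segmentation accuracy,
embedding quality, clustering recovery and syntax-model comparisons can all
be measured against construction-time truth.

## Worked example

```python
import numpy as np
from vocalatent import (default_spec, generate_repertoire, dynamic_threshold_segment,
                        syllable_dataset_from_bouts, embed_discrete, EmbeddingParams,
                        cluster_hdbscan, overlap, hopkins, silhouette, Corpus, fit_markov)

spec = default_spec(k=5, n_bouts=125, n_syllables_per_bout=8, snr_db=20.0, seed=5)
waveforms, truth = generate_repertoire(spec)

segments = [dynamic_threshold_segment(w, bout_id=b) for b, w in enumerate(waveforms)]
for seg, labels in zip(segments, truth.labels):
    if len(seg) == len(labels):
        seg["label"] = labels
dataset = syllable_dataset_from_bouts(waveforms, segments)
print(f"segmented {len(dataset)} syllables from {len(waveforms)} bouts")

embedding = embed_discrete(dataset, EmbeddingParams(seed=0))
clusters = cluster_hdbscan(embedding.Z)
print(f"HDBSCAN found {clusters.n_clusters} clusters "
      f"({int((clusters.labels == -1).sum())} noise points)")

print(f"Hopkins statistic of the embedding: "
      f"{hopkins(embedding.Z, m=500, seed=0).statistic:.4f}")
print(f"silhouette score (true labels):     "
      f"{silhouette(embedding.Z, dataset.labels).score:.3f}")
ov = overlap(dataset.labels, clusters.labels)
print(f"overlap with ground truth:          "
      f"h={ov.homogeneity:.3f} c={ov.completeness:.3f} V={ov.v_measure:.3f}")

corpus = Corpus.from_bouts([list(s.sort_values("onset_s")["label"]) for s in segments])
markov = fit_markov(corpus)
err = np.abs(markov.transition - truth.true_transition_matrix).max()
print(f"Markov transition matrix recovered to sup-norm {err:.3f}")
```

Output:

```
segmented 1000 syllables from 125 bouts
HDBSCAN found 5 clusters (0 noise points)
Hopkins statistic of the embedding: 0.0006
silhouette score (true labels):     0.814
overlap with ground truth:          h=1.000 c=1.000 V=1.000
Markov transition matrix recovered to sup-norm 0.062
```

Reading the numbers: all 1000 planted syllables are recovered by the
segmenter; HDBSCAN on the UMAP embedding finds exactly the 5 planted
categories, in perfect agreement with ground truth (V = 1); the Hopkins
statistic near 0 says the embedding is strongly clustered (0.5 would mean
uniform); and the syllable-to-syllable transition probabilities estimated
from the recovered labels match the generator's chain to ±0.06 (875
observed transitions — the error shrinks as ~1/√n).

A command-line interface mirrors the library
(`vocalatent synth | denoise | segment | project | cluster | metrics |
sequence | run`); see `vocalatent --help`.

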