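# Methods

This note records the models and procedures `vocalatent` implements, the
parameter choices that matter, the numerical decisions taken where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Signal path and conventions

All matrices are (time, frequency); flattening is time-major.  STFT frames
lie fully inside the signal (no padding), so a recording of *n* samples
yields 1 + ⌊(n − n_fft)/hop⌋ frames — framing arithmetic is exact and
tested.  Default analysis parameters: 22.05 kHz audio, n_fft = 512
(23 ms), hop = 128 samples (5.8 ms), Hann window, Butterworth band
500–8000 Hz.

Spectrograms are magnitude STFTs, optionally collapsed onto a 32-band
triangular mel filterbank (HTK mel scale, peak-normalized filters), log
scaled in dB relative to the recording's own maximum — absolute calibration
is unavailable for field recordings — floored at `db_floor`, and affinely
rescaled to [0, 1].  The floor doubles as a noise gate: anything quieter
than `db_floor` relative to the loudest bin becomes exactly 0.

## Spectral gating

The gate estimates per-frequency mean and standard deviation of the noise
clip's log-magnitude STFT, thresholds the signal at mean + n_std·σ
(n_std = 1.5 by default; the threshold lives in the log domain so the gate
is invariant to absolute scale), smooths the binary keep/suppress mask with
a normalized separable triangular kernel (default widths 4 frequency bins ×
4 time frames), and multiplies the signal magnitude by the mask, keeping
the noisy phase at inversion.

One rule required care.  Smoothing alone multiplies an isolated
single-bin keep-decision by the kernel's center weight (≈ 0.25), so a pure
tone loses most of its energy on every application — the gate would not be
idempotent and would erode narrowband signal.  The final mask is therefore
floored at the *confirmed* raw mask: a raw keep becomes a hard keep when at
least 4 of its 8 neighbors are also above threshold (sustained signal
always has such support; isolated noise exceedances usually do not), while
unconfirmed exceedances fall back to the smoothed value.  Measured on the
package's own invariants, this keeps all three properties at once: ≥ 10 dB
in-band SNR gain for a tone at 0 dB SNR, < 20% residual RMS on noise-only
input, and < 5% RMS change on re-application.

## Dynamic-threshold segmentation

Silence versus vocalization is a threshold on the envelope
E(t) = √μ_S(t) · max_f S(t, f) of the normalized spectrogram, rescaled to
peak 1 so thresholds are fractions of the recording's own maximum.  The
threshold schedule starts at 0.05 and multiplies by 1.5 until either the
segmentation satisfies the configured expectations — silent-frame fraction
≥ `min_silence_fraction` (default 0.4), longest vocal run ≤ `max_vocal_s`
(default 0.4 s), at least one segment — or it exceeds 0.5 and the recording
is rejected as too low SNR.  Runs separated by silences shorter than
`min_silence_s` (30 ms) are merged first; segments shorter than
`min_segment_s` (40 ms) are then dropped.

Two default choices matter and were validated empirically:

* **The segmentation envelope uses a linear-frequency spectrogram with a
  −30 dB floor**, independent of the mel parameters used for syllable
  features.  Wide mel bands sum dozens of FFT bins, which lifts the
  white-noise envelope to ~0.2 of maximum at 20 dB SNR and produces
  spurious segments; per-linear-bin noise sits near −42 dB and is zeroed
  by the −30 dB floor, leaving a crisp envelope.

* **Boundaries are refined in the time domain.**  An STFT frame responds as
  soon as its window overlaps a syllable, so run edges over-cover the
  syllable by up to a window length; reporting onsets at the window end
  (offsets at the window start) of the interpolated threshold crossing
  cancels most of that, but the Hann taper still biases both edges
  symmetrically by ~5 ms (the bias scales with n_fft, not with the
  signal).  Each boundary is therefore snapped, within one window of the
  coarse estimate, to the edge of the region where a 1.5 ms moving RMS
  exceeds 25% of the segment's own 90th-percentile RMS.  Boundary error on
  synthetic bouts drops to ≈ 1.5 ms — a quarter of a hop.

Intervals are half-open [onset, offset) in seconds; extraction maps them to
spectrogram columns ⌊onset/hop⌋ … ⌈offset/hop⌉, so abutting segments
partition columns without overlap.

## Log-time rescaling and padding

Syllable spectrograms are resampled in time to
L_i = T_pad · ln(1 + d_i/d_ref) / ln(1 + d_max/d_ref) frames (linear
interpolation; T_pad = 32, d_ref = 20 ms) and right-padded with zeros.
L_i is treated as **real-valued**: the frame straddling the cut boundary is
weighted by the fractional part, so the padded representation varies
continuously with duration.  Rounding L_i to an integer instead quantizes
jittered durations into discrete pad lengths, and the hard zero-pad edge
then fragments each true category into several embedding islands (measured
on the 5-category benchmark: 17 clusters and V = 0.78 with rounding versus
5 clusters and V = 1.0 with fractional weighting).  The integer-rounding
variant remains available (`fractional=False`).

d_ref is deliberately its own parameter rather than inherited from
`min_segment_s`: the two quantities answer different questions (how small a
unit to keep versus where the log-compression of duration begins), and
coupling them couples segmentation robustness to embedding geometry.

## Projections

Discrete syllables are embedded by UMAP (defaults: 15 neighbors, min_dist
0.1, 2 components, Euclidean, fixed seed), with PCA / t-SNE / MDS available
behind the same interface.  Continuous trajectories take rolling windows of
a fixed duration over a bout spectrogram, stepping one frame at a time; the
spectrogram is right-padded with w − 1 floor-valued frames so a trajectory
has exactly one point per spectrogram frame.  2-D coordinates map to RGB by
min–max normalizing each dimension into one color channel and holding the
third constant (0.5 for a zero-range dimension).

## Clusterability and overlap statistics

* **Hopkins**: statistic = Σw_i^d / (Σu_i^d + Σw_i^d), where w_i are
  nearest-neighbor distances within the data (self excluded, over an
  m-subsample drawn without replacement; m defaults to N) and u_i are
  distances from m reference points to the data.  Reference points are
  sampled uniformly over the convex hull of the data (rejection sampling
  inside a Delaunay triangulation) for d ≤ 3; for d > 3 the axis-aligned
  bounding box is used and the result is flagged.  The exponent d is the
  embedding dimensionality.  Under this convention ≈ 0 means clustered and
  ≈ 0.5 means uniform.  All-duplicate data (every w_i = 0) returns 0 with a
  degeneracy flag.  The internal random stream is derived from the seed
  through a spawn key so it can never replay a data generator that happens
  to share the same seed.
* **Silhouette**: a_i is the mean distance to own-cluster others, b_i the
  smallest mean distance to another cluster, s_i = (b_i − a_i)/max(a_i, b_i);
  the score is the mean s_i.  Points in singleton clusters get s_i = 0 by
  convention.  Euclidean distance throughout.
* **Homogeneity / completeness / V-measure**: computed from the joint
  contingency table with entropies in bits (the h, c, V ratios are
  base-invariant).  h = 1 when the class labeling carries no entropy; c = 1
  symmetrically; V = 0 when h + c = 0.  The permutation chance level
  shuffles the cluster labeling (default 10,000 times) and reports the mean
  null V and p = (1 + #{null ≥ observed})/(n_perm + 1).
* **Kruskal–Wallis** (tie-corrected) compares groups of silhouette
  coefficients; implementation delegated to scipy, with a hand rank-sum
  oracle in the tests.

Density-clustering noise points keep the label −1 and are retained in
overlap computations by default; `drop_noise` masks them out when the
analysis calls for it.

## Clustering parameterizations

HDBSCAN uses minimum cluster size max(2, round(0.01·N)) — 1% of the
dataset — and `allow_single_cluster=True`, since a dataset that genuinely
is one cluster must be reportable as such rather than split into children
of the condensed-tree root.  k-means runs at a user-supplied k with 10
seeded restarts; the Gaussian mixture uses full covariances and
expectation-maximization on small note-feature matrices (e.g. duration
plus start/end peak frequency).  PCA reduction to 100 dimensions (truncated
to available rank) is provided for clustering spectrograms directly.

## Syntax models and AIC

Corpora treat each bout as an independent symbol sequence; per-bout
log-likelihoods add.  The Markov fit uses pseudocount-smoothed transition
counts (γ = 0 by default for exactness; rows with no observations fall
back to uniform and are flagged).  Fixed-hidden-state HMMs pin the hidden
sequence to an aligned labeling and estimate transition, emission and
initial probabilities by maximum-likelihood counts; the reported
log-likelihood is then the *forward-algorithm* likelihood of the visible
corpus under the resulting model — the hidden labels are not conditioned on
at scoring time.  Baum–Welch fits delegate EM to hmmlearn's CategoricalHMM
(best of 10 seeded restarts by default, tol 1e-4), optionally adding one
run warm-started at a fixed fit's parameters; EM monotonicity then
guarantees the free model never scores below that fit.  Log-likelihoods of
every model source are recomputed with this package's own scaled forward
algorithm so AICs are mutually consistent.

AIC = 2k − 2 log L with k = S(S−1) + S(V−1) + (S−1) free stochastic
parameters for S hidden states and V visible symbols; ΔAIC > 2 relative to
the runner-up marks a decisive winner.  The parameter count is a
convention (model comparison only needs internal consistency) and is
documented here for that reason.

## The synthetic benchmark

`default_spec` defines the study conditions: K ≤ 6 spectrotemporally
separable categories (pure tones at 1.5/4.2 kHz, up/down chirps, a 4-
harmonic stack, a noise burst; durations 60–165 ms with ~10% jitter,
frequency jitter well inside category spacing), bouts of 8 syllables
sequenced by a sticky ergodic Markov chain, 200 ± 50 ms silent gaps, and
white Gaussian noise calibrated so that clean-segment power over noise
power equals the requested SNR (20 dB by default; SNR is verifiable to
±1 dB by subtracting noise power from noisy-segment power, the standard
field estimate).  One master seed drives per-bout substreams, so
generation is bit-reproducible and order-independent.  Syllables get 5 ms
raised-cosine ramps; sample rates are kept ≥ 4× the highest rendered
frequency.

`generate_subclass_corpus` builds label corpora whose true dynamics are
second-order: each visible class has two hidden sub-classes with distinct
successor classes by construction (fidelity 0.85), so class-level models
provably miss structure that sub-class-aware and free-hidden-state models
capture — for every seed, not just favorable draws.

**What passing these benchmarks shows — and does not.**  The generator
produces stationary white noise, non-overlapping vocalizations, stereotyped
category templates and first-order (or constructed second-order) syntax.
Real recordings bring non-stationary and colored noise, overlapping
vocalizers, graded categories, amplitude variation with distance, and
reverberation; success on the benchmark demonstrates the machinery is
implemented correctly and that the chain is recoverable under its own
assumptions, not that any particular species' repertoire will cluster this
cleanly.  Two observed behaviors carry over to real data: the 1% HDBSCAN
rule needs categories to be a substantial fraction (≳ 4–5%) of the dataset
or it fragments dense groups, and a category whose only within-class
variation is duration embeds as a thin filament that density clustering may
cut into pure segments (homogeneity stays 1.0 while completeness drops) —
at some generator seeds the end-to-end V-measure therefore lands near 0.85–0.9
rather than 1.0, with all error on the completeness side.

## Numerical details and degenerate inputs

Zero recordings produce all-zero spectrograms (the dB reference is the
recording maximum; a silent recording maps to 0 everywhere) and are
rejected by segmentation as low-SNR.  The envelope of an all-zero frame is
0.  Mask values are clipped to [0, 1] after smoothing.  The forward
algorithm scales α per step and sums log normalizers; impossible sequences
return −∞.  Segment CSVs round-trip bit-exactly (floats are written at
full precision and parsed with round-trip precision).  Stochastic stages
(UMAP, k-means, GMM, Baum–Welch) expose seeds and are reproducible for a
fixed library version; deterministic stages are bit-reproducible.

## Problem sizes used in the test and acceptance runs

Segmentation recovery: 40 bouts × 8 syllables at 20 dB SNR.  End-to-end
clustering: 125 bouts (1000 syllables), 5 categories.  Metric-oracle
equivalence: 1000 random instances per statistic at n ≤ 15.  Syntax-model
ordering: 20 corpus seeds × 40 bouts × 25 symbols, 6-state HMMs with 3
random EM restarts plus a warm start.  Parameter recovery: 2000 Markov
transitions; 5000 HMM symbols.  These sizes make the statistical
assertions stable while keeping a full run to a couple of minutes.
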