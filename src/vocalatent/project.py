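"""Latent projections of syllables and bout trajectories.

Discrete mode embeds uniformly sized syllable spectrograms (each
time-frequency bin an independent dimension) with UMAP, PCA, MDS or t-SNE.
Continuous mode embeds rolling windows over a bout spectrogram — a window of
a set duration steps one STFT frame at a time, so a trajectory has exactly
one point per spectrogram frame (the spectrogram is right-padded with
floor-valued frames to make that hold at the edge).

2-D embeddings can be rendered into RGB colorspace by assigning each latent
dimension to a color channel and holding the third channel constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import Spectrogram
from .segment import SyllableDataset

_METHODS = ("umap", "pca", "mds", "tsne")


@dataclass(frozen=True)
class EmbeddingParams:
    method: str = "umap"
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown embedding method {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.method == "umap" and self.n_neighbors < 2:
            raise ValueError("umap requires n_neighbors >= 2")


@dataclass
class Embedding:
    Z: np.ndarray
    params: EmbeddingParams


@dataclass
class Trajectory:
    Z: np.ndarray
    frame_times_s: np.ndarray
    window_s: float
    params: EmbeddingParams


def _embed_matrix(X: np.ndarray, p: EmbeddingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if p.method == "umap":
        if n < p.n_neighbors + 1:
            raise ValueError(
                f"umap with n_neighbors={p.n_neighbors} needs at least "
                f"{p.n_neighbors + 1} samples, got {n}"
            )
        import umap

        reducer = umap.UMAP(n_neighbors=p.n_neighbors, min_dist=p.min_dist,
                            n_components=p.n_components, metric=p.metric,
                            random_state=p.seed)
        return np.asarray(reducer.fit_transform(X), dtype=float)
    if p.method == "pca":
        from sklearn.decomposition import PCA

        k = min(p.n_components, n, X.shape[1])
        return PCA(n_components=k, random_state=p.seed).fit_transform(X)
    if p.method == "mds":
        from sklearn.manifold import MDS

        return MDS(n_components=p.n_components, random_state=p.seed,
                   normalized_stress="auto").fit_transform(X)
    if p.method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
        return TSNE(n_components=p.n_components, random_state=p.seed,
                    perplexity=perplexity, init="pca").fit_transform(X)
    raise AssertionError(p.method)


def embed_discrete(ds: SyllableDataset | np.ndarray,
                   p: EmbeddingParams | None = None) -> Embedding:
    """Embed syllable rows into the latent space; row i of Z aligns to row i of X."""
    if p is None:
        p = EmbeddingParams()
    X = ds.X if isinstance(ds, SyllableDataset) else np.asarray(ds)
    return Embedding(Z=_embed_matrix(X, p), params=p)


def rolling_windows(S: np.ndarray, w_frames: int, pad_value: float = 0.0) -> np.ndarray:
    """Rolling windows of w consecutive frames, step 1, flattened time-major.

    The input is right-padded with w-1 pad_value frames, so the output has
    exactly one row per input frame.
    """
    if w_frames < 1:
        raise ValueError("window must span at least one frame")
    T, F = S.shape
    if T < 1:
        raise ValueError("empty spectrogram")
    padded = np.concatenate([S, np.full((w_frames - 1, F), pad_value)], axis=0)
    idx = np.arange(w_frames)[None, :] + np.arange(T)[:, None]
    return padded[idx].reshape(T, w_frames * F)


def embed_continuous(spec: Spectrogram, window_s: float,
                     p: EmbeddingParams | None = None) -> Trajectory:
    """Rolling-window trajectory of a bout; one latent point per spectrogram frame."""
    if p is None:
        p = EmbeddingParams()
    hop_s = spec.params.hop_samples(spec.sample_rate_hz) / spec.sample_rate_hz
    w_frames = max(1, int(round(window_s / hop_s)))
    windows = rolling_windows(spec.S, w_frames, pad_value=0.0)
    Z = _embed_matrix(windows, p)
    return Trajectory(Z=Z, frame_times_s=spec.frame_times_s,
                      window_s=window_s, params=p)


def to_colorspace(Z: np.ndarray, held_channel_value: float = 0.5,
                  held_channel: int = 2) -> np.ndarray:
    """Map a 2-D embedding to RGB: each dimension min-max normalized into one
    channel, the remaining channel held constant.

    A dimension with zero range maps to 0.5 everywhere.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError("colorspace mapping requires an N x 2 embedding")
    if held_channel not in (0, 1, 2):
        raise ValueError("held_channel must be 0, 1 or 2")
    channels = [c for c in range(3) if c != held_channel]
    rgb = np.full((Z.shape[0], 3), float(held_channel_value))
    for dim, ch in enumerate(channels):
        col = Z[:, dim]
        rng = col.max() - col.min()
        rgb[:, ch] = 0.5 if rng == 0 else (col - col.min()) / rng
    return rgb
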