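"""Vocal-syntax models: Markov chains and discrete-emission HMMs with AIC.

A labeled segment table is abstracted into a corpus of symbol sequences (one
per bout).  Three model families are fit and compared on the likelihood of
the *visible* corpus:

* a first-order Markov chain over the visible symbols;
* fixed-hidden-state HMMs, where an aligned labeling (hand labels, or
  cluster labels) is treated as the hidden state sequence and all
  probabilities are maximum-likelihood counts; and
* Baum-Welch HMMs, where hidden states are free and learned by EM,
  so higher-order visible dependence can be absorbed into the states.

Models are compared by AIC = 2k - 2 log L, with the free-parameter count
k = S(S-1) + S(V-1) + (S-1) for S hidden states and V visible symbols.
Bouts are modeled as independent sequences; per-bout log-likelihoods add.
A difference in AIC greater than 2 is flagged as decisive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Corpus:
    bouts: list
    alphabet: tuple

    def __post_init__(self):
        if any(len(b) == 0 for b in self.bouts):
            raise ValueError("corpus contains an empty bout")
        alpha = set(self.alphabet)
        for b in self.bouts:
            unknown = set(b) - alpha
            if unknown:
                raise ValueError(f"symbols outside alphabet: {sorted(unknown)}")

    @classmethod
    def from_bouts(cls, bouts) -> "Corpus":
        bouts = [list(b) for b in bouts]
        alphabet = tuple(sorted({s for b in bouts for s in b}))
        return cls(bouts=bouts, alphabet=alphabet)

    @property
    def n_symbols(self) -> int:
        return sum(len(b) for b in self.bouts)

    def index_bouts(self) -> list:
        lookup = {s: i for i, s in enumerate(self.alphabet)}
        return [[lookup[s] for s in b] for b in self.bouts]


@dataclass
class MarkovModel:
    states: tuple
    transition: np.ndarray
    initial: np.ndarray
    pseudocount: float
    unobserved_rows: np.ndarray = field(default=None)  # rows that fell back to uniform


@dataclass
class HMMFit:
    hidden_states: tuple
    transition: np.ndarray
    emission: np.ndarray
    initial: np.ndarray
    log_likelihood: float
    n_params: int
    aic: float
    source: str                 # fixed_hand | fixed_cluster | baum_welch
    corpus_n_symbols: int
    corpus_alphabet: tuple
    converged: bool = True


@dataclass
class ModelComparison:
    aics: dict
    delta_aic: dict
    winner: str
    decisive: bool


def transcribe(seg: pd.DataFrame, bout_column: str = "bout_id") -> Corpus:
    """Labeled segment table -> corpus of per-bout label sequences.

    Rows are ordered by onset within each bout; bouts appear in order of
    their identifier's first appearance.
    """
    if len(seg) == 0:
        return Corpus(bouts=[], alphabet=())
    if seg["label"].isna().any():
        raise ValueError("all segments must be labeled before transcription")
    bouts = []
    for _, group in seg.groupby(bout_column, sort=False):
        bouts.append(list(group.sort_values("onset_s")["label"]))
    return Corpus.from_bouts(bouts)


def fit_markov(c: Corpus, pseudocount: float = 0.0) -> MarkovModel:
    """Maximum-likelihood first-order Markov chain with optional smoothing.

    transition[i, j] = (count(i -> j) + g) / (sum_j count(i -> j) + g * K);
    rows with no observed transitions (and g = 0) fall back to uniform and
    are flagged.  The initial distribution is estimated from bout-first
    symbols the same way.
    """
    if not c.bouts:
        raise ValueError("empty corpus")
    k = len(c.alphabet)
    counts = np.zeros((k, k))
    first = np.zeros(k)
    for b in c.index_bouts():
        first[b[0]] += 1
        for i, j in zip(b[:-1], b[1:]):
            counts[i, j] += 1
    counts_s = counts + pseudocount
    row_sums = counts_s.sum(axis=1)
    unobserved = row_sums == 0
    transition = np.where(unobserved[:, None], 1.0 / k,
                          counts_s / np.where(row_sums == 0, 1, row_sums)[:, None])
    first_s = first + pseudocount
    initial = (np.full(k, 1.0 / k) if first_s.sum() == 0
               else first_s / first_s.sum())
    return MarkovModel(states=c.alphabet, transition=transition, initial=initial,
                       pseudocount=pseudocount, unobserved_rows=unobserved)


def forward_log_likelihood(obs: list, initial: np.ndarray, transition: np.ndarray,
                           emission: np.ndarray) -> float:
    """Log-likelihood of one observation sequence under a discrete HMM.

    Scaled forward algorithm: alpha recursions normalized per step, with the
    log normalizers summed.  Returns -inf for an impossible sequence.
    """
    alpha = initial * emission[:, obs[0]]
    total = 0.0
    for t, o in enumerate(obs):
        if t > 0:
            alpha = (alpha @ transition) * emission[:, o]
        z = alpha.sum()
        if z == 0:
            return -np.inf
        total += np.log(z)
        alpha = alpha / z
    return total


def corpus_log_likelihood(c: Corpus, initial, transition, emission) -> float:
    return sum(forward_log_likelihood(b, initial, transition, emission)
               for b in c.index_bouts())


def hmm_n_params(n_hidden: int, n_visible: int) -> int:
    return n_hidden * (n_hidden - 1) + n_hidden * (n_visible - 1) + (n_hidden - 1)


def fit_hmm_fixed(c: Corpus, hidden, pseudocount: float = 0.0,
                  source: str = "fixed_hand") -> HMMFit:
    """HMM whose hidden state sequence is fixed to an aligned labeling.

    Transition, emission and initial probabilities are maximum-likelihood
    counts over the given (hidden, visible) pairs; the reported
    log-likelihood is the forward-algorithm likelihood of the visible corpus
    under the resulting model (the hidden labels are *not* conditioned on at
    scoring time).
    """
    hidden = [list(h) for h in hidden]
    if len(hidden) != len(c.bouts) or any(
            len(h) != len(b) for h, b in zip(hidden, c.bouts)):
        raise ValueError("hidden sequences must align 1:1 with visible bouts")
    states = tuple(sorted({s for h in hidden for s in h}))
    s_lookup = {s: i for i, s in enumerate(states)}
    v_lookup = {v: i for i, v in enumerate(c.alphabet)}
    S, V = len(states), len(c.alphabet)

    trans = np.full((S, S), pseudocount)
    emit = np.full((S, V), pseudocount)
    init = np.full(S, pseudocount)
    for h, b in zip(hidden, c.bouts):
        hs = [s_lookup[x] for x in h]
        vs = [v_lookup[x] for x in b]
        init[hs[0]] += 1
        for i, j in zip(hs[:-1], hs[1:]):
            trans[i, j] += 1
        for i, o in zip(hs, vs):
            emit[i, o] += 1

    trans = _normalize_rows(trans)
    emit = _normalize_rows(emit)
    init = init / init.sum() if init.sum() > 0 else np.full(S, 1.0 / S)

    logl = corpus_log_likelihood(c, init, trans, emit)
    k = hmm_n_params(S, V)
    return HMMFit(hidden_states=states, transition=trans, emission=emit,
                  initial=init, log_likelihood=logl, n_params=k,
                  aic=2.0 * k - 2.0 * logl, source=source,
                  corpus_n_symbols=c.n_symbols, corpus_alphabet=c.alphabet)


def _renorm(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def _renorm_rows(m: np.ndarray) -> np.ndarray:
    return m / m.sum(axis=1, keepdims=True)


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=1)
    out = np.where(sums[:, None] == 0, 1.0 / m.shape[1],
                   m / np.where(sums == 0, 1, sums)[:, None])
    return out


def fit_hmm_baumwelch(c: Corpus, n_states: int, seed: int = 0, tol: float = 1e-4,
                      max_iter: int = 500, n_init: int = 10,
                      warm_start: "HMMFit | None" = None) -> HMMFit:
    """Best-of-n_init Baum-Welch (EM) fit of a discrete-emission HMM.

    EM is delegated to hmmlearn's CategoricalHMM; the reported
    log-likelihood is recomputed with this module's forward algorithm on the
    fitted parameters, so AICs are consistent across model sources.

    ``warm_start`` adds one EM run initialized at an existing fit's
    parameters (e.g. a fixed-cluster-label model with the same state count)
    alongside the random restarts; since EM is monotone, the returned model
    then scores at least as well as the warm-start point.
    """
    from hmmlearn.hmm import CategoricalHMM

    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    idx_bouts = c.index_bouts()
    X = np.concatenate([np.asarray(b) for b in idx_bouts])[:, None]
    lengths = [len(b) for b in idx_bouts]
    V = len(c.alphabet)

    best = None
    for i in range(n_init + (warm_start is not None)):
        model = CategoricalHMM(n_components=n_states, n_features=V,
                               n_iter=max_iter, tol=tol,
                               random_state=np.random.default_rng([seed, i])
                               .integers(2 ** 31))
        if warm_start is not None and i == n_init:
            if len(warm_start.hidden_states) != n_states:
                raise ValueError("warm_start state count must match n_states")
            model.init_params = ""
            eps = 1e-6  # keep strictly positive for EM
            model.startprob_ = _renorm(warm_start.initial + eps)
            model.transmat_ = _renorm_rows(warm_start.transition + eps)
            model.emissionprob_ = _renorm_rows(warm_start.emission + eps)
        model.fit(X, lengths)
        score = model.score(X, lengths)
        if best is None or score > best[0]:
            best = (score, model)
    model = best[1]
    trans = np.asarray(model.transmat_)
    emit = np.asarray(model.emissionprob_)
    init = np.asarray(model.startprob_)
    logl = corpus_log_likelihood(c, init, trans, emit)
    k = hmm_n_params(n_states, V)
    states = tuple(f"h{i}" for i in range(n_states))
    return HMMFit(hidden_states=states, transition=trans, emission=emit,
                  initial=init, log_likelihood=logl, n_params=k,
                  aic=2.0 * k - 2.0 * logl, source="baum_welch",
                  corpus_n_symbols=c.n_symbols, corpus_alphabet=c.alphabet,
                  converged=bool(model.monitor_.converged))


def compare_models(fits: dict | list) -> ModelComparison:
    """Rank HMM fits of the same corpus by AIC; delta > 2 is decisive."""
    if isinstance(fits, list):
        fits = {f.source: f for f in fits}
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = next(iter(fits.values()))
    for f in fits.values():
        if (f.corpus_n_symbols != ref.corpus_n_symbols
                or f.corpus_alphabet != ref.corpus_alphabet):
            raise ValueError("fits were scored on different corpora")
    aics = {name: f.aic for name, f in fits.items()}
    best = min(aics.values())
    delta = {name: a - best for name, a in aics.items()}
    winner = min(aics, key=aics.get)
    runners = sorted(d for name, d in delta.items() if name != winner)
    decisive = bool(runners and runners[0] > 2.0)
    return ModelComparison(aics=aics, delta_aic=delta, winner=winner,
                           decisive=decisive)
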