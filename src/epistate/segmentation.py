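"""Methylation-aware chromatin-state segmentation.

Genome-wide histone-mark signal is summarised in fixed-width bins (200 bp by
default), a transformed DNA-methylation channel is appended as an extra
column, and a K-state hidden Markov model with overdispersed count emissions
is fitted by EM (Baum-Welch).  Decoding the fitted model yields a per-bin
chromatin-state track.

The emission family is a per-state *negative multinomial*: the per-bin total
count follows a negative binomial with state-specific mean and dispersion,
and is split across channels by state-specific proportions.  An
independent-Poisson-per-channel emission is selectable as a simpler
alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("epistate")

_PROB_FLOOR = 1e-300  # floor on scaled probabilities in the linear-space recursions
NEG_INF = float("-inf")  # sentinel for impossible observations


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeBins:
    """A gapless tiling of one chromosome by fixed-width bins.

    Coordinates are 0-based half-open internally; bin ``i`` spans
    ``[i * bin_size, (i + 1) * bin_size)``.
    """

    chrom: str
    n_bins: int
    bin_size: int = 200

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    @property
    def length(self) -> int:
        return self.n_bins * self.bin_size

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size


@dataclass
class TrackMatrix:
    """Per-bin mark counts plus an optional transformed methylation channel."""

    bins: GenomeBins
    marks: list[str]
    counts: np.ndarray  # (n_bins, M) nonnegative integers
    meth_channel: np.ndarray | None = None  # (n_bins,) nonnegative integers

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.bins.n_bins, len(self.marks)):
            raise ValueError("counts shape does not match bins/marks")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.meth_channel is not None:
            self.meth_channel = np.asarray(self.meth_channel)
            if self.meth_channel.shape != (self.bins.n_bins,):
                raise ValueError("meth_channel length must equal n_bins")

    @property
    def channel_names(self) -> list[str]:
        if self.meth_channel is None:
            return list(self.marks)
        return list(self.marks) + ["meth"]

    def data(self) -> np.ndarray:
        """Counts with the methylation channel appended as the last column."""
        if self.meth_channel is None:
            return np.asarray(self.counts, dtype=float)
        return np.column_stack([self.counts, self.meth_channel]).astype(float)


@dataclass
class SegmentationModel:
    """K-state HMM over binned count channels.

    ``means[k, c]`` is the expected count of channel ``c`` in state ``k``;
    ``dispersion[k]`` is the negative-binomial size of the per-bin total in
    state ``k`` (``inf`` marks the Poisson limit / Poisson emission mode).
    """

    pi: np.ndarray  # (K,)
    A: np.ndarray  # (K, K) row-stochastic
    means: np.ndarray  # (K, C)
    dispersion: np.ndarray  # (K,)
    emission: str = "negmultinom"  # or "poisson"
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("rows of A must sum to 1")
        if (self.means < 0).any():
            raise ValueError("emission means must be nonnegative")
        if (self.dispersion <= 0).any():
            raise ValueError("dispersion must be positive")
        if self.emission not in ("negmultinom", "poisson"):
            raise ValueError(f"unknown emission family {self.emission!r}")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]


@dataclass
class StateTrack:
    """Decoded per-bin chromatin states (1-based labels)."""

    bins: GenomeBins
    states: np.ndarray  # (n_bins,) ints in {1..K}
    posteriors: np.ndarray | None = None  # (n_bins, K)
    labels: dict[int, str] | None = None  # optional manual annotation map

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (self.bins.n_bins,):
            raise ValueError("states length must equal n_bins")
        if self.states.min() < 1:
            raise ValueError("states are 1-based")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if np.abs(self.posteriors.sum(axis=1) - 1.0).max() > 1e-8:
                raise ValueError("posterior rows must sum to 1")

    @property
    def K(self) -> int:
        if self.posteriors is not None:
            return self.posteriors.shape[1]
        return int(self.states.max())


# ---------------------------------------------------------------------------
# Binning and the methylation channel
# ---------------------------------------------------------------------------

def bin_signal(intervals, bins: GenomeBins) -> np.ndarray:
    """Count fragments per bin by their midpoint; average replicates.

    ``intervals`` is a pandas DataFrame with 0-based half-open ``start``/
    ``end`` columns and an optional ``replicate`` column.  Each fragment is
    assigned to exactly one bin: the bin containing its midpoint.  Replicate
    tracks are counted separately, averaged element-wise, and rounded half-up
    to integers.  Fragments whose midpoint falls outside the chromosome are
    skipped (a warning count is logged).
    """
    import pandas as pd

    if len(intervals) == 0:
        return np.zeros(bins.n_bins, dtype=np.int64)
    df = pd.DataFrame(intervals)
    if "chrom" in df.columns and (df["chrom"] != bins.chrom).any():
        raise ValueError("intervals contain chromosomes other than the bins'")
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    in_bounds = (mid >= 0) & (mid < bins.length)
    n_skipped = int((~in_bounds).sum())
    if n_skipped:
        logger.warning("bin_signal: skipped %d out-of-bounds fragments", n_skipped)
    bin_idx = (mid[in_bounds] // bins.bin_size).astype(np.int64)
    if "replicate" in df.columns:
        reps = df.loc[in_bounds, "replicate"].to_numpy()
        tracks = []
        for rep in pd.unique(reps):
            tracks.append(np.bincount(bin_idx[reps == rep], minlength=bins.n_bins))
        avg = np.mean(tracks, axis=0)
        return np.floor(avg + 0.5).astype(np.int64)  # round half-up
    return np.bincount(bin_idx, minlength=bins.n_bins).astype(np.int64)


def transform_methylation(cpg_table, bins: GenomeBins, window: int = 600,
                          shift: int = 200, scale: int = 10) -> np.ndarray:
    """Turn per-CpG %methylation into an inversely scaled per-bin channel.

    For each bin a ``window`` bp window centred on the bin (600 bp for 200 bp
    bins, i.e. bin +/- 200 bp) is scanned; the channel value is
    ``round(scale * (100 - median(%meth)) / 100)`` (half-up), so unmethylated
    accessible regions score high and the methylated background scores 0.
    Windows containing no CpG get 0, matching the fully methylated background.

    ``cpg_table`` is a DataFrame with 1-based ``pos`` and ``meth`` (percent)
    columns.  ``shift``, the step between consecutive windows, must equal the
    bin width so the channel has one value per bin.
    """
    import pandas as pd

    if shift != bins.bin_size:
        raise ValueError("window shift must equal the bin size")
    df = pd.DataFrame(cpg_table)
    meth = df["meth"].to_numpy(dtype=float)
    if len(meth) and (meth.min() < 0 or meth.max() > 100):
        raise ValueError("%methylation values must lie in [0, 100]")
    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
    order = np.argsort(pos0, kind="stable")
    pos0, meth = pos0[order], meth[order]

    ext = (window - bins.bin_size) // 2
    out = np.zeros(bins.n_bins, dtype=np.int64)
    starts = bins.starts() - ext
    ends = starts + window
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    for i in range(bins.n_bins):
        if hi[i] > lo[i]:
            med = float(np.median(meth[lo[i]:hi[i]]))
            out[i] = math.floor(scale * (100.0 - med) / 100.0 + 0.5)
    return out


# ---------------------------------------------------------------------------
# Emission log-probabilities
# ---------------------------------------------------------------------------

def _log_emissions(X: np.ndarray, means: np.ndarray, dispersion: np.ndarray,
                   emission: str) -> np.ndarray:
    """(n, K) log P(x_t | state k).

    Channels with mean exactly 0 contribute -inf when the observed count is
    positive (an impossible observation), and 0 otherwise.
    """
    n, C = X.shape
    K = means.shape[0]
    logB = np.zeros((n, K))
    totals = X.sum(axis=1)
    const = gammaln(X + 1.0).sum(axis=1)  # log prod x_c!
    for k in range(K):
        m = means[k]
        mu = m.sum()
        r = dispersion[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            if emission == "poisson" or np.isinf(r):
                # independent Poisson per channel
                logm = np.where(m > 0, np.log(np.maximum(m, _PROB_FLOOR)), NEG_INF)
                term = np.where((X > 0) & (m == 0), NEG_INF, X * np.where(m > 0, logm, 0.0))
                logB[:, k] = term.sum(axis=1) - mu - const
            else:
                denom = r + mu
                logq = np.where(m > 0, np.log(np.maximum(m, _PROB_FLOOR) / denom), NEG_INF)
                term = np.where((X > 0) & (m == 0), NEG_INF, X * np.where(m > 0, logq, 0.0))
                logB[:, k] = (gammaln(totals + r) - gammaln(r) - const
                              + r * np.log(r / denom) + term.sum(axis=1))
    return logB


def _scaled_forward_backward(pi, A, logB):
    """Rabiner-scaled forward-backward.

    Returns (loglik, gamma, xi_sum) where ``xi_sum[k, l]`` is the expected
    number of k->l transitions.  Returns ``loglik = -inf`` (and None, None)
    when some bin is impossible under every state.
    """
    n, K = logB.shape
    shifts = logB.max(axis=1)
    if not np.isfinite(shifts).all():
        return NEG_INF, None, None
    B = np.exp(logB - shifts[:, None])  # row max 1
    alpha = np.empty((n, K))
    c = np.empty(n)
    a = pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        return NEG_INF, None, None
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= _PROB_FLOOR:
            c[t] = _PROB_FLOOR
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shifts.sum())

    beta = np.empty((n, K))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = A * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    return loglik, gamma, xi_sum


def forward_loglik(model: SegmentationModel, track: TrackMatrix) -> float:
    """log P(track | model) by the scaled forward recursion.

    A bin that is impossible under every state yields the ``-inf`` sentinel.
    """
    X = track.data()
    if X.shape[1] != model.n_channels:
        raise ValueError("track channel count does not match the model")
    logB = _log_emissions(X, model.means, model.dispersion, model.emission)
    ll, _, _ = _scaled_forward_backward(model.pi, model.A, logB)
    return ll


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _optimize_dispersion(totals, weights, mu, r0):
    """M-step for the NB size r of the per-bin total: 1-D bounded maximisation
    of the expected complete-data log-likelihood (keeps EM monotone, which a
    moment-matching update would not guarantee)."""
    from scipy.optimize import minimize_scalar

    wsum = weights.sum()
    if wsum <= 0 or mu <= 0:
        return r0

    def nll(log_r):
        r = math.exp(log_r)
        return -float(np.sum(weights * (gammaln(totals + r) - gammaln(r)))
                      + wsum * r * math.log(r / (r + mu))
                      - np.sum(weights * totals) * math.log(r + mu))

    res = minimize_scalar(nll, bounds=(math.log(1e-3), math.log(1e8)),
                          method="bounded", options={"xatol": 1e-8})
    # keep the old value if the optimizer failed to improve
    return math.exp(res.x) if res.fun <= nll(math.log(r0)) + 1e-12 else r0


def _kmeans_init(X, K, seed):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=seed % (2**31 - 1))
    lab = km.fit_predict(np.log1p(X))
    means = np.zeros((K, X.shape[1]))
    for k in range(K):
        sel = lab == k
        means[k] = X[sel].mean(axis=0) if sel.any() else X.mean(axis=0)
    return means


def fit_hmm(track: TrackMatrix, K: int, max_iter: int = 100, tol: float = 1e-6,
            seed: int = 0, emission: str = "negmultinom",
            n_restarts: int = 3) -> SegmentationModel:
    """Fit a K-state HMM to the binned track by Baum-Welch EM.

    State means are seeded by k-means on log1p counts; ``n_restarts`` EM runs
    with different k-means seeds are performed and the best log-likelihood is
    kept.  The per-iteration log-likelihood is recorded in
    ``model.loglik_history`` and is non-decreasing up to numerical slack.
    Convergence is declared when the relative log-likelihood change falls
    below ``tol``.
    """
    X = track.data()
    n, C = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError("track must have at least K bins")

    if K == 1:
        means = X.mean(axis=0, keepdims=True)
        totals = X.sum(axis=1)
        mu = float(totals.mean())
        var = float(totals.var())
        r = mu * mu / (var - mu) if var > mu else np.inf
        if emission == "poisson":
            r = np.inf
        model = SegmentationModel(pi=np.ones(1), A=np.ones((1, 1)), means=means,
                                  dispersion=np.array([r if np.isfinite(r) and r > 0 else 1e6]),
                                  emission=emission)
        model.loglik_history = [forward_loglik(model, track)]
        return model

    if np.allclose(X, 0):
        logger.warning("fit_hmm: all-zero track; EM will converge to a degenerate model")

    best = None
    for restart in range(n_restarts):
        means = np.maximum(_kmeans_init(X, K, seed + restart), 1e-6)
        pi = np.full(K, 1.0 / K)
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9)
        dispersion = np.full(K, 2.0)
        if emission == "poisson":
            dispersion = np.full(K, np.inf)
        history: list[float] = []
        totals = X.sum(axis=1)
        prev = None
        for _ in range(max_iter):
            logB = _log_emissions(X, means, dispersion, emission)
            ll, gamma, xi_sum = _scaled_forward_backward(pi, A, logB)
            if not np.isfinite(ll):
                break
            if history and ll < history[-1] - 1e-6 * max(1.0, abs(history[-1])):
                logger.warning("fit_hmm: log-likelihood decreased (%.6g -> %.6g)",
                               history[-1], ll)
            history.append(ll)
            # M-step
            pi = gamma[0] / gamma[0].sum()
            A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), _PROB_FLOOR)
            w = gamma.sum(axis=0)
            means = (gamma.T @ X) / np.maximum(w[:, None], _PROB_FLOOR)
            if emission == "negmultinom":
                for k in range(K):
                    mu_k = float(means[k].sum())
                    dispersion[k] = _optimize_dispersion(totals, gamma[:, k], mu_k,
                                                         dispersion[k])
            if prev is not None and abs(ll - prev) <= tol * max(1.0, abs(prev)):
                break
            prev = ll
        if history:
            final = history[-1]
            if best is None or final > best.loglik_history[-1]:
                best = SegmentationModel(pi=pi, A=A, means=means,
                                         dispersion=dispersion.copy(),
                                         emission=emission)
                best.loglik_history = history
    if best is None:
        raise RuntimeError("EM failed on every restart (degenerate input?)")
    return best


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_states(model: SegmentationModel, track: TrackMatrix,
                  mode: str = "posterior") -> StateTrack:
    """Decode a per-bin state track.

    ``posterior`` (default) takes the per-bin argmax of the forward-backward
    marginals; ``viterbi`` returns the single most probable path.  Argmax
    ties break to the lowest state index.  Posterior marginals are stored in
    either mode.
    """
    X = track.data()
    if X.shape[1] != model.n_channels:
        raise ValueError("track channel count does not match the model")
    logB = _log_emissions(X, model.means, model.dispersion, model.emission)
    ll, gamma, _ = _scaled_forward_backward(model.pi, model.A, logB)
    if gamma is None:
        raise ValueError("track is impossible under the model")
    if mode == "posterior":
        states = gamma.argmax(axis=1) + 1
    elif mode == "viterbi":
        states = _viterbi(model.pi, model.A, logB) + 1
    else:
        raise ValueError(f"unknown decoding mode {mode!r}")
    return StateTrack(bins=track.bins, states=states, posteriors=gamma)


def _viterbi(pi, A, logB):
    n, K = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(pi, _PROB_FLOOR))
        logA = np.log(np.maximum(A, _PROB_FLOOR))
    delta = log_pi + logB[0]
    back = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)  # ties -> lowest predecessor index
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def emission_summary(model: SegmentationModel, channel_names,
                     label_map: dict[int, str] | None = None):
    """Per-state expected counts per channel as a DataFrame.

    States are rows (stable 1..K order) with an attached annotation label:
    a user-supplied map such as ``{1: "A", 2: "M", 3: "S"}`` or the default
    ``state_k``.  Grouping of states into named classes is a manual,
    emissions-guided call and is therefore left to the caller.
    """
    import pandas as pd

    names = list(channel_names)
    if len(names) != model.n_channels:
        raise ValueError("channel_names length does not match the model")
    label_map = label_map or {}
    unknown = set(label_map) - set(range(1, model.K + 1))
    if unknown:
        raise ValueError(f"label map references unknown states: {sorted(unknown)}")
    df = pd.DataFrame(model.means, columns=names,
                      index=pd.RangeIndex(1, model.K + 1, name="state"))
    df.insert(0, "label", [label_map.get(k, f"state_{k}") for k in df.index])
    return df
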