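"""Segmentation: binning, methylation transform, HMM fitting and decoding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multinomial, nbinom, poisson

import epistate as es
from epistate.segmentation import GenomeBins, SegmentationModel, TrackMatrix


def small_bins(n_bins=10, bin_size=200, chrom="chrS"):
    return GenomeBins(chrom=chrom, n_bins=n_bins, bin_size=bin_size)


# ---------------------------------------------------------------------------
# bin_signal
# ---------------------------------------------------------------------------

class TestBinSignal:
    def test_midpoint_rule(self):
        iv = pd.DataFrame({"start": [50], "end": [250]})  # midpoint 150 -> bin 0
        counts = es.bin_signal(iv, small_bins())
        assert counts[0] == 1 and counts.sum() == 1

    def test_empty_input(self):
        counts = es.bin_signal(pd.DataFrame({"start": [], "end": []}), small_bins())
        assert (counts == 0).all()

    def test_replicates_averaged_half_up(self):
        # replicate a: 2 fragments in bin 0; replicate b: 4 -> average 3
        iv = pd.DataFrame({
            "start": [0] * 2 + [0] * 4 + [210, 210, 210],
            "end": [100] * 2 + [100] * 4 + [290, 290, 290],
            "replicate": ["a"] * 2 + ["b"] * 4 + ["a", "a", "b"],
        })
        counts = es.bin_signal(iv, small_bins())
        assert counts[0] == 3
        assert counts[1] == 2  # (2 + 1)/2 = 1.5 rounds half-up to 2

    def test_out_of_bounds_skipped(self):
        iv = pd.DataFrame({"start": [0, 5000], "end": [100, 5100]})
        counts = es.bin_signal(iv, small_bins())
        assert counts.sum() == 1

    @given(st.lists(st.integers(min_value=0, max_value=1900), min_size=0,
                    max_size=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_total_count_conserved(self, starts):
        iv = pd.DataFrame({"start": starts, "end": [s + 80 for s in starts]})
        counts = es.bin_signal(iv, small_bins())
        assert counts.sum() == len(starts)


# ---------------------------------------------------------------------------
# transform_methylation
# ---------------------------------------------------------------------------

class TestTransformMethylation:
    def test_fully_methylated_gives_zero(self):
        cpg = pd.DataFrame({"pos": np.arange(1, 2000, 50), "meth": 100.0})
        assert (es.transform_methylation(cpg, small_bins()) == 0).all()

    def test_direct_formula(self):
        # three CpGs inside bin 2's window, median 40% -> round(10*0.6) = 6
        cpg = pd.DataFrame({"pos": [450, 500, 550], "meth": [20.0, 40.0, 60.0]})
        out = es.transform_methylation(cpg, small_bins())
        assert out[2] == 6

    def test_empty_window_is_zero(self):
        cpg = pd.DataFrame({"pos": [50], "meth": [0.0]})
        out = es.transform_methylation(cpg, small_bins())
        assert out[5] == 0  # no CpG anywhere near bin 5

    def test_meth_out_of_range_rejected(self):
        cpg = pd.DataFrame({"pos": [10], "meth": [101.0]})
        with pytest.raises(ValueError):
            es.transform_methylation(cpg, small_bins())

    def test_monotone_in_median_and_order_invariant(self, rng):
        bins = small_bins(n_bins=1)
        pos = rng.integers(1, 201, size=9)
        lo = pd.DataFrame({"pos": pos, "meth": rng.uniform(0, 40, 9)})
        hi = lo.assign(meth=lo.meth + 50)
        assert es.transform_methylation(lo, bins)[0] >= \
            es.transform_methylation(hi, bins)[0]
        shuffled = lo.sample(frac=1, random_state=1)
        assert es.transform_methylation(lo, bins)[0] == \
            es.transform_methylation(shuffled, bins)[0]


# ---------------------------------------------------------------------------
# HMM: oracles and fitting
# ---------------------------------------------------------------------------

def oracle_log_emission(x, means, r):
    """Independent negative-multinomial log pmf via scipy building blocks."""
    mu = means.sum()
    T = x.sum()
    if np.isinf(r):
        return poisson.logpmf(x, means).sum()
    lp_total = nbinom.logpmf(T, r, r / (r + mu))
    p = means / mu
    return lp_total + multinomial.logpmf(x, int(T), p)


def oracle_path_sum(model, X):
    """Brute-force log P(X) by enumerating every state path."""
    import itertools

    from scipy.special import logsumexp

    n = len(X)
    K = model.K
    terms = []
    for path in itertools.product(range(K), repeat=n):
        lp = math.log(model.pi[path[0]])
        lp += oracle_log_emission(X[0], model.means[path[0]],
                                  model.dispersion[path[0]])
        for t in range(1, n):
            lp += math.log(model.A[path[t - 1], path[t]])
            lp += oracle_log_emission(X[t], model.means[path[t]],
                                      model.dispersion[path[t]])
        terms.append(lp)
    return logsumexp(terms)


def oracle_best_path(model, X):
    import itertools

    n = len(X)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(model.K), repeat=n):
        lp = math.log(model.pi[path[0]])
        lp += oracle_log_emission(X[0], model.means[path[0]],
                                  model.dispersion[path[0]])
        for t in range(1, n):
            lp += math.log(model.A[path[t - 1], path[t]])
            lp += oracle_log_emission(X[t], model.means[path[t]],
                                      model.dispersion[path[t]])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best) + 1


def random_model(K, C, rng, emission="negmultinom"):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    means = rng.uniform(0.5, 20.0, size=(K, C))
    disp = rng.uniform(1.0, 10.0, size=K)
    return SegmentationModel(pi=pi, A=A, means=means, dispersion=disp,
                             emission=emission)


def make_track(X, bin_size=200):
    X = np.asarray(X)
    bins = GenomeBins(chrom="chrS", n_bins=X.shape[0], bin_size=bin_size)
    return TrackMatrix(bins=bins, marks=[f"m{i}" for i in range(X.shape[1])],
                       counts=X)


class TestForwardLoglik:
    def test_single_bin_closed_form(self, rng):
        model = random_model(2, 3, rng)
        X = rng.integers(0, 10, size=(1, 3))
        direct = np.logaddexp(
            math.log(model.pi[0]) + oracle_log_emission(X[0], model.means[0],
                                                        model.dispersion[0]),
            math.log(model.pi[1]) + oracle_log_emission(X[0], model.means[1],
                                                        model.dispersion[1]))
        assert es.forward_loglik(model, make_track(X)) == pytest.approx(direct,
                                                                       abs=1e-8)

    def test_matches_exhaustive_enumeration(self, rng):
        model = random_model(2, 2, rng)
        X = rng.integers(0, 8, size=(4, 2))
        assert es.forward_loglik(model, make_track(X)) == pytest.approx(
            oracle_path_sum(model, X), abs=1e-8)

    def test_impossible_bin_gives_neg_inf(self):
        model = SegmentationModel(pi=[1.0], A=[[1.0]], means=[[0.0]],
                                  dispersion=[2.0])
        X = np.array([[3]])  # count where every state's mean is 0
        assert es.forward_loglik(model, make_track(X)) == -np.inf

    def test_dimension_mismatch_rejected(self, rng):
        model = random_model(2, 3, rng)
        with pytest.raises(ValueError):
            es.forward_loglik(model, make_track(np.zeros((4, 2), dtype=int)))


class TestDecodeStates:
    def test_single_state(self):
        model = SegmentationModel(pi=[1.0], A=[[1.0]], means=[[2.0]],
                                  dispersion=[5.0])
        dec = es.decode_states(model, make_track(np.array([[1], [2], [3]])))
        assert (dec.states == 1).all()
        assert np.allclose(dec.posteriors, 1.0)

    def test_viterbi_matches_exhaustive(self, rng):
        for _ in range(5):
            model = random_model(3, 2, rng)
            X = rng.integers(0, 6, size=(5, 2))
            dec = es.decode_states(model, make_track(X), mode="viterbi")
            assert (dec.states == oracle_best_path(model, X)).all()

    def test_posterior_rows_normalized(self, rng):
        model = random_model(3, 2, rng)
        X = rng.integers(0, 10, size=(20, 2))
        dec = es.decode_states(model, make_track(X))
        assert np.abs(dec.posteriors.sum(axis=1) - 1).max() < 1e-8


class TestFitHMM:
    def test_k1_moment_match(self, rng):
        X = rng.integers(0, 12, size=(50, 3))
        model = es.fit_hmm(make_track(X), K=1)
        assert model.A.shape == (1, 1) and model.A[0, 0] == 1.0
        assert np.allclose(model.means[0], X.mean(axis=0))

    def test_loglik_nondecreasing(self, rng):
        X = rng.integers(0, 15, size=(200, 2))
        model = es.fit_hmm(make_track(X), K=2, max_iter=20, seed=4,
                           n_restarts=1)
        hist = np.array(model.loglik_history)
        assert (np.diff(hist) >= -1e-6 * np.abs(hist[:-1])).all()

    def test_poisson_emission_mode(self, rng):
        X = rng.poisson(5, size=(200, 2))
        model = es.fit_hmm(make_track(X), K=2, max_iter=10, seed=0,
                           emission="poisson", n_restarts=1)
        assert np.isinf(model.dispersion).all()

    def test_rejects_k_larger_than_track(self):
        with pytest.raises(ValueError):
            es.fit_hmm(make_track(np.zeros((2, 1), dtype=int)), K=5)


class TestEmissionSummary:
    def test_k1_column_means(self, rng):
        X = rng.integers(0, 9, size=(40, 2))
        model = es.fit_hmm(make_track(X), K=1)
        summ = es.emission_summary(model, ["a", "b"])
        assert np.allclose(summ[["a", "b"]].to_numpy()[0], X.mean(axis=0))
        assert summ["label"].iloc[0] == "state_1"

    def test_label_map_attached_and_validated(self, rng):
        model = random_model(3, 2, rng)
        summ = es.emission_summary(model, ["a", "b"], {1: "A", 2: "M"})
        assert list(summ["label"]) == ["A", "M", "state_3"]
        with pytest.raises(ValueError):
            es.emission_summary(model, ["a", "b"], {9: "X"})
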