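"""Binomial-emission three-state ancestry HMM and its Viterbi decoder."""

import numpy as np
import pytest
from scipy.stats import binom

from radancestry import (
    HET,
    MISSING,
    NAT,
    SRC,
    EmissionParams,
    ObservationTrack,
    TransitionModel,
    WindowGrid,
    build_track,
    decode_individual,
    emission_loglik,
    estimate_emission_params,
    forward_backward,
    viterbi,
)
from radancestry.hmm import _viterbi_logemit
from radancestry.pairdiv import PairWindowCounts, pair_key
from radancestry.errors import DivergenceError, InsufficientDataError

PARAMS = EmissionParams(p_src=0.0005, p_nat=0.0023)


def make_counts(pairs_kn, grid):
    """{(a, b): (k array, n array)} -> counts mapping on a 1-chrom grid."""
    out = {}
    for (a, b), (k, n) in pairs_kn.items():
        key = pair_key(a, b)
        out[key] = PairWindowCounts(
            key,
            {"chr1": np.asarray(k, dtype=np.int64)},
            {"chr1": np.asarray(n, dtype=np.int64)},
            grid,
        )
    return out


def enumerate_best(logemit, trans):
    """Exhaustive max over all 3^L paths (independent oracle)."""
    from itertools import product

    L = logemit.shape[0]
    with np.errstate(divide="ignore"):
        la = np.log(trans.matrix)
        li = np.log(trans.initial)
    best = -np.inf
    for path in product(range(3), repeat=L):
        ll = li[path[0]] + logemit[0, path[0]]
        for t in range(1, L):
            ll += la[path[t - 1], path[t]] + logemit[t, path[t]]
        best = max(best, ll)
    return best


class TestEmissionParams:
    def test_het_is_exact_mean(self):
        p = EmissionParams(p_src=0.0005, p_nat=0.0023)
        assert p.p_het == pytest.approx(0.0014, abs=0)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            EmissionParams(p_src=0.01, p_nat=0.001)

    def test_estimated_medians_recovered_exactly(self):
        grid = WindowGrid({"chr1": 300_000})
        n = [10_000, 10_000, 10_000]
        counts = make_counts(
            {
                ("p1", "p2"): ([4, 5, 6], n),  # rates 4e-4, 5e-4, 6e-4
                ("ref", "p1"): ([22, 23, 30], n),
                ("ref", "p2"): ([10, 23, 40], n),
            },
            grid,
        )
        params = estimate_emission_params(counts, "foc", ["p1", "p2"], ["ref"])
        assert params.p_src == pytest.approx(5e-4)
        assert params.p_nat == pytest.approx(23e-4)
        assert params.p_het == pytest.approx((5e-4 + 23e-4) / 2)

    def test_single_sample_panel_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_emission_params({}, "foc", ["p1"], ["ref"])

    def test_undiverged_populations_rejected(self):
        grid = WindowGrid({"chr1": 100_000})
        counts = make_counts(
            {
                ("p1", "p2"): ([5], [10_000]),
                ("ref", "p1"): ([5], [10_000]),
                ("ref", "p2"): ([5], [10_000]),
            },
            grid,
        )
        with pytest.raises(DivergenceError):
            estimate_emission_params(counts, "foc", ["p1", "p2"], ["ref"])


class TestEmission:
    def test_no_data_gives_certainty(self):
        assert np.allclose(emission_loglik(0, 0, PARAMS), 0.0)

    def test_matches_direct_binomial_pmf(self):
        ll = emission_loglik(2, 2000, PARAMS)
        for i, p in enumerate([0.0005, 0.0014, 0.0023]):
            assert ll[i] == pytest.approx(binom.logpmf(2, 2000, p), abs=1e-12)
        # k=2 sits between the SRC mean (1.0) and HET mean (2.8); the direct
        # pmf oracle puts HET on top, with SRC ahead of NAT
        assert np.argmax(ll) == HET
        assert ll[SRC] > ll[NAT]

    def test_argmax_sweeps_src_het_nat_without_reversal(self):
        n = 300
        order = [int(np.argmax(emission_loglik(k, n, PARAMS))) for k in range(n + 1)]
        assert order[0] == SRC and order[-1] == NAT
        assert np.all(np.diff(order) >= 0)

    @pytest.mark.parametrize("n", [0, 1, 7, 50, 200])
    def test_normalization(self, n):
        ll = emission_loglik(np.arange(n + 1), np.full(n + 1, n), PARAMS)
        if n == 0:
            return  # convention: no data -> log prob 0 for each state
        total = np.exp(ll).sum(axis=0)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            emission_loglik(5, 3, PARAMS)


class TestViterbi:
    def test_single_low_rate_window_decodes_src(self):
        track = ObservationTrack("chr1", np.array([0]), np.array([1000]),
                                 np.array([False]))
        path = viterbi(track, PARAMS, TransitionModel.symmetric())
        assert path.states[0] == SRC

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 9))
        n = rng.integers(0, 3000, size=L)
        k = rng.binomial(n, rng.choice([0.0005, 0.0014, 0.0023], size=L))
        track = ObservationTrack("chr1", k, n, n < 100)
        tau = float(rng.uniform(1e-4, 0.2))
        trans = TransitionModel.symmetric(tau)
        path = viterbi(track, PARAMS, trans)
        logemit = emission_loglik(k, n, PARAMS)
        logemit[track.missing] = 0.0
        assert path.loglik == pytest.approx(enumerate_best(logemit, trans), rel=1e-12)

    def test_missing_window_bridged_by_sticky_transitions(self):
        track = ObservationTrack(
            "chr1",
            np.array([0, 0, 0]),
            np.array([1000, 0, 1000]),
            np.array([False, True, False]),
        )
        trans = TransitionModel.symmetric(tau=0.001)
        path = viterbi(track, PARAMS, trans)
        assert path.states[0] == SRC and path.states[2] == SRC
        assert path.states[1] == MISSING
        logemit = emission_loglik(track.k, track.n, PARAMS)
        logemit[1] = 0.0
        assert path.loglik == pytest.approx(enumerate_best(logemit, trans))

    def test_scaling_invariance_of_log_emissions(self):
        rng = np.random.default_rng(5)
        logemit = rng.normal(size=(12, 3))
        trans = TransitionModel.symmetric(0.05)
        p1, _ = _viterbi_logemit(logemit, trans)
        shifted = logemit.copy()
        shifted[4] += 123.4  # constant per window cancels along every path
        p2, _ = _viterbi_logemit(shifted, trans)
        assert np.array_equal(p1, p2)

    def test_exact_ties_prefer_native_state(self):
        logemit = np.zeros((4, 3))
        trans = TransitionModel.symmetric(0.5)  # uniform everything
        path, _ = _viterbi_logemit(logemit, trans)
        assert np.all(path == NAT)

    def test_empty_chromosome_returns_empty_path(self):
        track = ObservationTrack("chr1", np.empty(0, int), np.empty(0, int),
                                 np.empty(0, bool))
        path = viterbi(track, PARAMS, TransitionModel.symmetric())
        assert len(path.states) == 0


class TestTrackAndDecode:
    def test_mean_aggregation_divides_summed_counts(self):
        grid = WindowGrid({"chr1": 200_000})
        counts = make_counts(
            {
                ("foc", "p1"): ([4, 8], [1000, 2000]),
                ("foc", "p2"): ([6, 0], [3000, 2000]),
            },
            grid,
        )
        t_sum = build_track(counts, "foc", ["p1", "p2"], "chr1", aggregate="sum")
        assert list(t_sum.k) == [10, 8] and list(t_sum.n) == [4000, 4000]
        t_mean = build_track(counts, "foc", ["p1", "p2"], "chr1")
        assert list(t_mean.k) == [5, 4] and list(t_mean.n) == [2000, 2000]
        t_one = build_track(counts, "foc", ["p1", "p2"], "chr1", max_panel=1)
        assert list(t_one.k) == [4, 8]

    def test_low_data_windows_flagged_missing(self):
        grid = WindowGrid({"chr1": 200_000})
        counts = make_counts({("foc", "p1"): ([0, 1], [50, 5000])}, grid)
        t = build_track(counts, "foc", ["p1"], "chr1", min_sites=100)
        assert t.missing.tolist() == [True, False]

    def test_chromosomes_decode_independently(self):
        rng = np.random.default_rng(3)
        grid = WindowGrid({"chr1": 500_000, "chr2": 500_000})
        kn = {}
        for pair in [("foc", "p1"), ("foc", "p2"), ("p1", "p2"), ("ref", "p1"), ("ref", "p2")]:
            key = pair_key(*pair)
            n = {c: rng.integers(1000, 5000, size=5) for c in ("chr1", "chr2")}
            p = 0.0005 if pair == ("p1", "p2") else 0.0023
            k = {c: rng.binomial(n[c], p) for c in n}
            kn[key] = PairWindowCounts(key, k, n, grid)
        paths = decode_individual(kn, "foc", ["p1", "p2"], ["ref"], grid)
        assert set(paths) == {"chr1", "chr2"}
        # decoding one chromosome alone gives the identical path
        grid1 = WindowGrid({"chr1": 500_000})
        kn1 = {
            key: PairWindowCounts(key, {"chr1": c.k["chr1"]}, {"chr1": c.n["chr1"]}, grid1)
            for key, c in kn.items()
        }
        solo = decode_individual(kn1, "foc", ["p1", "p2"], ["ref"], grid1)
        assert np.array_equal(paths["chr1"].states, solo["chr1"].states)


def test_posterior_probabilities_are_normalized_and_consistent():
    rng = np.random.default_rng(9)
    n = np.full(20, 8000)
    k = rng.binomial(n, 0.0023)
    k[5:10] = 0  # unambiguous donor-like stretch
    track = ObservationTrack("chr1", k, n, n < 100)
    post = forward_backward(track, PARAMS, TransitionModel.symmetric())
    assert post.shape == (20, 3)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
    assert post[7, SRC] > 0.9 and post[0, NAT] > 0.9
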