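"""Beta-binomial HMM: emission arithmetic, EM, Viterbi, segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom as scipy_betabinom

from nomepipe import hmm
from nomepipe.hmm import (
    BetaBinomialHMMParams, assemble_segments, beta_binomial_logpmf,
    chain_slices, default_init_params, fit_hmm, viterbi_decode,
)

from conftest import make_calls


class TestEmission:
    def test_empty_observation_has_log_probability_zero(self):
        assert beta_binomial_logpmf(0, 0, 1.0, 1.0) == pytest.approx(0.0)

    def test_uniform_case(self):
        # alpha = beta = 1 makes every count 0..n equally likely
        assert beta_binomial_logpmf(3, 10, 1.0, 1.0) == pytest.approx(np.log(1 / 11))

    def test_matches_scipy_and_brute_force_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b = rng.uniform(0.1, 20, 2)
            n = int(rng.integers(1, 51))
            k = np.arange(n + 1)
            lp = beta_binomial_logpmf(k, np.full(n + 1, n), a, b)
            assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(lp, scipy_betabinom.logpmf(k, n, a, b),
                                       rtol=1e-9, atol=1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            beta_binomial_logpmf(5, 3, 1.0, 1.0)
        with pytest.raises(ValueError):
            beta_binomial_logpmf(1, 3, -1.0, 1.0)


class TestParams:
    def test_identifiability_ordering_enforced(self):
        with pytest.raises(ValueError):
            BetaBinomialHMMParams(alpha=(6.0, 0.5), beta=(2.0, 9.5),
                                  transition=((0.9, 0.1), (0.1, 0.9)),
                                  initial=(0.5, 0.5))

    def test_row_stochastic_enforced(self):
        with pytest.raises(ValueError):
            BetaBinomialHMMParams(alpha=(0.5, 6.0), beta=(9.5, 2.0),
                                  transition=((0.9, 0.2), (0.1, 0.9)),
                                  initial=(0.5, 0.5))

    def test_yaml_dict_round_trip(self):
        p = default_init_params()
        assert BetaBinomialHMMParams.from_dict(p.to_dict()) == p


class TestChains:
    def test_split_on_gap_and_chromosome(self):
        calls = pd.concat([
            make_calls([0, 100, 900, 1000], [1] * 4, [10] * 4, chrom="chr1"),
            make_calls([0, 10], [1, 1], [10, 10], chrom="chr2"),
        ]).reset_index(drop=True)
        assert chain_slices(calls, max_gap=500) == [(0, 2), (2, 4), (4, 6)]


def _brute_force_viterbi(k, n, params):
    """Exhaustive max over all 2^T joint paths (oracle)."""
    import itertools

    la = np.log(np.asarray(params.transition))
    li = np.log(np.asarray(params.initial))
    e = np.stack([
        np.asarray(beta_binomial_logpmf(k, n, params.alpha[s], params.beta[s]))
        for s in (0, 1)
    ])
    best, best_score = None, -np.inf
    for path in itertools.product((0, 1), repeat=len(k)):
        score = li[path[0]] + e[path[0], 0]
        for t in range(1, len(k)):
            score += la[path[t - 1], path[t]] + e[path[t], t]
        # ties resolved toward protected: lexicographically smaller path wins
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and best is not None and path < best
        ):
            best, best_score = path, score
    return np.asarray(best)


class TestViterbi:
    def test_single_site_reduces_to_argmax(self):
        p = default_init_params()
        calls = make_calls([10], [28], [30])
        assert viterbi_decode(calls, p)[0] == hmm.ACCESSIBLE
        calls = make_calls([10], [0], [30])
        assert viterbi_decode(calls, p)[0] == hmm.PROTECTED

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            T = int(rng.integers(1, 11))
            a = tuple(rng.uniform(0.2, 8, 2))
            b = tuple(rng.uniform(0.2, 8, 2))
            if a[1] / (a[1] + b[1]) <= a[0] / (a[0] + b[0]):
                a, b = a[::-1], b[::-1]
            t0, t1 = rng.uniform(0.05, 0.95, 2)
            params = BetaBinomialHMMParams(
                alpha=a, beta=b,
                transition=((t0, 1 - t0), (1 - t1, t1)),
                initial=(0.5, 0.5),
            )
            n = rng.integers(1, 40, T)
            k = rng.binomial(n, rng.uniform(0, 1, T))
            calls = make_calls(np.arange(T) * 20, k, n)
            np.testing.assert_array_equal(
                viterbi_decode(calls, params), _brute_force_viterbi(k, n, params)
            )

    def test_tie_breaks_toward_protected(self):
        params = BetaBinomialHMMParams(
            alpha=(1.0, 2.0), beta=(2.0, 1.0),
            transition=((0.5, 0.5), (0.5, 0.5)), initial=(0.5, 0.5),
        )
        # n = 0 everywhere: emissions identical across states
        calls = make_calls(np.arange(6) * 10, [0] * 6, [0] * 6)
        assert (viterbi_decode(calls, params) == hmm.PROTECTED).all()

    def test_empty_input(self):
        assert viterbi_decode(make_calls([], [], []), default_init_params()).size == 0


class TestEM:
    def test_loglik_non_decreasing(self, fitted_series):
        _, _, _, fit = fitted_series
        ll = np.asarray(fit.loglik)
        assert np.all(np.diff(ll) >= -1e-6 * np.maximum(np.abs(ll[1:]), 1.0))

    def test_parameter_recovery(self, fitted_series):
        true, _, _, fit = fitted_series
        got, want = fit.params.emission_means, true.emission_means
        assert abs(got[0] - want[0]) < 0.03 and abs(got[1] - want[1]) < 0.03
        tr = np.asarray(fit.params.transition)
        assert abs(tr[0, 0] - 0.98) < 0.01 and abs(tr[1, 1] - 0.98) < 0.01

    def test_decoded_path_tracks_truth(self, fitted_series):
        _, calls, states, fit = fitted_series
        path = viterbi_decode(calls, fit.params)
        assert (path == states).mean() > 0.95

    def test_chain_order_irrelevant(self):
        p = default_init_params()
        calls, _ = hmm.sample_series(p, 600, seed=2)
        # two chroms whose sort order differs between the two labelings
        half = len(calls) // 2
        a = calls.copy()
        a.loc[: half - 1, "chrom"] = "chr1"
        a.loc[half:, "chrom"] = "chr2"
        b = calls.copy()
        b.loc[: half - 1, "chrom"] = "chr2"
        b.loc[half:, "chrom"] = "chr1"
        b = b.sort_values(["chrom", "pos"]).reset_index(drop=True)
        fa = fit_hmm(a, max_iter=10)
        fb = fit_hmm(b, max_iter=10)
        np.testing.assert_allclose(fa.params.alpha, fb.params.alpha, rtol=1e-8)
        np.testing.assert_allclose(fa.params.transition, fb.params.transition,
                                   rtol=1e-8)

    def test_depth_scaling_leaves_decoding_stable(self, fitted_series):
        _, calls, _, fit = fitted_series
        base = viterbi_decode(calls, fit.params)
        scaled = calls.assign(n_meth=calls["n_meth"] * 10,
                              n_total=calls["n_total"] * 10)
        assert (viterbi_decode(scaled, fit.params) == base).mean() >= 0.99

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(make_calls([1, 2], [0, 1], [5, 5]))

    def test_all_zero_coverage_warns(self):
        calls = make_calls(np.arange(150) * 20, [0] * 150, [0] * 150)
        with pytest.warns(UserWarning, match="zero coverage"):
            fit_hmm(calls)


def _path_calls(spec, spacing=20):
    """Build (path, calls) from a string like 'MMMAAAMMM'."""
    states = np.array([0 if c == "M" else 1 for c in spec], dtype=np.int8)
    k = np.where(states == 1, 27, 2)
    n = np.full(states.size, 30)
    return states, make_calls(np.arange(states.size) * spacing, k, n)


class TestSegments:
    def test_single_accessible_run(self):
        path, calls = _path_calls("AAAAA")
        seg = assemble_segments(path, calls)
        assert len(seg) == 1
        assert seg.iloc[0]["state"] == "MAR" and seg.iloc[0]["n_sites"] == 5
        # end covers the final dinucleotide
        assert seg.iloc[0]["end"] == calls["pos"].iloc[-1] + 2

    def test_three_runs_kept(self):
        path, calls = _path_calls("MMMAAAMMM")
        seg = assemble_segments(path, calls)
        assert list(seg["state"]) == ["MPR", "MAR", "MPR"]

    def test_short_interior_run_absorbed(self):
        path, calls = _path_calls("MMMAAMMM")
        seg = assemble_segments(path, calls)
        assert len(seg) == 1
        assert seg.iloc[0]["state"] == "MPR" and seg.iloc[0]["n_sites"] == 8
        # absorbed sites' counts pool into the host segment
        assert seg.iloc[0]["n_total"] == calls["n_total"].sum()

    def test_terminal_short_run_absorbed_into_only_neighbor(self):
        path, calls = _path_calls("AAMMMM")
        seg = assemble_segments(path, calls)
        assert len(seg) == 1 and seg.iloc[0]["state"] == "MPR"

    def test_chain_below_min_sites_yields_nothing(self):
        path, calls = _path_calls("AA")
        assert len(assemble_segments(path, calls)) == 0

    def test_partition_and_alternation(self):
        rng = np.random.default_rng(7)
        path = rng.integers(0, 2, 300).astype(np.int8)
        k = np.where(path == 1, 25, 1)
        calls = make_calls(np.arange(300) * 20, k, np.full(300, 30))
        seg = assemble_segments(path, calls, params=default_init_params())
        assert seg["n_sites"].sum() == 300  # partitions the chain
        assert (seg["n_sites"] >= 3).all()
        states = list(seg["state"])
        assert all(a != b for a, b in zip(states, states[1:]))  # alternation

    def test_mononucleosome_flag(self):
        # MPR of ~140 bp flanked by MARs on both sides
        path, calls = _path_calls("AAAMMMMAAA", spacing=40)
        seg = assemble_segments(path, calls)
        mpr = seg[seg["state"] == "MPR"]
        assert len(mpr) == 1
        length = int(mpr.iloc[0]["end"] - mpr.iloc[0]["start"])
        assert 100 <= length <= 200
        assert bool(mpr.iloc[0]["is_mononucleosome"])
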