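"""Z-scoring, anchor-aligned profiles, clustering, window summaries."""

import numpy as np
import pandas as pd
import pytest

from nomepipe import synthetic, tracks
from nomepipe.tracks import (
    BinnedTrack, ProfileMatrix, aggregate_profile, hcluster_rows,
    window_summarize, zscore_track,
)

from conftest import make_calls


class TestZscore:
    def test_two_point_standardization(self):
        t = BinnedTrack(bin_width=10, values={"c": np.array([0.0, 2.0, 0.0, 2.0])})
        np.testing.assert_allclose(zscore_track(t).values["c"], [-1, 1, -1, 1])

    def test_moments_after_transform(self):
        rng = np.random.default_rng(0)
        t = BinnedTrack(bin_width=10, values={
            "c1": rng.normal(3, 2, 500), "c2": rng.normal(5, 1, 300),
        })
        z = zscore_track(t).flat()
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_matches_two_pass_oracle_and_keeps_missing(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 3, 200)
        v[::7] = np.nan
        t = BinnedTrack(bin_width=10, values={"c": v})
        z = zscore_track(t).values["c"]
        covered = v[np.isfinite(v)]
        expect = (v - covered.mean()) / covered.std()
        np.testing.assert_allclose(z[np.isfinite(v)], expect[np.isfinite(v)])
        assert np.isnan(z[np.isnan(v)]).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore_track(BinnedTrack(bin_width=10, values={"c": np.ones(5)}))


class TestBedgraphBinning:
    def test_interval_length_weighted_means(self):
        df = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 5],
                           "end": [5, 20], "value": [2.0, 4.0]})
        t = BinnedTrack.from_bedgraph(df, bin_width=10)
        np.testing.assert_allclose(t.values["c"], [3.0, 4.0])

    def test_round_trip_through_bedgraph(self):
        t = BinnedTrack(bin_width=10, values={"c": np.array([1.0, np.nan, 2.0])})
        back = BinnedTrack.from_bedgraph(t.to_bedgraph(), bin_width=10)
        np.testing.assert_allclose(back.values["c"], [1.0, np.nan, 2.0])


class TestProfiles:
    def test_constant_level_fills_all_bins(self):
        calls = make_calls(np.arange(0, 2000, 10), np.full(200, 12),
                           np.full(200, 30), chrom="chrS")
        anchors = pd.DataFrame({"chrom": ["chrS"], "pos": [1000], "strand": ["+"]})
        pm = aggregate_profile(calls, anchors, flank=500, bin_width=10)
        np.testing.assert_allclose(pm.matrix[0], 0.4)

    def test_minus_strand_row_is_reversed(self):
        pos = np.arange(0, 2000, 10)
        level = (pos > 1000).astype(int) * 20
        calls = make_calls(pos, level, np.full(pos.size, 20), chrom="chrS")
        anchors = pd.DataFrame({"chrom": ["chrS", "chrS"], "pos": [1000, 1000],
                                "strand": ["+", "-"]})
        pm = aggregate_profile(calls, anchors, flank=500, bin_width=10)
        np.testing.assert_allclose(pm.matrix[1], pm.matrix[0][::-1])

    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(4000, 300, replace=False))
        total = rng.integers(5, 40, 300)
        calls = make_calls(pos, rng.binomial(total, 0.3), total, chrom="chrS")
        anchors = pd.DataFrame({"chrom": ["chrS"] * 3, "pos": [1500, 2000, 2500],
                                "strand": ["+", "-", "+"]})
        pm1 = aggregate_profile(calls, anchors, flank=1000, bin_width=10)
        flipped = anchors.assign(strand=anchors["strand"].map({"+": "-", "-": "+"}))
        pm2 = aggregate_profile(calls, flipped, flank=1000, bin_width=10)
        np.testing.assert_allclose(pm1.matrix, pm2.matrix[:, ::-1])

    def test_missing_chromosome_row_dropped_with_warning(self):
        calls = make_calls([100], [1], [10], chrom="chrS")
        anchors = pd.DataFrame({"chrom": ["chrX"], "pos": [100], "strand": ["+"]})
        with pytest.warns(UserWarning, match="absent"):
            pm = aggregate_profile(calls, anchors, flank=100, bin_width=10)
        assert np.isnan(pm.matrix).all()

    def test_ndr_metaplot_shows_central_peak_and_phased_flanks(self):
        """Anchored at NDR centers: maximal accessibility centrally, damped
        oscillation at the simulated repeat length in the flanks."""
        R = 190
        land = synthetic.scatter_ndr_landscape(2_000_000, 60, seed=3,
                                               repeat_length=R)
        calls = synthetic.sample_nome_calls(
            land, synthetic.SimulationConfig(seed=3))[0]
        centers = [(s + e) // 2 for s, e in land.truth_ndrs]
        anchors = pd.DataFrame({"chrom": "chrS", "pos": centers, "strand": "+"})
        pm = aggregate_profile(calls, anchors, flank=1000, bin_width=10)
        meta = pm.metaplot()
        x = pm.bin_centers
        central = np.abs(x) < 50
        assert np.nanmean(meta[central]) == pytest.approx(np.nanmax(meta), rel=0.05)
        # flank oscillation: peak spectral period near R
        flank = meta[(x > 150) & (x < 950)]
        flank = flank - np.nanmean(flank)
        ac = np.correlate(flank, flank, mode="full")[flank.size - 1:]
        lag_bins = np.arange(ac.size) * 10
        sel = (lag_bins >= 120) & (lag_bins <= 300)
        assert abs(lag_bins[sel][np.argmax(ac[sel])] - R) <= 20

    def test_aggregation_linearity(self):
        rng = np.random.default_rng(4)
        v1 = rng.normal(0, 1, 400)
        v2 = rng.normal(2, 1, 400)
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [2000], "strand": ["+"]})
        mats = []
        for v in (v1, v2, v1 + v2):
            t = BinnedTrack(bin_width=10, values={"c": v})
            mats.append(aggregate_profile(t, anchors, flank=1000, bin_width=10).matrix)
        np.testing.assert_allclose(mats[0] + mats[1], mats[2], atol=1e-9)


class TestClustering:
    def test_separated_blobs_split_perfectly(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (20, 30)), rng.normal(5, 0.1, (15, 30))])
        labels, order = hcluster_rows(X, k=2)
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]
        assert sorted(order) == list(range(35))

    def test_duplicated_rows_cluster_together(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, (10, 20))
        X = np.vstack([base, base[3]])
        labels, _ = hcluster_rows(X, k=3)
        assert labels[-1] == labels[3]

    def test_column_restriction_ignores_flank_differences(self):
        anchors = pd.DataFrame({"chrom": ["c"] * 6, "pos": [0] * 6,
                                "strand": ["+"] * 6})
        X = np.zeros((6, 100))
        X[:3, :20] = 9.0   # differences only outside the +/-250 bp core
        pm = ProfileMatrix(matrix=X, anchors=anchors, flank=500, bin_width=10)
        labels, _ = hcluster_rows(pm, k=2, window=(-250, 250))
        assert len(set(labels)) == 1 or (
            # all-core-identical rows must land in one cluster
            max(np.bincount(labels)[1:]) == 6
        )

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            hcluster_rows(np.ones((3, 5)), k=4)


class TestWindowSummaries:
    def test_constant_level_everywhere(self):
        pos = np.arange(0, 3_000_000, 5000)
        calls = make_calls(pos, np.full(pos.size, 6), np.full(pos.size, 30),
                           chrom="chrS")
        out = window_summarize(calls, None, None, {"chrS": 3_000_000})
        np.testing.assert_allclose(out["gch_level"], 0.2)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(2_000_000, 4000, replace=False))
        total = rng.integers(1, 50, 4000)
        calls = make_calls(pos, rng.binomial(total, 0.3), total, chrom="chrS")
        out = window_summarize(calls, None, None, {"chrS": 2_000_000},
                               window=500_000)
        for _, row in out.iterrows():
            sel = (pos >= row["start"]) & (pos < row["end"])
            expect = calls.loc[sel, "n_meth"].sum() / calls.loc[sel, "n_total"].sum()
            assert row["gch_level"] == pytest.approx(expect)

    def test_low_accessibility_domain_ranks_bottom(self):
        land = synthetic.build_landscape(
            8_000_000, [synthetic.DomainFeature(3_000_000, 6_000_000, 0.4)]
        )
        cfg = synthetic.SimulationConfig(seed=0, mean_gch_spacing=40)
        calls = synthetic.sample_nome_calls(land, cfg)[0]
        out = window_summarize(calls, None, None, {"chrS": 8_000_000})
        bottom = set(out.tail(3)["start"])
        assert bottom == {3_000_000, 4_000_000, 5_000_000}

    def test_cgi_bins_excluded_from_track_means(self):
        v = np.zeros(100)
        v[:10] = 50.0  # huge signal confined to a CGI
        t = BinnedTrack(bin_width=10, values={"c": v})
        cgi = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        out = window_summarize(None, None, {"chip": t}, {"c": 1000},
                               window=1000, cgi=cgi, rank_by="chip")
        assert out["chip"].iloc[0] == pytest.approx(0.0)
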