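"""Windowing, percentile merging, Fisher combination, resampling, final merge."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.io_formats import Region
from sweepscan.window_scan import (
    METHOD_FISHER, METHOD_PBS, METHOD_XPEHH, ScanConfig, fisher_combine,
    finalize_regions, make_windows, resample_significance, top_snps_xpehh,
    top_windows,
)


def track_of(n, seed=0, spacing=400):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "position": np.arange(1, n + 1) * spacing,
        "pbs": rng.normal(size=n),
        "xpehh": rng.normal(size=n),
    })


class TestMakeWindows:
    @pytest.mark.parametrize("n,expected", [(30, 3), (20, 1), (19, 0), (24, 1), (25, 2)])
    def test_window_count(self, n, expected):
        w = make_windows(track_of(n))
        assert len(w) == expected

    def test_window_indices_and_scores(self):
        track = track_of(30)
        w = make_windows(track)
        assert w["start_idx"].tolist() == [0, 5, 10]
        assert w["end_idx"].tolist() == [19, 24, 29]
        np.testing.assert_allclose(w["pbs_mean"].iloc[1],
                                   track["pbs"].iloc[5:25].mean())
        np.testing.assert_allclose(w["xpehh_max"].iloc[2],
                                   track["xpehh"].iloc[10:30].max())

    def test_missing_scores_excluded_before_indexing(self):
        track = track_of(25)
        track.loc[3, "pbs"] = np.nan
        w = make_windows(track)
        assert len(w) == 1  # 24 clean SNPs -> one window
        clean = track.dropna()
        np.testing.assert_allclose(w["pbs_mean"].iloc[0],
                                   clean["pbs"].iloc[:20].mean())

    def test_config_threshold_validation(self):
        with pytest.raises(ValueError, match="n_resamples"):
            ScanConfig(p_thresholds={METHOD_PBS: 1e-9},
                       n_resamples={METHOD_PBS: 100})


class TestTopWindows:
    def test_merge_gap_threshold(self):
        windows = pd.DataFrame({
            "start_bp": [1_000, 30_999, 200_000],
            "end_bp": [21_000, 50_000, 220_000],
            "pbs_mean": [5.0, 4.0, 3.0],
        })
        # force all retained: percentile 0 -> threshold = min
        cfg = ScanConfig(percentile=0.0)
        regions = top_windows(windows, "pbs_mean", cfg)
        # gap 30_999 - 21_000 = 9_999 <= 10 kb: first two merge
        assert [(r.start, r.end) for r in regions] == [(1_000, 50_000), (200_000, 220_000)]
        assert regions[0].score_dict()[METHOD_PBS] == 5.0
        windows.loc[1, "start_bp"] = 31_001  # gap 10_001 -> separate regions
        regions = top_windows(windows, "pbs_mean", cfg)
        assert len(regions) == 3

    def test_99th_percentile_keeps_top_ten_of_thousand(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(np.arange(1000, dtype=float))
        windows = pd.DataFrame({
            "start_bp": np.arange(1000) * 100_000,
            "end_bp": np.arange(1000) * 100_000 + 7_000,
            "pbs_mean": scores,
        })
        regions = top_windows(windows, "pbs_mean")
        assert len(regions) == 10  # far apart, never merge
        assert max(r.score_dict()[METHOD_PBS] for r in regions) == scores.max()
        # brute-force: every retained window score is in the top 1%
        kept = sorted(s for r in regions for m, s in r.scores)
        assert kept == sorted(scores)[-10:]


class TestTopSnps:
    def test_isolated_top_snp_yields_point_region(self):
        track = pd.DataFrame({"position": [10, 500_000, 1_000_000],
                              "score": [0.0, 0.1, 9.0]})
        cfg = ScanConfig(percentile=0.5)
        regions = top_snps_xpehh(track, cfg)
        assert (regions[-1].start, regions[-1].end) == (1_000_000, 1_000_000)

    def test_chain_merge_rule(self):
        track = pd.DataFrame({
            "position": [100, 9_000, 18_500, 900_000],
            "score": [5.0, 6.0, 7.0, -1.0],
        })
        cfg = ScanConfig(percentile=0.25)  # the three clustered SNPs are top
        regions = top_snps_xpehh(track, cfg)
        assert [(r.start, r.end) for r in regions][0] == (100, 18_500)

    def test_lower_tail_equals_upper_tail_of_negated_track(self):
        rng = np.random.default_rng(8)
        track = pd.DataFrame({"position": np.arange(1, 301) * 1_000,
                              "score": rng.normal(size=300)})
        lower = top_snps_xpehh(track, tail="lower")
        negated = track.assign(score=-track["score"])
        upper = top_snps_xpehh(negated, tail="upper")
        assert [(r.start, r.end) for r in lower] == [(r.start, r.end) for r in upper]


class TestFisherCombine:
    def test_rank_arithmetic(self):
        n = 1000
        pbs = np.arange(n, dtype=float)
        xp = np.arange(n, dtype=float)
        w = pd.DataFrame({"start_bp": np.arange(n), "end_bp": np.arange(n) + 1,
                          "pbs_mean": pbs, "xpehh_max": xp})
        out = fisher_combine(w)
        best = out["fisher"].iloc[-1]     # rank 1/1000 on both
        assert best == pytest.approx(6.0)
        worst = out["fisher"].iloc[0]     # rank 1.0 on both
        assert worst == pytest.approx(0.0)
        # median window: 500 of 1000 score >= it on both -> -2 log10(0.5)
        mid = out["fisher"].iloc[500]
        assert mid == pytest.approx(-2 * np.log10(0.5), abs=1e-9)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        w = pd.DataFrame({"start_bp": np.arange(50), "end_bp": np.arange(50) + 1,
                          "pbs_mean": rng.normal(size=50),
                          "xpehh_max": rng.normal(size=50)})
        a = fisher_combine(w)["fisher"]
        w2 = w.assign(pbs_mean=np.exp(w["pbs_mean"]),
                      xpehh_max=5 * w["xpehh_max"] ** 3)
        b = fisher_combine(w2)["fisher"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestResampleSignificance:
    def test_extremes(self):
        scores = np.arange(100, dtype=float)
        rng = np.random.default_rng(0)
        p_top = resample_significance(99.0, scores, 10_000, rng)
        # only the max itself matches: k ~ Binomial(M, 1/100)
        assert p_top == pytest.approx(0.01, abs=0.005)
        p_min = resample_significance(0.0, scores, 1_000, rng)
        assert p_min == 1.0
        strictly_above = resample_significance(99.5, scores, 1_000, rng)
        assert strictly_above == pytest.approx(1 / 1001)

    def test_converges_to_exact_exceedance(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=1_000)
        for q in (0.5, 1.2):
            exact = (scores >= q).mean()
            p = resample_significance(q, scores, 100_000, np.random.default_rng(9))
            assert abs(p - exact) < 0.01

    def test_requires_at_least_one_resample(self):
        with pytest.raises(ValueError):
            resample_significance(0.0, [1.0], 0, np.random.default_rng(0))


class TestFinalizeRegions:
    def _region(self, start, end, method, score, p=1e-9):
        return Region("chr1", start, end, frozenset({method}),
                      ((method, score),), p)

    def test_thirty_disjoint_inputs_stay_thirty(self):
        per_method = {}
        base = 1
        for m in (METHOD_PBS, METHOD_XPEHH, METHOD_FISHER):
            per_method[m] = [self._region(base + i * 2_000_000,
                                          base + i * 2_000_000 + 1_000, m, 10 - i)
                             for i in range(10)]
            base += 600_000  # interleaved but > 100 kb apart after flanks
        final = finalize_regions(per_method, ScanConfig())
        assert len(final) == 30

    def test_identical_region_from_all_methods_merges_once(self):
        per_method = {m: [self._region(1_000_000, 1_100_000, m, 1.0)]
                      for m in (METHOD_PBS, METHOD_XPEHH, METHOD_FISHER)}
        final = finalize_regions(per_method, ScanConfig())
        assert len(final) == 1
        assert final[0].methods == {METHOD_PBS, METHOD_XPEHH, METHOD_FISHER}
        assert (final[0].start, final[0].end) == (950_000, 1_150_000)

    def test_flanks_bridge_near_misses(self):
        per_method = {
            METHOD_PBS: [self._region(1_000_000, 1_100_000, METHOD_PBS, 1.0)],
            METHOD_XPEHH: [self._region(1_190_000, 1_300_000, METHOD_XPEHH, 2.0)],
        }
        final = finalize_regions(per_method, ScanConfig())
        # flanked: [950000, 1150000] and [1140000, 1350000] overlap -> one region
        assert len(final) == 1
        assert (final[0].start, final[0].end) == (950_000, 1_350_000)

    def test_p_threshold_filters(self):
        cfg = ScanConfig()
        per_method = {METHOD_PBS: [
            self._region(1, 10, METHOD_PBS, 5.0, p=1e-9),
            self._region(10_000_000, 10_000_010, METHOD_PBS, 4.0, p=0.5),
        ]}
        final = finalize_regions(per_method, cfg)
        assert len(final) == 1 and final[0].start == 1

    def test_idempotent_under_remerge(self):
        rng = np.random.default_rng(6)
        per_method = {METHOD_PBS: [
            self._region(int(s), int(s) + 5_000, METHOD_PBS, float(v))
            for s, v in zip(rng.integers(1, 5_000_000, 10), rng.normal(size=10))
        ]}
        once = finalize_regions(per_method, ScanConfig())
        again = finalize_regions(
            {METHOD_PBS: once}, ScanConfig(flank_bp=0))
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in once]
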