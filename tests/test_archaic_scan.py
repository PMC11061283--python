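"""Two-state Poisson HMM correctness and the aSNP/ancestry/cluster logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import sweepscan as sw
from sweepscan import archaic_scan, synthetic_data
from sweepscan.archaic_scan import (
    HmmConfig, _forward_backward_batch, assign_ancestry, cluster_haplotypes,
    detect_all_segments, detect_segments, filter_for_region, fit_poisson_hmm,
    private_window_counts, region_report,
)
from sweepscan.io_formats import HaplotypePanel, Region

ARCHAIC_COLS = ["AltaiNea", "VindijaNea", "ChagyrskayaNea", "Denisova"]


def brute_force_posterior(counts, rates, transmat, startprob):
    """Posterior P(state_t = j | data) by enumerating all 2^T state paths."""
    T = len(counts)
    post = np.zeros((T, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = startprob[path[0]] * poisson.pmf(counts[0], rates[path[0]])
        for t in range(1, T):
            p *= transmat[path[t - 1], path[t]] * poisson.pmf(counts[t], rates[path[t]])
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total, np.log(total)


class TestForwardBackward:
    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(0)
        T = 10
        counts = rng.poisson(0.5, size=T).astype(float)
        rates = np.array([0.1, 1.4])
        transmat = np.array([[0.9, 0.1], [0.3, 0.7]])
        startprob = np.array([0.8, 0.2])
        want_post, want_ll = brute_force_posterior(counts, rates, transmat, startprob)
        ll, post, _ = _forward_backward_batch(counts[None], rates[None],
                                              transmat[None], startprob[None])
        np.testing.assert_allclose(post[0], want_post, atol=1e-10)
        assert ll[0] == pytest.approx(want_ll, abs=1e-10)

    def test_numba_and_numpy_recursions_agree(self):
        rng = np.random.default_rng(1)
        H, T = 4, 60
        counts = rng.poisson(0.4, size=(H, T)).astype(float)
        rates = np.abs(rng.normal(1, 0.4, size=(H, 2))) + 0.05
        transmat = rng.dirichlet([6, 1], size=(H, 2))
        startprob = rng.dirichlet([1, 1], size=H)
        a = _forward_backward_batch(counts, rates, transmat, startprob, use_numba=False)
        b = _forward_backward_batch(counts, rates, transmat, startprob, use_numba=True)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x, y, atol=1e-10)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.5, size=(3, 200)).astype(float)
        _, post, _ = _forward_backward_batch(
            counts, np.tile([0.1, 1.0], (3, 1)),
            np.tile([[0.99, 0.01], [0.05, 0.95]], (3, 1, 1)),
            np.tile([0.9, 0.1], (3, 1)))
        np.testing.assert_allclose(post.sum(axis=2), 1.0, atol=1e-12)


def _panel_with_tract(seed=17):
    cfg = sw.SimConfig(seed=seed)
    panel, truth = sw.simulate_panel(cfg)
    sources = (synthetic_data.ArchaicSourceSpec(ancestry="Neanderthal", anchor=400_000),
               synthetic_data.ArchaicSourceSpec(ancestry="Denisova", anchor=1_100_000))
    panel, truth, arch = synthetic_data.inject_archaic(
        panel, truth, sources, rng=np.random.default_rng(seed))
    return cfg, panel, truth, arch


class TestDetectSegments:
    def test_zero_private_variants_gives_no_segments(self):
        H = np.zeros((6, 50), dtype=np.int8)
        H[4:, :] = 1  # outgroup carries everything the others carry
        panel = HaplotypePanel(chrom="chr1", positions=np.arange(1, 51) * 100,
                               H=H, sample_ids=["a", "b", "c"],
                               populations=["TGT", "TGT", "OUT"])
        assert detect_segments(panel, 0, "OUT") == []

    def test_degenerate_fit_warns_and_returns_nothing(self):
        # private variants spread evenly: one emission rate fits everything
        pos = np.arange(1, 401) * 150
        H = np.zeros((4, 400), dtype=np.int8)
        H[0] = 1
        panel = HaplotypePanel(chrom="chr1", positions=pos, H=H,
                               sample_ids=["a", "b"], populations=["TGT", "OUT"])
        with pytest.warns(UserWarning, match="degenerate"):
            segs = detect_segments(panel, 0, "OUT")
        assert segs == []

    def test_recovers_injected_tract(self):
        cfg, panel, truth, _ = _panel_with_tract()
        segments = detect_all_segments(panel, "TGT", "OUT", chrom_length=cfg.L)
        by_row = {}
        for s in segments:
            by_row.setdefault(s.hap_row, []).append(s)
        overlaps = []
        for row, a, b, _ in truth.tracts:
            covered = sum(max(0, min(b, s.end) - max(a, s.start) + 1)
                          for s in by_row.get(row, []))
            overlaps.append(covered / (b - a + 1))
        assert np.median(overlaps) >= 0.8
        for s in segments:
            assert 0 <= s.mean_prob <= 1
            assert ((s.asnp_positions >= s.start) & (s.asnp_positions <= s.end)).all()


class TestRegionFilter:
    def _segment(self, start, end, asnps, row=0):
        return archaic_scan.ArchaicSegment(
            sample_id="s0", hap_index=0, hap_row=row, start=start, end=end,
            mean_prob=0.9, asnp_positions=np.asarray(asnps, dtype=np.int64))

    def _arch(self, derived_positions):
        idx = pd.Index(np.arange(1, 10_001) * 10, name="position")
        df = pd.DataFrame(False, index=idx, columns=ARCHAIC_COLS)
        for pos, col in derived_positions:
            df.loc[pos, col] = True
        return df

    def test_full_overlap_required(self):
        region = Region("chr1", 1_000, 2_000)
        arch = self._arch([(1500, "Denisova")])
        inside = self._segment(1_100, 1_900, [1_500])
        one_past = self._segment(1_100, 2_001, [1_500])
        assert filter_for_region([inside, one_past], region, arch) == [inside]

    def test_requires_shared_asnp_with_any_archaic(self):
        region = Region("chr1", 1_000, 2_000)
        seg = self._segment(1_100, 1_900, [1_500])
        assert filter_for_region([seg], region, self._arch([])) == []
        assert filter_for_region([seg], region,
                                 self._arch([(1500, "AltaiNea")])) == [seg]

    def test_ancestry_assignment_rules(self):
        arch = self._arch([(10 * i, "Denisova") for i in range(1, 6)]
                          + [(10 * i, "VindijaNea") for i in range(6, 8)])
        assert assign_ancestry([10, 20, 30, 40, 50, 60, 70], arch) == "Denisova"
        arch2 = self._arch([(10, "Denisova"), (20, "Denisova"), (30, "Denisova"),
                            (40, "AltaiNea"), (50, "VindijaNea"), (60, "ChagyrskayaNea")])
        assert assign_ancestry([10, 20, 30, 40, 50, 60], arch2) == "ambiguous"
        arch3 = self._arch([(10 * i, "ChagyrskayaNea") for i in range(1, 5)])
        assert assign_ancestry([10, 20, 30, 40], arch3) == "Neanderthal"
        with pytest.raises(ValueError, match="empty"):
            assign_ancestry([], arch)


class TestClusterHaplotypes:
    def test_shared_asnp_set_gives_single_cluster_with_exact_frequency(self):
        # 10 target haplotypes; 4 carry the same derived alleles at 3 sites
        pos = np.array([100, 200, 300, 400, 500])
        H = np.zeros((14, 5), dtype=np.int8)
        carriers = [0, 2, 5, 9]
        for r in carriers:
            H[r, [0, 1, 2]] = 1
        panel = HaplotypePanel(chrom="chr1", positions=pos, H=H,
                               sample_ids=[f"t{i}" for i in range(5)] + ["o0", "o1"],
                               populations=["TGT"] * 5 + ["OUT"] * 2)
        region = Region("chr1", 1, 600)
        arch = pd.DataFrame(False, index=pd.Index(pos, name="position"),
                            columns=ARCHAIC_COLS)
        arch.loc[[100, 200, 300], "Denisova"] = True
        segments = [archaic_scan.ArchaicSegment(
            sample_id=f"t{r // 2}", hap_index=r % 2, hap_row=r,
            start=50, end=350, mean_prob=0.95,
            asnp_positions=np.array([100, 200, 300])) for r in carriers]
        for s in segments:
            s.ancestry = assign_ancestry(s.asnp_positions, arch)
        haps = cluster_haplotypes(segments, panel, "TGT", region, arch)
        assert len(haps) == 1
        assert haps[0].frequency == pytest.approx(len(carriers) / 10)
        assert haps[0].ancestry == "Denisova"
        # brute-force carrier count agrees
        assert set(haps[0].carrier_rows) == set(carriers)

    def test_unlinked_asnp_groups_form_two_clusters(self):
        pos = np.array([100, 200, 10_000, 10_100])
        H = np.zeros((12, 4), dtype=np.int8)
        H[[0, 1, 2], 0] = 1
        H[[0, 1, 2], 1] = 1
        H[[5, 6, 7], 2] = 1    # disjoint carriers: r^2 = 0 across groups
        H[[5, 6, 7], 3] = 1
        panel = HaplotypePanel(chrom="chr1", positions=pos, H=H,
                               sample_ids=[f"t{i}" for i in range(6)],
                               populations=["TGT"] * 6)
        arch = pd.DataFrame(True, index=pd.Index(pos, name="position"),
                            columns=ARCHAIC_COLS)
        segs = [
            archaic_scan.ArchaicSegment("t0", 0, 0, 50, 250, 0.9, np.array([100, 200]),
                                        ancestry="Neanderthal"),
            archaic_scan.ArchaicSegment("t2", 1, 5, 9_900, 10_200, 0.9,
                                        np.array([10_000, 10_100]), ancestry="Denisova"),
        ]
        haps = cluster_haplotypes(segs, panel, "TGT", Region("chr1", 1, 20_000), arch)
        assert len(haps) == 2

    def test_region_report_flags_candidate_ld(self):
        cfg, panel, truth, arch = _panel_with_tract(seed=23)
        segments = detect_all_segments(panel, "TGT", "OUT", chrom_length=cfg.L)
        region = Region("chr1", 250_000, 550_000)
        kept = filter_for_region(segments, region, arch)
        assert kept, "expected segments inside the anchored tract region"
        for s in kept:
            s.ancestry = assign_ancestry(s.asnp_positions, arch)
        haps = cluster_haplotypes(kept, panel, "TGT", region, arch)
        best = max(haps, key=lambda h: h.frequency)
        # pick an aSNP of the top cluster as "candidate": must be in high LD
        cand = int(best.asnp_positions[0])
        rep = region_report(haps, panel, "TGT", candidate_position=cand)
        assert rep["frequency"] == best.frequency
        assert rep["candidate_high_ld"]
        assert rep["candidate_max_r2"] > 0.5


class TestPrivateWindowCounts:
    def test_counts_windows_and_positions(self):
        pos = np.array([100, 1_100, 1_200, 2_500])
        H = np.array([[1, 1, 1, 1], [0, 0, 0, 0], [0, 1, 0, 0], [0, 1, 0, 0]],
                     dtype=np.int8)
        panel = HaplotypePanel(chrom="chr1", positions=pos, H=H,
                               sample_ids=["t", "o"], populations=["TGT", "OUT"])
        absent = archaic_scan.outgroup_absent_mask(panel, "OUT")
        counts, starts = private_window_counts(panel, 0, absent, 1_000,
                                               chrom_length=3_000)
        # site 1100 is carried by the outgroup -> not private
        np.testing.assert_array_equal(counts, [1, 1, 1])
        np.testing.assert_array_equal(starts, [1, 1_001, 2_001])
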