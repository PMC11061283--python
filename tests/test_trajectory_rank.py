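"""Wright-Fisher trajectory model and two-stage candidate ranking."""

import numpy as np
import pytest

from sweepscan.io_formats import Region
from sweepscan.trajectory_rank import (
    GENERATION_YEARS, TrajectoryModel, fit_s_from_trajectory, rank_candidates,
    simulate_wf_trajectories, simulate_wf_trajectory, wf_loglr,
)


class TestTrajectoryModel:
    def test_grid_validation(self):
        with pytest.raises(ValueError, match="include 0"):
            TrajectoryModel(s_grid=np.array([0.01, 0.02]))
        with pytest.raises(ValueError, match="n_bins"):
            TrajectoryModel(n_bins=10)

    def test_transition_rows_sum_to_one(self):
        m = TrajectoryModel(n_bins=60)
        for s in (0.0, 0.05):
            T = m.transition_matrix(s)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
            # near-boundary bins absorb
            assert T[0, 0] == 1.0 and T[-1, -1] == 1.0

    def test_degenerate_grid_gives_zero_loglr(self):
        m = TrajectoryModel(s_grid=np.array([0.0]))
        assert m.loglr(30, 100) == 0.0

    def test_loglr_nonnegative_and_monotone_under_grid_refinement(self):
        coarse = TrajectoryModel(s_grid=np.array([0.0, 0.02, 0.08]))
        fine = TrajectoryModel(s_grid=np.array([0.0, 0.01, 0.02, 0.04, 0.08]))
        for k in (5, 40, 90, 104):
            a, b = coarse.loglr(k, 108), fine.loglr(k, 108)
            assert a >= 0.0 and b >= 0.0
            assert b >= a - 1e-12  # superset grid can only improve the max


class TestWfLoglr:
    def test_requires_segregating_input(self, trajectory_model):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            wf_loglr(trajectory_model, 0, 100, rng)
        with pytest.raises(ValueError):
            wf_loglr(trajectory_model, 100, 100, rng)

    def test_unscorable_after_exhausted_retries(self, trajectory_model):
        class AlwaysFixed:
            def binomial(self, n, p):
                return n
        assert wf_loglr(trajectory_model, 99, 100, AlwaysFixed()) is None

    def test_bootstrap_runs_vary_but_are_seeded(self, trajectory_model):
        a = [wf_loglr(trajectory_model, 60, 108, np.random.default_rng(1))
             for _ in range(3)]
        b = [wf_loglr(trajectory_model, 60, 108, np.random.default_rng(1))
             for _ in range(3)]
        assert a == b

    def test_rank_order_recovery_under_selection(self):
        """Final counts simulated under s=0.02 score higher than neutral ones.

        Run at a 200-generation horizon, where a selected allele from a
        uniform start still commonly segregates (at the default 980
        generations essentially every selected trajectory fixes, leaving
        no present-day sample to score).
        """
        G = 200
        model = TrajectoryModel(generations=G)
        rng = np.random.default_rng(11)
        n, N2 = 108, 20_000

        def final_freqs(s, size):
            cur = rng.uniform(size=size)
            for _ in range(G):
                free = (cur > 0) & (cur < 1)
                if not free.any():
                    break
                mean = np.clip(cur[free] + s * cur[free] * (1 - cur[free]), 0, 1)
                cur[free] = rng.binomial(N2, mean) / N2
            return cur

        def survivor_loglrs(s, want):
            out = []
            while len(out) < want:
                y = final_freqs(s, 2_000)
                for yy in y[(y > 0) & (y < 1)]:
                    k = rng.binomial(n, yy)
                    if 0 < k < n:
                        out.append(model.loglr(k, n))
            return np.array(out[:want])

        neutral = survivor_loglrs(0.0, 60)
        selected = survivor_loglrs(0.02, 60)
        assert np.median(neutral) < np.median(selected)

    def test_horizon_in_years(self):
        assert TrajectoryModel().generations * GENERATION_YEARS == 27_440


class TestRankCandidates:
    def _panel(self, H, positions):
        from sweepscan.io_formats import HaplotypePanel
        n = H.shape[0] // 2
        return HaplotypePanel(chrom="chr1", positions=positions, H=H,
                              sample_ids=[f"s{i}" for i in range(n)],
                              populations=["P"] * n)

    def test_single_eligible_snp_wins_regardless(self, trajectory_model):
        rng = np.random.default_rng(0)
        H = np.zeros((20, 5), dtype=np.int8)
        H[:3, 2] = 1                     # DAF 0.15: the only eligible site
        H[0, 0] = 1                      # DAF 0.05 at site 0? no: 1/20 = 0.05
        H[:, 1] = 1                      # fixed -> excluded
        pos = np.array([10, 20, 30, 40, 50])
        region = Region("chr1", 1, 60)
        cand = rank_candidates(region, self._panel(H, pos), trajectory_model,
                               "P", seed=1)
        assert cand.site_index == 2 or cand.site_index == 0
        # make site 0 ineligible (DAF < 0.05 exactly means eligible at 0.05)
        H[0, 0] = 0
        cand = rank_candidates(region, self._panel(H, pos), trajectory_model,
                               "P", seed=1)
        assert cand.site_index == 2
        assert cand.daf == pytest.approx(0.15)

    def test_daf_filter_and_fixed_filter(self, trajectory_model):
        H = np.zeros((40, 3), dtype=np.int8)
        H[0, 0] = 1          # DAF 1/40 = 0.025 < 0.05 -> excluded
        H[:, 1] = 1          # fixed -> excluded
        H[:10, 2] = 1        # eligible
        pos = np.array([5, 10, 15])
        cand = rank_candidates(Region("chr1", 1, 20), self._panel(H, pos),
                               trajectory_model, "P", seed=0)
        assert cand.site_index == 2

    def test_exactly_five_eligible_all_advance(self, trajectory_model):
        rng = np.random.default_rng(2)
        H = (rng.random((30, 5)) < 0.4).astype(np.int8)
        pos = np.array([10, 20, 30, 40, 50])
        cand = rank_candidates(Region("chr1", 1, 60), self._panel(H, pos),
                               trajectory_model, "P", seed=3)
        assert len(cand.stage2) == 5

    def test_no_eligible_snp_gives_null_candidate(self, trajectory_model):
        H = np.zeros((10, 2), dtype=np.int8)
        cand = rank_candidates(Region("chr1", 1, 100),
                               self._panel(H, np.array([5, 6])),
                               trajectory_model, "P", seed=0)
        assert cand.site_index is None and cand.position is None

    def test_deterministic_given_seed(self, trajectory_model):
        rng = np.random.default_rng(5)
        H = (rng.random((30, 12)) < 0.5).astype(np.int8)
        pos = np.arange(1, 13) * 7
        a = rank_candidates(Region("chr1", 1, 100), self._panel(H, pos),
                            trajectory_model, "P", seed=9)
        b = rank_candidates(Region("chr1", 1, 100), self._panel(H, pos),
                            trajectory_model, "P", seed=9)
        assert a.site_index == b.site_index
        assert a.stage2 == b.stage2

    def test_ties_break_to_lower_position(self):
        # degenerate grid: every logLR is exactly 0, so ranking is pure
        # tie-breaking and must pick the lowest eligible position
        model = TrajectoryModel(s_grid=np.array([0.0]))
        rng = np.random.default_rng(1)
        H = np.zeros((20, 8), dtype=np.int8)
        H[:10, :] = 1  # every site DAF 0.5
        pos = np.arange(1, 9) * 11
        cand = rank_candidates(Region("chr1", 1, 100), self._panel(H, pos),
                               model, "P", seed=4)
        assert cand.site_index == 0


class TestTrajectoryFit:
    def test_absorbed_trajectory_rejected(self):
        m = TrajectoryModel()
        with pytest.raises(ValueError, match="absorbed"):
            fit_s_from_trajectory(m, np.ones(50))

    def test_neutral_trajectory_recovers_zero(self):
        m = TrajectoryModel(n_bins=200)
        rng = np.random.default_rng(3)
        paths = simulate_wf_trajectories(0.0, 1e4, 400, np.full(6, 0.5), rng)
        errs = [fit_s_from_trajectory(m, p) for p in paths]
        assert np.median(errs) <= 0.002

    def test_scalar_and_vector_simulators_absorb_consistently(self):
        rng1 = np.random.default_rng(8)
        path = simulate_wf_trajectory(0.1, 500, 300, 0.3, rng1)
        assert path[0] == 0.3
        absorbed = np.flatnonzero((path == 0) | (path == 1))
        if absorbed.size:  # once absorbed, stays absorbed
            assert np.all(path[absorbed[0]:] == path[absorbed[0]])
        rng2 = np.random.default_rng(8)
        paths = simulate_wf_trajectories(0.1, 500, 300, np.array([0.3]), rng2)
        assert paths.shape == (1, 301)
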