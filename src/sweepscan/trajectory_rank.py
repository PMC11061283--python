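"""Allele-frequency-trajectory likelihood ratios and candidate-SNP ranking.

Every eligible SNP in a candidate region is scored with a non-negative
log-likelihood ratio (logLR) comparing the best selected Wright-Fisher
trajectory model against the neutral one, and the two-stage multi-run
procedure picks one candidate SNP per region: every eligible SNP is scored
five times on bootstrap resamples of the sampled chromosomes and averaged;
the top five advance and are scored fifty additional times; the SNP with
the highest fifty-run mean wins.  SNPs with derived allele frequency below
0.05 or fixed are never considered.

The trajectory model is a discretized Wright-Fisher diffusion: the allele
frequency lives on a grid of B bins on (0, 1); per generation the frequency
moves by Normal(x + s*x*(1-x), x*(1-x)/(2*Ne)) with the two near-boundary
bins absorbing; the initial distribution is uniform over bins; the only
data enter as a Binomial(n, x) emission of the present-day derived count at
the final generation.  logLR = ln max_s L(s) - ln L(0) over a selection
grid containing s = 0, so logLR >= 0 by construction.  Because only the
present-day count is observed, the logLR is (by design) a monotone summary
of how far the present frequency sits from where neutral drift tends to
leave it; the run-to-run stochasticity that a genealogy-based method gets
from branch-length resampling is supplied here by bootstrap resampling of
the sampled chromosomes.

:func:`fit_s_from_trajectory` additionally estimates s from a fully
observed frequency trajectory via the same discretized transition kernel;
it is the parameter-recovery diagnostic for the kernel itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import HaplotypePanel, Region

__all__ = [
    "TrajectoryModel", "CandidateSNP", "wf_loglr", "rank_candidates",
    "simulate_wf_trajectory", "fit_s_from_trajectory",
]

GENERATION_YEARS = 28  # 980 generations x 28 y = 27,440 years


def default_s_grid() -> np.ndarray:
    """Positive-selection grid {0, 0.002, ..., 0.1}."""
    return np.round(np.arange(0.0, 0.1001, 0.002), 6)


@dataclass
class TrajectoryModel:
    """Discretized Wright-Fisher trajectory model.

    Parameters
    ----------
    generations
        Trajectory horizon G (980 generations = 27,440 years at 28 years
        per generation).
    Ne
        Effective population size controlling drift variance.
    n_bins
        Frequency grid size B (>= 50); bin midpoints (i + 0.5)/B.
    s_grid
        Selection coefficients; must contain 0.
    """

    generations: int = 980
    Ne: float = 10_000.0
    n_bins: int = 100
    s_grid: np.ndarray = field(default_factory=default_s_grid)

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if self.n_bins < 50:
            raise ValueError("n_bins must be >= 50")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not np.any(self.s_grid == 0.0):
            raise ValueError("s grid must include 0")
        self._final_dist: dict[float, np.ndarray] = {}

    # -- grid ---------------------------------------------------------------
    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) / self.n_bins

    def transition_matrix(self, s: float) -> np.ndarray:
        """Row-stochastic one-generation kernel; boundary bins absorbing."""
        x = self.midpoints
        mu = x + s * x * (1 - x)
        sd = np.sqrt(x * (1 - x) / (2 * self.Ne))
        z = (self.edges[np.newaxis, :] - mu[:, np.newaxis]) / sd[:, np.newaxis]
        cdf = stats.norm.cdf(z)
        T = np.diff(cdf, axis=1)
        # Tail mass beyond the outer edges goes to the boundary bins.
        T[:, 0] += cdf[:, 0]
        T[:, -1] += 1.0 - cdf[:, -1]
        T[0, :] = 0.0
        T[0, 0] = 1.0
        T[-1, :] = 0.0
        T[-1, -1] = 1.0
        return T

    def final_distribution(self, s: float) -> np.ndarray:
        """State distribution after G generations from a uniform start."""
        key = float(s)
        if key not in self._final_dist:
            T = self.transition_matrix(s)
            # T^G by binary exponentiation, then one vector product.
            power = np.eye(self.n_bins)
            base = T
            g = self.generations
            while g:
                if g & 1:
                    power = power @ base
                g >>= 1
                if g:
                    base = base @ base
            pi0 = np.full(self.n_bins, 1.0 / self.n_bins)
            self._final_dist[key] = pi0 @ power
        return self._final_dist[key]

    def log_likelihoods(self, k: int, n: int) -> np.ndarray:
        """ln L(s) for every s on the grid, given k derived of n sampled."""
        emission = stats.binom.pmf(k, n, self.midpoints)
        out = np.empty(self.s_grid.size)
        for i, s in enumerate(self.s_grid):
            out[i] = np.log(max(self.final_distribution(s) @ emission, 1e-300))
        return out

    def loglr(self, k: int, n: int) -> float:
        """ln max_s L(s) - ln L(0); non-negative because the grid contains 0."""
        ll = self.log_likelihoods(k, n)
        return float(ll.max() - ll[self.s_grid == 0.0][0])


def wf_loglr(model: TrajectoryModel, k: int, n: int,
             rng: np.random.Generator, max_retries: int = 10) -> float | None:
    """One stochastic logLR run for a SNP with k derived of n chromosomes.

    The n sampled chromosomes are bootstrap-resampled (so the resampled
    derived count is Binomial(n, k/n)); if the resample is monomorphic the
    draw is retried up to ``max_retries`` times, after which the SNP is
    flagged unscorable (None).
    """
    if not 0 < k < n:
        raise ValueError("need a segregating SNP: 0 < k < n")
    for _ in range(max_retries + 1):
        kb = int(rng.binomial(n, k / n))
        if 0 < kb < n:
            return model.loglr(kb, n)
    return None


@dataclass
class CandidateSNP:
    """Winner of the two-stage ranking for one region."""

    region: Region
    site_index: int | None
    position: int | None
    daf: float | None
    mean_loglr_stage2: float | None
    stage1: dict = field(default_factory=dict)  # site_index -> mean of 5 runs
    stage2: dict = field(default_factory=dict)  # site_index -> mean of 50 runs
    runs: dict = field(default_factory=dict)    # site_index -> list of run logLRs


def rank_candidates(region: Region, panel: HaplotypePanel, model: TrajectoryModel,
                    population: str, seed: int = 0,
                    n_stage1: int = 5, n_stage2: int = 50,
                    min_daf: float = 0.05) -> CandidateSNP:
    """Two-stage candidate-SNP selection within one region.

    Eligible SNPs lie inside the region, segregate in the population and
    have DAF >= ``min_daf``.  Stage 1 scores each eligible SNP
    ``n_stage1`` times (distinct seeds) and averages; the top five
    stage-1 means advance to stage 2 and receive ``n_stage2`` additional
    runs; the winner is the SNP with the highest stage-2 mean.  Ties
    break to the lower position, so the procedure is deterministic given
    the seed.  A region with no eligible SNP yields a null candidate.
    """
    k, n_tot = panel.derived_counts(population)
    in_region = (panel.positions >= region.start) & (panel.positions <= region.end)
    with np.errstate(invalid="ignore"):
        daf = np.where(n_tot > 0, k / np.maximum(n_tot, 1), 0.0)
    eligible = np.flatnonzero(in_region & (daf >= min_daf) & (k > 0) & (daf < 1))
    if eligible.size == 0:
        return CandidateSNP(region=region, site_index=None, position=None,
                            daf=None, mean_loglr_stage2=None)

    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, region.start])
    children = ss.spawn(eligible.size)
    runs: dict[int, list[float]] = {}
    stage1: dict[int, float] = {}
    for j, child in zip(eligible, children):
        rng = np.random.default_rng(child)
        vals = [wf_loglr(model, int(k[j]), int(n_tot[j]), rng) for _ in range(n_stage1)]
        vals = [v for v in vals if v is not None]
        runs[int(j)] = vals
        stage1[int(j)] = float(np.mean(vals)) if vals else -np.inf

    # Top five stage-1 means; ties to the lower position.
    order = sorted(stage1, key=lambda j: (-stage1[j], panel.positions[j]))
    finalists = order[:5]
    stage2: dict[int, float] = {}
    children2 = ss.spawn(len(finalists))
    for j, child in zip(finalists, children2):
        rng = np.random.default_rng(child)
        vals = [wf_loglr(model, int(k[j]), int(n_tot[j]), rng) for _ in range(n_stage2)]
        vals = [v for v in vals if v is not None]
        runs[j] = runs.get(j, []) + vals
        stage2[j] = float(np.mean(vals)) if vals else -np.inf

    winner = min(stage2, key=lambda j: (-stage2[j], panel.positions[j]))
    return CandidateSNP(
        region=region,
        site_index=int(winner),
        position=int(panel.positions[winner]),
        daf=float(daf[winner]),
        mean_loglr_stage2=stage2[winner],
        stage1=stage1, stage2=stage2, runs=runs,
    )


# ---------------------------------------------------------------------------
# Trajectory simulation and kernel parameter recovery
# ---------------------------------------------------------------------------

def simulate_wf_trajectory(s: float, Ne: float, generations: int,
                           x0: float, rng: np.random.Generator) -> np.ndarray:
    """Forward Wright-Fisher frequency trajectory (binomial sampling).

    Returns the length-(G+1) frequency path including the start; absorbs
    at 0 and 1.
    """
    N2 = int(round(2 * Ne))
    x = np.empty(generations + 1)
    x[0] = x0
    cur = x0
    for t in range(1, generations + 1):
        if cur <= 0.0 or cur >= 1.0:
            x[t:] = cur
            break
        mean = cur + s * cur * (1 - cur)
        cur = rng.binomial(N2, min(max(mean, 0.0), 1.0)) / N2
        x[t] = cur
    return x

def simulate_wf_trajectories(s: float, Ne: float, generations: int,
                             x0, rng: np.random.Generator) -> np.ndarray:
    """Vectorized forward Wright-Fisher paths, one row per trajectory.

    ``x0`` is an array of starting frequencies; returns an
    ``(len(x0), generations + 1)`` frequency array with absorption at 0
    and 1.
    """
    x0 = np.asarray(x0, dtype=float)
    N2 = int(round(2 * Ne))
    out = np.empty((x0.size, generations + 1))
    out[:, 0] = x0
    cur = x0.copy()
    for t in range(1, generations + 1):
        mean = np.clip(cur + s * cur * (1 - cur), 0.0, 1.0)
        free = (cur > 0.0) & (cur < 1.0)
        nxt = cur.copy()
        if free.any():
            nxt[free] = rng.binomial(N2, mean[free]) / N2
        cur = nxt
        out[:, t] = cur
    return out


def fit_s_from_trajectory(model: TrajectoryModel, trajectory: np.ndarray) -> float:
    """Maximum-likelihood s (on the model grid) from an observed trajectory.

    Bins the trajectory on the model grid and maximizes the product of
    one-generation transition probabilities over the grid of selection
    coefficients.  Absorbed stretches (frequency at 0 or 1) carry no
    information and are excluded.
    """
    x = np.asarray(trajectory, dtype=float)
    interior = (x > 0.0) & (x < 1.0)
    # transitions whose source state is interior and not yet absorbed
    src = np.flatnonzero(interior[:-1])
    if src.size == 0:
        raise ValueError("trajectory is absorbed everywhere; cannot fit s")
    bins = np.clip((x * model.n_bins).astype(int), 0, model.n_bins - 1)
    best_s, best_ll = None, -np.inf
    for s in model.s_grid:
        T = model.transition_matrix(s)
        ll = np.log(np.maximum(T[bins[src], bins[src + 1]], 1e-300)).sum()
        if ll > best_ll:
            best_s, best_ll = float(s), ll
    return best_s
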