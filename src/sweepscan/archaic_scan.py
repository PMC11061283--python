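"""Archaic-introgression detection, ancestry assignment and clustering.

Candidate archaic tracts are detected per haplotype with a two-state
hidden Markov model over fixed windows: the observation for a window is
the number of derived alleles on the focal haplotype that are absent from
the unadmixed outgroup panel, emitted as Poisson with a low rate in the
modern-human state and a higher rate in the archaic state.  Parameters are
fit by Baum-Welch; posterior decoding defines segments as maximal runs of
windows with P(Archaic) > 0.5, kept when the mean posterior over the run
(``mean_prob``) is at least 0.8.

An aSNP is a derived variant absent from the outgroup that falls within
the borders of an inferred segment.  Segments fully contained in a
candidate region and sharing at least one aSNP with any of the four
archaic genotype panels are retained; ancestry is Denisova if a segment
shares more aSNPs with the Denisovan panel than with the union of the
three Neanderthal panels, Neanderthal in the opposite case, and ambiguous
on ties.  Individual-level segments are combined into region-level
introgressed haplotypes through connected components of highly linked
aSNPs (r^2 > 0.5 on target-population chromosomes); the reported haplotype
frequency is carrier chromosomes over total chromosomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import HaplotypePanel, Region

logger = logging.getLogger("sweepscan")

__all__ = [
    "HmmConfig", "ArchaicSegment", "ArchaicHaplotype", "private_window_counts",
    "fit_poisson_hmm", "detect_segments", "detect_all_segments",
    "filter_for_region", "assign_ancestry", "cluster_haplotypes", "region_report",
]

NEANDERTHAL_PANELS = ["AltaiNea", "VindijaNea", "ChagyrskayaNea"]
DENISOVAN_PANELS = ["Denisova"]


@dataclass
class HmmConfig:
    window_bp: int = 1_000
    mean_prob_min: float = 0.8     # keep segments with mean posterior >= this
    posterior_threshold: float = 0.5
    max_iter: int = 500
    tol: float = 1e-4              # Baum-Welch log-likelihood convergence
    min_rate_ratio: float = 1.5    # below this the fit is degenerate


@dataclass
class ArchaicSegment:
    """A candidate introgressed tract on one haplotype."""

    sample_id: str
    hap_index: int                 # 0 or 1 within the sample
    hap_row: int                   # row in the panel matrix
    start: int                     # 1-based inclusive, window-aligned
    end: int
    mean_prob: float
    asnp_positions: np.ndarray     # private derived positions inside the tract
    ancestry: str | None = None


@dataclass
class ArchaicHaplotype:
    """A region-level cluster of linked aSNPs shared across individuals."""

    region: Region
    asnp_positions: np.ndarray
    ancestry: str
    carrier_rows: np.ndarray
    frequency: float               # carrier chromosomes / total chromosomes
    frequencies: dict = field(default_factory=dict)  # population -> frequency


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def outgroup_absent_mask(panel: HaplotypePanel, outgroup: str) -> np.ndarray:
    """Sites whose derived allele is carried by no outgroup chromosome."""
    k_out, _ = panel.derived_counts(outgroup)
    return k_out == 0

def private_window_counts(panel: HaplotypePanel, hap_row: int,
                          absent_mask: np.ndarray, window_bp: int,
                          chrom_length: int | None = None):
    """Per-window count of derived alleles private to this haplotype
    (absent from the outgroup).

    Returns ``(counts, window_starts)`` with windows tiling
    ``[1, chrom_length]`` (default: up to the last site).
    """
    L = chrom_length or int(panel.positions[-1])
    n_windows = (L + window_bp - 1) // window_bp
    derived = (panel.H[hap_row] == 1) & absent_mask
    win = (panel.positions[derived] - 1) // window_bp
    counts = np.bincount(win, minlength=n_windows)[:n_windows]
    starts = np.arange(n_windows, dtype=np.int64) * window_bp + 1
    return counts.astype(float), starts


# ---------------------------------------------------------------------------
# Two-state Poisson HMM
# ---------------------------------------------------------------------------

def _log_poisson_pmf(counts: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """log Poisson pmf for counts (H, T) at per-haplotype rates (H, 2) -> (H, T, 2)."""
    from scipy.special import gammaln
    k = counts[:, :, None]
    lam = rates[:, None, :]
    return k * np.log(lam) - lam - gammaln(k + 1.0)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    _njit = None


def _fb_recursion_numpy(B, transmat, startprob):
    """Scaled forward-backward recursions on pre-scaled emissions.

    B: (H, T, 2); transmat (H, 2, 2); startprob (H, 2).  Returns
    (log sum of scale factors (H,), posterior (H, T, 2), xi (H, 2, 2)).
    Reference implementation; the numba kernel below must agree with it.
    """
    H, T, _ = B.shape
    alpha = np.empty((H, T, 2))
    c = np.empty((H, T))
    a0 = startprob * B[:, 0]
    c[:, 0] = a0.sum(axis=1)
    alpha[:, 0] = a0 / c[:, 0, None]
    for t in range(1, T):
        a = np.einsum("hi,hij->hj", alpha[:, t - 1], transmat) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((H, T, 2))
    beta[:, -1] = 1.0
    xi = np.zeros((H, 2, 2))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        xi += (alpha[:, t, :, None] * transmat * bb[:, None, :]) / c[:, t + 1, None, None]
        beta[:, t] = np.einsum("hij,hj->hi", transmat, bb) / c[:, t + 1, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return np.log(c).sum(axis=1), post, xi


def _fb_recursion_scalar(B, transmat, startprob):
    """Same recursions written with scalar loops (numba-compiled)."""
    H, T, _ = B.shape
    logc = np.zeros(H)
    post = np.empty((H, T, 2))
    xi = np.zeros((H, 2, 2))
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    c = np.empty(T)
    for h in range(H):
        t00, t01 = transmat[h, 0, 0], transmat[h, 0, 1]
        t10, t11 = transmat[h, 1, 0], transmat[h, 1, 1]
        a0 = startprob[h, 0] * B[h, 0, 0]
        a1 = startprob[h, 1] * B[h, 0, 1]
        s = a0 + a1
        c[0] = s
        alpha[0, 0] = a0 / s
        alpha[0, 1] = a1 / s
        for t in range(1, T):
            a0 = (alpha[t - 1, 0] * t00 + alpha[t - 1, 1] * t10) * B[h, t, 0]
            a1 = (alpha[t - 1, 0] * t01 + alpha[t - 1, 1] * t11) * B[h, t, 1]
            s = a0 + a1
            c[t] = s
            alpha[t, 0] = a0 / s
            alpha[t, 1] = a1 / s
        beta[T - 1, 0] = 1.0
        beta[T - 1, 1] = 1.0
        for t in range(T - 2, -1, -1):
            bb0 = B[h, t + 1, 0] * beta[t + 1, 0]
            bb1 = B[h, t + 1, 1] * beta[t + 1, 1]
            inv_c = 1.0 / c[t + 1]
            xi[h, 0, 0] += alpha[t, 0] * t00 * bb0 * inv_c
            xi[h, 0, 1] += alpha[t, 0] * t01 * bb1 * inv_c
            xi[h, 1, 0] += alpha[t, 1] * t10 * bb0 * inv_c
            xi[h, 1, 1] += alpha[t, 1] * t11 * bb1 * inv_c
            beta[t, 0] = (t00 * bb0 + t01 * bb1) * inv_c
            beta[t, 1] = (t10 * bb0 + t11 * bb1) * inv_c
        acc = 0.0
        for t in range(T):
            p0 = alpha[t, 0] * beta[t, 0]
            p1 = alpha[t, 1] * beta[t, 1]
            ps = p0 + p1
            post[h, t, 0] = p0 / ps
            post[h, t, 1] = p1 / ps
            acc += np.log(c[t])
        logc[h] = acc
    return logc, post, xi


if _njit is not None:
    _fb_recursion_scalar = _njit(cache=True)(_fb_recursion_scalar)


def _forward_backward_batch(counts, rates, transmat, startprob, use_numba=True):
    """Scaled forward-backward, batched over haplotypes.

    Shapes: counts (H, T); rates (H, 2); transmat (H, 2, 2); startprob
    (H, 2).  Returns (loglik (H,), posterior (H, T, 2), xi (H, 2, 2)),
    the per-sequence log-likelihoods, state posteriors and expected
    transition counts.  Each sequence carries its own parameters, so the
    recursion over time serves every haplotype at once.
    """
    logB = _log_poisson_pmf(counts, rates)
    shift = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - shift)                      # (H, T, 2)
    recursion = _fb_recursion_scalar if (use_numba and _njit is not None) \
        else _fb_recursion_numpy
    logc, post, xi = recursion(np.ascontiguousarray(B),
                               np.ascontiguousarray(transmat),
                               np.ascontiguousarray(startprob))
    loglik = logc + shift[:, :, 0].sum(axis=1)
    return loglik, post, xi


def fit_poisson_hmm_batch(counts, config: HmmConfig | None = None):
    """Baum-Welch fit of the two-state (Human, Archaic) Poisson HMM, one
    independent fit per row of ``counts``.

    Returns ``(rates, transmat, startprob, posterior, loglik)`` with state
    0 = Human (low rate) and state 1 = Archaic (high rate) in every row.
    Rows keep iterating until their log-likelihood improves by less than
    ``tol`` (they are simply carried along; the M step is idempotent at
    convergence).
    """
    config = config or HmmConfig()
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    H, T = counts.shape
    mean = counts.mean(axis=1)
    nzmean = np.array([c[c > 0].mean() if (c > 0).any() else 1.0 for c in counts])
    lam_h = np.maximum(0.2 * mean, 1e-3)
    lam_a = np.maximum.reduce([nzmean, 5 * lam_h, np.full(H, 0.5)])
    rates = np.stack([lam_h, lam_a], axis=1)
    transmat = np.broadcast_to(np.array([[0.999, 0.001], [0.02, 0.98]]),
                               (H, 2, 2)).copy()
    startprob = np.broadcast_to(np.array([0.95, 0.05]), (H, 2)).copy()
    out_post = np.empty((H, T, 2))
    out_ll = np.full(H, -np.inf)
    active = np.arange(H)                         # rows still iterating
    prev_ll = np.full(H, -np.inf)
    for _ in range(config.max_iter):
        ll, post, xi = _forward_backward_batch(counts[active], rates[active],
                                               transmat[active], startprob[active])
        denom = post.sum(axis=1)                  # (h, 2)
        r = np.maximum((post * counts[active][:, :, None]).sum(axis=1)
                       / np.maximum(denom, 1e-12), 1e-6)
        tm = xi / np.maximum(xi.sum(axis=2, keepdims=True), 1e-12)
        tm = np.clip(tm, 1e-12, None)
        tm /= tm.sum(axis=2, keepdims=True)
        sp = np.clip(post[:, 0], 1e-12, None)
        sp /= sp.sum(axis=1, keepdims=True)
        flip = r[:, 0] > r[:, 1]                  # keep state 1 the high rate
        if flip.any():
            r[flip] = r[flip][:, ::-1]
            tm[flip] = tm[flip][:, ::-1, ::-1]
            sp[flip] = sp[flip][:, ::-1]
            post[flip] = post[flip][:, :, ::-1]
        rates[active] = r
        transmat[active] = tm
        startprob[active] = sp
        out_post[active] = post
        out_ll[active] = ll
        done = np.abs(ll - prev_ll[active]) < config.tol
        prev_ll[active] = ll
        active = active[~done]
        if active.size == 0:
            break
    return rates, transmat, startprob, out_post, out_ll


def fit_poisson_hmm(counts, config: HmmConfig | None = None):
    """Single-sequence convenience wrapper around the batched fit."""
    rates, transmat, startprob, post, ll = fit_poisson_hmm_batch(
        np.asarray(counts, dtype=float)[None, :], config)
    return rates[0], transmat[0], startprob[0], post[0], float(ll[0])


def detect_segments(panel: HaplotypePanel, hap_row: int, outgroup: str,
                    config: HmmConfig | None = None,
                    absent_mask: np.ndarray | None = None,
                    chrom_length: int | None = None) -> list[ArchaicSegment]:
    """Candidate archaic tracts on one haplotype.

    A segment is a maximal run of windows with posterior P(Archaic) > 0.5;
    it is kept when its mean posterior is >= ``mean_prob_min``.  A
    degenerate Baum-Welch fit (archaic and human rates indistinguishable)
    yields no segments, with a warning.
    """
    config = config or HmmConfig()
    if absent_mask is None:
        absent_mask = outgroup_absent_mask(panel, outgroup)
    counts, starts = private_window_counts(panel, hap_row, absent_mask,
                                           config.window_bp, chrom_length)
    if not counts.any():
        return []
    rates, transmat, startprob, post, _ = fit_poisson_hmm(counts, config)
    if rates[1] < config.min_rate_ratio * rates[0]:
        warnings.warn(
            f"degenerate Poisson-HMM fit (rates {rates[0]:.3g}, {rates[1]:.3g}); "
            "no archaic segments called", stacklevel=2)
        return []
    return _segments_from_posterior(panel, hap_row, post[:, 1], starts,
                                    config, absent_mask)


def _segments_from_posterior(panel, hap_row, p_arch, starts, config, absent_mask):
    """Maximal runs of P(Archaic) > threshold with mean_prob >= 0.8."""
    sample_id = panel.sample_ids[hap_row // 2]
    segments = []
    in_run = p_arch > config.posterior_threshold
    T = p_arch.shape[0]
    t = 0
    while t < T:
        if in_run[t]:
            u = t
            while u + 1 < T and in_run[u + 1]:
                u += 1
            mean_prob = float(p_arch[t:u + 1].mean())
            if mean_prob >= config.mean_prob_min:
                start = int(starts[t])
                end = int(starts[u]) + config.window_bp - 1
                sel = (panel.positions >= start) & (panel.positions <= end) \
                    & absent_mask & (panel.H[hap_row] == 1)
                segments.append(ArchaicSegment(
                    sample_id=sample_id, hap_index=hap_row % 2, hap_row=hap_row,
                    start=start, end=end, mean_prob=mean_prob,
                    asnp_positions=panel.positions[sel].copy(),
                ))
            t = u + 1
        else:
            t += 1
    return segments


def detect_all_segments(panel: HaplotypePanel, population: str, outgroup: str,
                        config: HmmConfig | None = None,
                        chrom_length: int | None = None) -> list[ArchaicSegment]:
    """Detect segments on every haplotype of a population (one batched fit).

    Haplotypes with a degenerate fit (archaic and human rates
    indistinguishable, the expected outcome on tract-free haplotypes)
    contribute no segments.
    """
    config = config or HmmConfig()
    absent = outgroup_absent_mask(panel, outgroup)
    rows = panel.haplotype_rows(population)
    counts_list, starts = [], None
    for row in rows:
        counts, starts = private_window_counts(panel, int(row), absent,
                                               config.window_bp, chrom_length)
        counts_list.append(counts)
    counts_mat = np.stack(counts_list, axis=0)
    rates, _, _, post, _ = fit_poisson_hmm_batch(counts_mat, config)
    out: list[ArchaicSegment] = []
    for i, row in enumerate(rows):
        if not counts_mat[i].any():
            continue
        if rates[i, 1] < config.min_rate_ratio * rates[i, 0]:
            continue
        out.extend(_segments_from_posterior(panel, int(row), post[i, :, 1],
                                            starts, config, absent))
    return out


# ---------------------------------------------------------------------------
# Region filtering, ancestry, clustering
# ---------------------------------------------------------------------------

def _derived_in_panel(archaic_panels: pd.DataFrame, positions, columns) -> np.ndarray:
    """Per-position: derived allele present in any of the given archaic columns.

    Positions missing from an archaic panel count as absence.
    """
    sub = archaic_panels.reindex(np.asarray(positions))[list(columns)].fillna(False)
    return sub.any(axis=1).to_numpy()


def filter_for_region(segments: list[ArchaicSegment], region: Region,
                      archaic_panels: pd.DataFrame) -> list[ArchaicSegment]:
    """Keep segments fully inside the region that share >= 1 aSNP with any
    of the four archaic panels."""
    all_cols = NEANDERTHAL_PANELS + DENISOVAN_PANELS
    kept = []
    for seg in segments:
        if seg.start < region.start or seg.end > region.end:
            continue
        if seg.asnp_positions.size == 0:
            continue
        if _derived_in_panel(archaic_panels, seg.asnp_positions, all_cols).any():
            kept.append(seg)
    return kept


def assign_ancestry(asnp_positions, archaic_panels: pd.DataFrame) -> str:
    """Denisova / Neanderthal / ambiguous by shared-aSNP counts.

    nD = aSNPs derived in the Denisovan panel; nN = aSNPs derived in the
    union of the three Neanderthal panels; the larger count wins, ties are
    ambiguous.
    """
    asnp_positions = np.asarray(asnp_positions)
    if asnp_positions.size == 0:
        raise ValueError("empty aSNP set (should have been filtered)")
    nd = int(_derived_in_panel(archaic_panels, asnp_positions, DENISOVAN_PANELS).sum())
    nn = int(_derived_in_panel(archaic_panels, asnp_positions, NEANDERTHAL_PANELS).sum())
    if nd > nn:
        return "Denisova"
    if nn > nd:
        return "Neanderthal"
    return "ambiguous"


def _r_squared(panel: HaplotypePanel, rows: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between sites (by position) on the given chromosomes."""
    idx = np.searchsorted(panel.positions, positions)
    X = (panel.H[np.ix_(rows, idx)] == 1).astype(float)
    p = X.mean(axis=0)
    var = p * (1 - p)
    cov = (X.T @ X) / X.shape[0] - np.outer(p, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov ** 2 / np.outer(var, var)
    r2[~np.isfinite(r2)] = 0.0
    return r2


def cluster_haplotypes(segments: list[ArchaicSegment], panel: HaplotypePanel,
                       population: str, region: Region,
                       archaic_panels: pd.DataFrame,
                       r2_threshold: float = 0.5) -> list[ArchaicHaplotype]:
    """Combine per-individual segments into region-level introgressed
    haplotypes via connected components of linked aSNPs (r^2 > 0.5).

    Each segment joins the component sharing most of its aSNPs (ties go to
    the larger component); a chromosome carries a haplotype if one of its
    kept segments is assigned to that component; frequency = carrier
    chromosomes / population chromosomes.  Cluster ancestry is the most
    frequent segment-level ancestry (ties: ambiguous).
    """
    if not segments:
        return []
    rows = panel.haplotype_rows(population)
    all_asnps = np.unique(np.concatenate([s.asnp_positions for s in segments]))
    r2 = _r_squared(panel, rows, all_asnps)
    adj = csr_matrix(r2 > r2_threshold)
    n_comp, labels = connected_components(adj, directed=False)
    comp_size = np.bincount(labels, minlength=n_comp)

    pos_to_comp = {int(p): int(c) for p, c in zip(all_asnps, labels)}
    members: dict[int, list[ArchaicSegment]] = {}
    for seg in segments:
        comps = np.array([pos_to_comp[int(p)] for p in seg.asnp_positions])
        shared = np.bincount(comps, minlength=n_comp)
        best = np.flatnonzero(shared == shared.max())
        chosen = int(best[np.argmax(comp_size[best])])  # tie -> larger component
        members.setdefault(chosen, []).append(seg)

    pops = sorted(set(panel.populations))
    out = []
    for comp, segs in sorted(members.items()):
        carrier_rows = np.unique([s.hap_row for s in segs])
        ancestries = [s.ancestry or assign_ancestry(s.asnp_positions, archaic_panels)
                      for s in segs]
        values, counts = np.unique(ancestries, return_counts=True)
        top = values[counts == counts.max()]
        ancestry = str(top[0]) if top.size == 1 else "ambiguous"
        freqs = {}
        for pop in pops:
            pop_rows = panel.haplotype_rows(pop)
            freqs[pop] = float(np.isin(pop_rows, carrier_rows).sum() / pop_rows.size)
        out.append(ArchaicHaplotype(
            region=region,
            asnp_positions=all_asnps[labels == comp],
            ancestry=ancestry,
            carrier_rows=carrier_rows,
            frequency=freqs[population],
            frequencies=freqs,
        ))
    return out


def region_report(haplotypes: list[ArchaicHaplotype], panel: HaplotypePanel,
                  population: str, candidate_position: int | None = None,
                  r2_threshold: float = 0.5) -> dict:
    """Top-frequency introgressed haplotype for a region, with the max r^2
    between the region's candidate SNP and any cluster aSNP."""
    if not haplotypes:
        return {"haplotype": None, "ancestry": None, "frequency": None,
                "candidate_max_r2": None, "candidate_high_ld": False}
    best = max(haplotypes, key=lambda h: h.frequency)
    max_r2 = None
    if candidate_position is not None and candidate_position in panel.positions:
        rows = panel.haplotype_rows(population)
        pos = np.concatenate([[candidate_position], best.asnp_positions])
        r2 = _r_squared(panel, rows, np.unique(pos))
        upos = np.unique(pos)
        ci = int(np.searchsorted(upos, candidate_position))
        others = np.arange(upos.size) != ci
        max_r2 = float(r2[ci, others].max()) if others.any() else 0.0
    return {
        "haplotype": best,
        "ancestry": best.ancestry,
        "frequency": best.frequency,
        "start": int(best.asnp_positions.min()),
        "end": int(best.asnp_positions.max()),
        "candidate_max_r2": max_r2,
        "candidate_high_ld": bool(max_r2 is not None and max_r2 > r2_threshold),
    }
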