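"""Per-SNP population-genetic statistics.

This module implements the statistics underlying the selection scans:

* Hudson's FST estimator (Bhatia et al. form, unbiased for unequal sample
  sizes) per site;
* the Population Branch Statistic, PBS = (T_TR + T_TO - T_RO) / 2 with
  T = -ln(1 - FST), quantifying target-specific allele-frequency change
  relative to a reference population and an outgroup;
* EHH (extended haplotype homozygosity) curves, their physical-distance
  integral iHH, and the cross-population XP-EHH statistic
  ln(iHH_target / iHH_reference), z-normalized over all scored sites.
  Positive normalized scores support a sweep in the target population,
  negative scores a sweep in the reference;
* the four-population D statistic (ABBA/BABA) with a delete-one block
  jackknife Z score.

EHH here is the probability that two haplotypes drawn without replacement
from the sample are identical over all markers between the core SNP and a
given distance.  Integration is over physical distance (bp); the curve is
truncated at the first marker where EHH falls below ``ehh_cutoff`` and
stops at gaps larger than ``max_gap_bp`` or at the edge of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PBSConfig", "XPEHHConfig", "hudson_fst", "pbs", "ehh", "ihh",
    "xpehh", "d_statistic",
]


@dataclass
class PBSConfig:
    """Settings for the FST -> PBS transform."""

    eps: float = 1e-6  # FST clamped to [0, 1 - eps] before -ln(1 - FST)

    def __post_init__(self) -> None:
        if not 0 < self.eps <= 0.01:
            raise ValueError("eps must lie in (0, 0.01]")


@dataclass
class XPEHHConfig:
    ehh_cutoff: float = 0.05       # stop integrating once EHH < cutoff
    max_gap_bp: int = 200_000      # stop at larger inter-marker gaps
    min_scored: int = 2            # need >= 2 scored sites to normalize

    def __post_init__(self) -> None:
        if not 0 < self.ehh_cutoff < 1:
            raise ValueError("ehh_cutoff must lie in (0, 1)")


# ---------------------------------------------------------------------------
# FST / PBS
# ---------------------------------------------------------------------------

def hudson_fst(p1, n1, p2, n2, eps: float = 1e-6, clamp: bool = True):
    """Hudson's per-site FST estimator.

    ``FST = [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
    / [p1(1-p2) + p2(1-p1)]``
    with ``n`` the number of sampled (non-missing) allele copies.  Sites
    where the denominator is zero (both populations fixed for the same
    allele) are returned as NaN.  With ``clamp`` the estimate is clamped to
    ``[0, 1 - eps]`` so that ``-ln(1 - FST)`` stays finite and non-negative.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    for p in (p1, p2):
        valid = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not np.all(valid):
            raise ValueError("allele frequency outside [0, 1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need >= 2 non-missing allele copies per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if clamp:
        fst = np.clip(fst, 0.0, 1.0 - eps)
    return fst


def pbs(fst_tr, fst_to, fst_ro):
    """Population Branch Statistic from the three pairwise FST values.

    ``T_XY = -ln(1 - FST_XY)``; ``PBS = (T_TR + T_TO - T_RO) / 2``.
    Missing (NaN) inputs propagate; negative PBS is retained.
    """
    t = lambda f: -np.log1p(-np.asarray(f, dtype=float))
    return (t(fst_tr) + t(fst_to) - t(fst_ro)) / 2.0


# ---------------------------------------------------------------------------
# EHH / iHH / XP-EHH
# ---------------------------------------------------------------------------

_BLOCK = 32  # markers per bit-packed block (2 bits per marker in a uint64)


def _ehh_one_direction(H, positions, core, step, cutoff, max_gap_bp,
                       pair_idx=None):
    """EHH values walking from the core in one direction.

    Returns parallel lists of (position, ehh).  Stops after the first
    marker where EHH < cutoff (that marker is included, giving the
    integrator its final trapezoid), at a gap > max_gap_bp, or at the edge.
    Missing alleles are treated as a distinct symbol.

    EHH at marker k equals the fraction of haplotype pairs identical over
    every marker between the core (exclusive) and k; pairs are tracked by
    bit-packing blocks of markers and locating each pair's first mismatch
    with XOR/low-bit arithmetic, which keeps the per-core cost at a few
    vector operations per 32 markers.
    """
    m, S = H.shape
    total_pairs = m * (m - 1) / 2.0
    if pair_idx is None:
        pair_idx = np.triu_indices(m, 1)
    ia, ib = pair_idx

    idxs = np.arange(core + 1, S) if step > 0 else np.arange(core - 1, -1, -1)
    if idxs.size:
        pos_seq = positions[idxs].astype(np.int64)
        prev = np.concatenate([[positions[core]], pos_seq[:-1]])
        big_gap = np.abs(pos_seq - prev) > max_gap_bp
        if big_gap.any():
            idxs = idxs[: int(np.argmax(big_gap))]

    out_pos: list[int] = []
    out_ehh: list[float] = []
    alive = np.ones(ia.size, dtype=bool)
    shifts = (2 * np.arange(_BLOCK, dtype=np.uint64))
    for b0 in range(0, idxs.size, _BLOCK):
        cols = idxs[b0:b0 + _BLOCK]
        sub = H[:, cols]
        code = np.where(sub < 0, 2, sub).astype(np.uint64)
        bits = (code << shifts[: cols.size]).sum(axis=1, dtype=np.uint64)
        x = (bits[ia] ^ bits[ib])[alive]
        mism = x != 0
        lowbit = x[mism] & (np.uint64(0) - x[mism])
        fm = (np.log2(lowbit.astype(np.float64)).astype(np.int64) // 2)
        dead_at = np.cumsum(np.bincount(fm, minlength=cols.size))
        n_alive = int(alive.sum())
        e_vals = (n_alive - dead_at) / total_pairs
        below = e_vals < cutoff
        stop = int(np.argmax(below)) + 1 if below.any() else cols.size
        out_pos.extend(int(p) for p in positions[cols[:stop]])
        out_ehh.extend(float(v) for v in e_vals[:stop])
        if below.any():
            break
        alive[alive] = ~mism
    return out_pos, out_ehh


def ehh(H, positions, core: int, direction: str = "both",
        cutoff: float = 0.0, max_gap_bp: int = 10**12) -> pd.DataFrame:
    """EHH curve around a core SNP for one population sample.

    Parameters
    ----------
    H
        Haplotype matrix (rows = haplotypes) for the population.
    positions
        1-based physical positions per column of ``H``.
    core
        Column index of the core SNP.
    direction
        "left", "right" or "both".
    cutoff, max_gap_bp
        Truncation rules (defaults keep the full curve).

    Returns a DataFrame with columns ``position``, ``distance`` (signed bp
    from the core) and ``ehh``; EHH at the core itself is 1 by definition
    and the curve is non-increasing away from it.
    """
    H = np.asarray(H)
    if H.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    if not 0 <= core < H.shape[1]:
        raise ValueError(f"core index {core} out of range")
    rows = [(int(positions[core]), 0, 1.0)]
    if direction in ("left", "both"):
        p, e = _ehh_one_direction(H, positions, core, -1, cutoff, max_gap_bp)
        rows = [(pi, pi - int(positions[core]), ei) for pi, ei in zip(p[::-1], e[::-1])] + rows
    if direction in ("right", "both"):
        p, e = _ehh_one_direction(H, positions, core, +1, cutoff, max_gap_bp)
        rows = rows + [(pi, pi - int(positions[core]), ei) for pi, ei in zip(p, e)]
    return pd.DataFrame(rows, columns=["position", "distance", "ehh"])


def ihh(H, positions, core: int, config: XPEHHConfig | None = None,
        _pair_idx=None) -> float:
    """Integrated EHH (trapezoid over physical distance, both directions)."""
    config = config or XPEHHConfig()
    total = 0.0
    for step in (-1, +1):
        pos, vals = _ehh_one_direction(H, positions, core,
                                       step, config.ehh_cutoff, config.max_gap_bp,
                                       pair_idx=_pair_idx)
        prev_p, prev_e = int(positions[core]), 1.0
        for p, e in zip(pos, vals):
            total += abs(p - prev_p) * (e + prev_e) / 2.0
            prev_p, prev_e = p, e
    return total


def xpehh(H_target, H_ref, positions, config: XPEHHConfig | None = None) -> pd.DataFrame:
    """XP-EHH track: raw ln(iHH_target / iHH_ref) and its z-normalization.

    Both panels must cover the same site set.  Sites where either iHH is 0
    are flagged missing and excluded from the normalization.  Maximal
    normalized scores support selection in the target population; minimal
    scores support selection in the reference.
    """
    config = config or XPEHHConfig()
    H_target = np.asarray(H_target)
    H_ref = np.asarray(H_ref)
    if H_target.shape[1] != H_ref.shape[1]:
        raise ValueError("target and reference panels must share the site set")
    S = H_target.shape[1]
    raw = np.full(S, np.nan)
    pairs_t = np.triu_indices(H_target.shape[0], 1)
    pairs_r = np.triu_indices(H_ref.shape[0], 1)
    for j in range(S):
        it = ihh(H_target, positions, j, config, _pair_idx=pairs_t)
        ir = ihh(H_ref, positions, j, config, _pair_idx=pairs_r)
        if it > 0 and ir > 0:
            raw[j] = np.log(it / ir)
    scored = ~np.isnan(raw)
    if scored.sum() < config.min_scored:
        raise ValueError("fewer than 2 scored sites; cannot normalize XP-EHH")
    mu = raw[scored].mean()
    sd = raw[scored].std()
    z = (raw - mu) / sd if sd > 0 else np.where(scored, 0.0, np.nan)
    return pd.DataFrame({
        "position": np.asarray(positions, dtype=np.int64),
        "raw": raw,
        "score": z,
        "missing": ~scored,
    })


# ---------------------------------------------------------------------------
# D statistic
# ---------------------------------------------------------------------------

def d_statistic(pw, px, py, pz, block_size: int = 100):
    """Four-population D (ABBA/BABA) with a delete-one block jackknife.

    Per site: ``ABBA = (1-pw) px py (1-pz)``, ``BABA = pw (1-px) py (1-pz)``;
    ``D = sum(ABBA - BABA) / sum(ABBA + BABA)``.  The standard error comes
    from a delete-one jackknife over consecutive blocks of ``block_size``
    SNPs (guarding against linkage), and ``Z = D / SE``.

    Returns ``(D, Z, SE)``; all NaN if ``sum(ABBA + BABA) == 0``.
    """
    pw, px, py, pz = (np.asarray(a, dtype=float) for a in (pw, px, py, pz))
    abba = (1 - pw) * px * py * (1 - pz)
    baba = pw * (1 - px) * py * (1 - pz)
    num = abba - baba
    den = abba + baba
    tot_den = den.sum()
    if tot_den == 0:
        return np.nan, np.nan, np.nan
    d = num.sum() / tot_den
    n_blocks = int(np.ceil(len(num) / block_size))
    if n_blocks < 2:
        return d, np.nan, np.nan
    d_jack = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        num_b = num.sum() - num[sl].sum()
        den_b = den.sum() - den[sl].sum()
        d_jack[b] = num_b / den_b if den_b != 0 else d
    se = np.sqrt((n_blocks - 1) / n_blocks * ((d_jack - d_jack.mean()) ** 2).sum())
    z = d / se if se > 0 else np.nan
    return d, z, se
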