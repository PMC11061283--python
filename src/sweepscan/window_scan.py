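"""Turn per-SNP score tracks into candidate regions.

The scan follows a fixed recipe: sliding windows of 20 SNPs with a step of
5 SNPs; window PBS = mean of the 20 per-SNP PBS values; window XP-EHH = max
of the 20 per-SNP scores; windows (or, for the SNP-level XP-EHH scan, single
SNPs) in the 99th percentile are merged when at most 10 kb apart; the ten
top-scoring merged regions per method are tested by resampling random score
units, filtered on that p-value, extended by 50 kb flanks, and unioned
across methods into the final non-overlapping candidate regions.

Reference-direction scans (selection in the *reference* population) are run by
negating the XP-EHH track and role-swapping the PBS populations upstream,
so that "top" always means the upper tail here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Region

__all__ = [
    "ScanConfig", "make_windows", "top_windows", "top_snps_xpehh",
    "fisher_combine", "resample_significance", "finalize_regions",
]

METHOD_PBS = "PBS"
METHOD_XPEHH = "XPEHH"
METHOD_FISHER = "Fisher"


@dataclass
class ScanConfig:
    """Scan recipe parameters.

    The per-method significance thresholds default to the genome-scale
    values (2e-5 XP-EHH, 2e-4 PBS, 2e-3 Fisher).  On short synthetic
    tracks the achievable resampling p is floored near 1/(number of score
    units), so desk-scale runs should set thresholds accordingly (the
    bundled demo configuration does).
    """

    window_snps: int = 20
    step_snps: int = 5
    merge_gap_bp: int = 10_000
    flank_bp: int = 50_000
    percentile: float = 0.99
    top_k: int = 10
    p_thresholds: dict = field(default_factory=lambda: {
        METHOD_XPEHH: 2e-5, METHOD_PBS: 2e-4, METHOD_FISHER: 2e-3,
    })
    n_resamples: dict = field(default_factory=lambda: {
        METHOD_XPEHH: 1_000_000, METHOD_PBS: 100_000, METHOD_FISHER: 100_000,
    })

    def __post_init__(self) -> None:
        for m, t in self.p_thresholds.items():
            if not 0 < t < 1:
                raise ValueError(f"threshold for {m} must lie in (0, 1)")
            if self.n_resamples.get(m, 0) < 1 / t:
                raise ValueError(
                    f"n_resamples[{m}] must be >= 1/threshold to resolve p < {t}"
                )


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(track: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """Sliding 20-SNP / step-5 windows over a per-SNP track.

    ``track`` needs columns ``position`` and ``pbs`` and/or ``xpehh``;
    rows with a missing (NaN) score in any present score column are
    excluded before windows are indexed.  A trailing remainder shorter
    than the window produces no window.
    """
    config = config or ScanConfig()
    w, s = config.window_snps, config.step_snps
    score_cols = [c for c in ("pbs", "xpehh") if c in track.columns]
    if not score_cols:
        raise ValueError("track must contain a 'pbs' and/or 'xpehh' column")
    clean = track.dropna(subset=score_cols).reset_index(drop=True)
    n = len(clean)
    empty_cols = ["start_idx", "end_idx", "start_bp", "end_bp"] \
        + [{"pbs": "pbs_mean", "xpehh": "xpehh_max"}[c] for c in score_cols]
    if n < w:  # a trailing remainder shorter than one window yields no window
        return pd.DataFrame({c: [] for c in empty_cols})
    starts = np.arange(0, n - w + 1, s)
    pos = clean["position"].to_numpy()
    out = {
        "start_idx": starts,
        "end_idx": starts + w - 1,
        "start_bp": pos[starts],
        "end_bp": pos[starts + w - 1],
    }
    for col in score_cols:
        vals = clean[col].to_numpy()
        windows = np.lib.stride_tricks.sliding_window_view(vals, w)[starts]
        if col == "pbs":
            out["pbs_mean"] = windows.mean(axis=1)
        else:
            out["xpehh_max"] = windows.max(axis=1)
    return pd.DataFrame(out)


def _merge_intervals(items, gap_bp: int):
    """Chain-merge (start, end, score) triples when gaps are <= gap_bp.

    Gap is measured between nearest endpoints; the merged score is the max
    member score.  Input must be sorted by start.
    """
    merged = []
    for start, end, score in items:
        if merged and start - merged[-1][1] <= gap_bp:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], end), max(prev[2], score))
        else:
            merged.append((start, end, score))
    return merged


def top_windows(windows: pd.DataFrame, score_col: str, config: ScanConfig | None = None,
                chrom: str = "chr1", method: str = METHOD_PBS) -> list[Region]:
    """Keep windows at or above the empirical 99th percentile and merge them.

    Windows whose bp gap is at most ``merge_gap_bp`` join the same region;
    the region score is the top member window score.
    """
    config = config or ScanConfig()
    scores = windows[score_col].to_numpy()
    thr = np.quantile(scores, config.percentile)
    kept = windows.loc[scores >= thr].sort_values("start_bp")
    items = list(zip(kept["start_bp"].astype(int), kept["end_bp"].astype(int),
                     kept[score_col].astype(float)))
    merged = _merge_intervals(items, config.merge_gap_bp)
    return [Region(chrom=chrom, start=a, end=b, methods=frozenset({method}),
                   scores=((method, sc),)) for a, b, sc in merged]


def top_snps_xpehh(track: pd.DataFrame, config: ScanConfig | None = None,
                   tail: str = "upper", chrom: str = "chr1") -> list[Region]:
    """SNP-level XP-EHH regions.

    ``tail="upper"`` keeps SNPs at or above the 99th percentile (selection
    in the target population); ``tail="lower"`` keeps SNPs at or below the
    1st percentile (selection in the reference) by negating the track, so
    one code path serves both.  Kept SNPs at most 10 kb apart chain into a
    region whose endpoints are the two most distant kept SNPs; an isolated
    SNP gives a zero-length region (later widened by the flank).
    """
    config = config or ScanConfig()
    clean = track.dropna(subset=["score"])
    scores = clean["score"].to_numpy(dtype=float)
    if tail == "lower":
        scores = -scores
    elif tail != "upper":
        raise ValueError("tail must be 'upper' or 'lower'")
    thr = np.quantile(scores, config.percentile)
    keep = scores >= thr
    pos = clean["position"].to_numpy()[keep]
    sc = scores[keep]
    order = np.argsort(pos)
    items = [(int(p), int(p), float(s)) for p, s in zip(pos[order], sc[order])]
    merged = _merge_intervals(items, config.merge_gap_bp)
    return [Region(chrom=chrom, start=a, end=b, methods=frozenset({METHOD_XPEHH}),
                   scores=((METHOD_XPEHH, s),)) for a, b, s in merged]


# ---------------------------------------------------------------------------
# Fisher combination
# ---------------------------------------------------------------------------

def fisher_combine(windows: pd.DataFrame) -> pd.DataFrame:
    """Add the Fisher score column to a window table.

    The percentile rank of a window is the upper-tail empirical proportion
    ``#{windows with score >= this one} / N`` (ties counted as >=, the
    conservative direction), so the best of N windows has rank 1/N and
    ``fisher = -log10(rank_PBS) - log10(rank_XPEHH)`` stays finite.
    Depends on the two score columns only through their ranks.
    """
    if not {"pbs_mean", "xpehh_max"} <= set(windows.columns):
        raise ValueError("windows must carry pbs_mean and xpehh_max")
    n = len(windows)

    def upper_rank(col):
        v = pd.Series(windows[col].to_numpy())
        # #{x_j >= x_i} = N - #{x_j < x_i}; ties count as >=
        count_ge = n - v.rank(method="max", ascending=True).to_numpy() + 1
        return count_ge / n

    out = windows.copy()
    out["fisher"] = -np.log10(upper_rank("pbs_mean")) - np.log10(upper_rank("xpehh_max"))
    return out


# ---------------------------------------------------------------------------
# Resampling significance
# ---------------------------------------------------------------------------

def resample_significance(region_score: float, unit_scores, n_resamples: int,
                          rng: np.random.Generator) -> float:
    """Resampling p-value for a region's top score.

    Samples ``n_resamples`` score units (SNPs for XP-EHH, 20-SNP windows
    for PBS/Fisher) uniformly with replacement from the genome-wide track
    and reports ``p = (1 + #{sampled >= region score}) / (1 + M)``, the
    add-one estimator that avoids exact zeros.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    unit_scores = np.asarray(unit_scores, dtype=float)
    unit_scores = unit_scores[~np.isnan(unit_scores)]
    draws = rng.choice(unit_scores, size=int(n_resamples), replace=True)
    k = int((draws >= region_score).sum())
    return (1 + k) / (1 + n_resamples)


def attach_pvalues(regions: list[Region], unit_scores, method: str,
                   config: ScanConfig, rng: np.random.Generator) -> list[Region]:
    """Resampling p for each region's top score under one method."""
    from dataclasses import replace
    out = []
    for r in regions:
        p = resample_significance(r.score_dict()[method], unit_scores,
                                  config.n_resamples[method], rng)
        out.append(replace(r, pvalue=p))
    return out


# ---------------------------------------------------------------------------
# Final merge
# ---------------------------------------------------------------------------

def finalize_regions(per_method: dict[str, list[Region]],
                     config: ScanConfig | None = None,
                     chrom_length: int | None = None) -> list[Region]:
    """Top-10 per method, p-filtered, 50 kb flanks, union across methods.

    Each method contributes its ``top_k`` regions by score that pass its
    p-value threshold; every kept region is extended by ``flank_bp`` on
    both sides (clipped to ``[1, chrom_length]``), and regions overlapping
    by at least 1 bp are unioned, combining their method provenance.  The
    result is sorted and idempotent under re-merging.
    """
    config = config or ScanConfig()
    flanked = []
    for method, regions in per_method.items():
        thr = config.p_thresholds.get(method, 1.0)
        ranked = sorted(regions, key=lambda r: -r.score_dict()[method])[:config.top_k]
        for r in ranked:
            if r.pvalue is not None and r.pvalue >= thr:
                continue
            start = max(1, r.start - config.flank_bp)
            end = r.end + config.flank_bp
            if chrom_length is not None:
                end = min(end, chrom_length)
            flanked.append(Region(chrom=r.chrom, start=start, end=end,
                                  methods=r.methods, scores=r.scores, pvalue=r.pvalue))
    flanked.sort(key=lambda r: (r.chrom, r.start, r.end))
    final: list[Region] = []
    for r in flanked:
        if final and final[-1].overlaps(r):
            prev = final[-1]
            scores = dict(prev.scores)
            for m, v in r.scores:
                scores[m] = max(scores.get(m, -np.inf), v)
            pvals = [p for p in (prev.pvalue, r.pvalue) if p is not None]
            final[-1] = Region(
                chrom=prev.chrom,
                start=min(prev.start, r.start),
                end=max(prev.end, r.end),
                methods=prev.methods | r.methods,
                scores=tuple(sorted(scores.items())),
                pvalue=min(pvals) if pvals else None,
            )
        else:
            final.append(r)
    return final
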