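"""Candidate-SNP lookup against an external association table, and the
blood-phenotype resampling enrichment test.

Candidate SNPs are matched against a position-keyed summary-statistics
table (an exact position match, else the closest table SNP within 50 bp up-
or downstream).  A phenotype association counts as significant when
log10(p) is below log10(5e-8 / n_phenotypes) — for the 1,470 phenotypes of
the emulated biobank screen that cutoff is -10.47.  Enrichment of
blood-count associations among candidates is tested by resampling sets of
100 bp windows from the universe of windows with at least one significant
association and comparing the observed number of blood-associated windows
with the resampled null; with draws taken without replacement the null is
hypergeometric, which the Monte-Carlo p converges to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "lookup_candidate", "bonferroni_log10_cutoff", "significant_phenotypes",
    "blood_enrichment_test",
]

BLOOD_CATEGORY = "Blood count"
GENOME_WIDE_ALPHA = 5e-8


def lookup_candidate(position: int, table: pd.DataFrame,
                     window_bp: int = 50) -> pd.DataFrame | None:
    """Rows of the lookup table matching a candidate SNP.

    An exact position match is preferred; otherwise the nearest table SNP
    within ``window_bp`` up- or downstream (ties go to the smaller
    distance, then the lower position).  Returns None when nothing is
    within range (the "not present in the table" case).
    """
    pos = np.asarray(table["position"], dtype=np.int64)
    exact = table.loc[pos == position]
    if len(exact):
        return exact
    dist = np.abs(pos - position)
    in_range = dist <= window_bp
    if not in_range.any():
        return None
    candidates = table.loc[in_range].copy()
    candidates["_dist"] = dist[in_range]
    best_dist = candidates["_dist"].min()
    at_best = candidates.loc[candidates["_dist"] == best_dist]
    chosen_pos = at_best["position"].min()  # equidistant tie -> lower position
    return table.loc[pos == chosen_pos]


def bonferroni_log10_cutoff(n_phenotypes: int) -> float:
    """log10 p cutoff: genome-wide 5e-8 Bonferroni-shared over phenotypes.

    For 1,470 phenotypes this is log10(5e-8 / 1470) = -10.47 (2 d.p.).
    """
    if n_phenotypes <= 0:
        raise ValueError("n_phenotypes must be positive")
    return float(np.log10(GENOME_WIDE_ALPHA / n_phenotypes))


def significant_phenotypes(records: pd.DataFrame, n_phenotypes: int = 1470) -> pd.DataFrame:
    """Phenotype rows whose log10(p) clears the multiple-testing cutoff."""
    cutoff = bonferroni_log10_cutoff(n_phenotypes)
    with np.errstate(divide="ignore"):
        keep = np.log10(records["p"].to_numpy(dtype=float)) < cutoff
    return records.loc[keep]


def _window_id(positions, window_bp: int = 100) -> np.ndarray:
    return np.asarray(positions, dtype=np.int64) // window_bp


def blood_enrichment_test(candidate_positions, table: pd.DataFrame,
                          n_phenotypes: int = 1470, n_resamples: int = 10_000,
                          rng: np.random.Generator | None = None,
                          blood_category: str = BLOOD_CATEGORY,
                          strict_greater: bool = False,
                          lookup_window_bp: int = 50) -> dict:
    """Resampling test for an excess of blood-count associations.

    ``x`` candidates have at least one significant association (matched by
    the +/-50 bp rule); the observed statistic is how many of those have a
    significant blood-category association.  The null resamples ``x``
    100 bp windows without replacement from all windows in the table with
    at least one significant association, ``n_resamples`` times;
    p = proportion of resamples whose blood-window count is >= the
    observed count (> with ``strict_greater``).

    Returns a dict with observed counts, x, the universe composition and
    the resampling p (None with x = 0, when the test is undefined).
    """
    rng = rng or np.random.default_rng(0)
    sig = significant_phenotypes(table, n_phenotypes)
    sig_windows = _window_id(sig["position"])
    blood_windows = set(_window_id(sig.loc[sig["category"] == blood_category, "position"]))
    universe = np.unique(sig_windows)

    x = 0
    observed = 0
    for pos in candidate_positions:
        rec = lookup_candidate(int(pos), table, lookup_window_bp)
        if rec is None:
            continue
        hits = significant_phenotypes(rec, n_phenotypes)
        if len(hits) == 0:
            continue
        x += 1
        if (hits["category"] == blood_category).any():
            observed += 1

    if x == 0:
        return {"x": 0, "observed": 0, "universe_size": int(universe.size),
                "n_blood_windows": len(blood_windows), "p": None}
    if x > universe.size:
        raise ValueError("more candidate hits than universe windows")
    is_blood = np.isin(universe, sorted(blood_windows))
    counts = np.empty(n_resamples, dtype=int)
    for i in range(n_resamples):
        draw = rng.choice(universe.size, size=x, replace=False)
        counts[i] = int(is_blood[draw].sum())
    p = float((counts > observed).mean() if strict_greater else (counts >= observed).mean())
    return {"x": x, "observed": observed, "universe_size": int(universe.size),
            "n_blood_windows": int(is_blood.sum()), "p": p}
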