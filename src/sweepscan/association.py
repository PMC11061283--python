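"""Phenotype covariate correction and mixed-model association.

The association stage is two-step: each raw phenotype is first regressed
on its covariate group (age + sex, or age + sex + height for the body-size
and spirometry measurements) by ordinary least squares and replaced by the
residuals; each candidate SNP is then tested against each corrected
phenotype under a univariate linear mixed model

    y = mu + g * beta + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I),

with K the centred relatedness matrix K = W W' / m computed from
mean-centred genotype dosages.  Variance components are estimated by
maximum likelihood after a one-off eigendecomposition of K (EMMA-style
one-dimensional search over the variance ratio), and beta gets a Wald
test.  P-values are Benjamini-Hochberg adjusted across SNPs within each
phenotype; adjusted p < 0.05 is reported as suggestive and p < 0.01
(0.05 / 5 correlated phenotype groups) as strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COVARIATE_GROUPS", "correct_phenotype", "kinship_matrix", "LmmResult",
    "lmm_assoc", "adjust_and_call",
]

COVARIATE_GROUPS = {
    "age_sex": ["age", "sex"],
    "age_sex_height": ["age", "sex", "height"],
}

PHENOTYPE_GROUP = {
    "heart_rate": "age_sex", "haemoglobin": "age_sex",
    "blood_pressure": "age_sex", "bmi": "age_sex",
    "chest_depth": "age_sex_height", "waist": "age_sex_height",
    "weight": "age_sex_height", "fev1": "age_sex_height",
    "pef": "age_sex_height", "fvc": "age_sex_height",
}


def correct_phenotype(raw, covariates: pd.DataFrame, group: str = "age_sex") -> np.ndarray:
    """OLS residuals of a raw phenotype on intercept + covariate group.

    Rows with a missing phenotype stay missing; rows with missing
    covariates are not allowed.  Collinear (rank-deficient) covariates
    raise.
    """
    if group not in COVARIATE_GROUPS:
        raise ValueError(f"unknown covariate group {group!r}")
    cols = COVARIATE_GROUPS[group]
    y = np.asarray(raw, dtype=float)
    X = np.column_stack([np.ones(len(y))] + [covariates[c].to_numpy(dtype=float)
                                             for c in cols])
    if np.isnan(X).any():
        raise ValueError("covariates must be complete")
    ok = ~np.isnan(y)
    if ok.sum() < 5:
        raise ValueError("need >= 5 complete rows")
    if np.linalg.matrix_rank(X[ok]) < X.shape[1]:
        raise ValueError("collinear covariates (rank-deficient design)")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - X[ok] @ beta
    return out


def kinship_matrix(G) -> np.ndarray:
    """Centred relatedness matrix K = W W' / m from 0/1/2 dosages (n x m)."""
    G = np.asarray(G, dtype=float)
    W = G - G.mean(axis=0, keepdims=True)
    return W @ W.T / G.shape[1]


@dataclass
class LmmResult:
    beta: float
    se: float
    pvalue: float
    sigma_g2: float
    sigma_e2: float


class LinearMixedModel:
    """Univariate LMM with a fixed kinship matrix, eigendecomposed once.

    ML over the variance ratio gamma = sg2 / se2 is a one-dimensional
    bounded search on log10(gamma); given gamma, beta and the residual
    variance have closed forms in the rotated coordinates.
    """

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T):
            raise ValueError("kinship matrix must be symmetric")
        self.n = K.shape[0]
        self.eigvals, self.eigvecs = np.linalg.eigh(K)
        self.eigvals = np.maximum(self.eigvals, 0.0)

    def _profile_ll(self, log10_gamma: float, ys: np.ndarray, Xs: np.ndarray):
        gamma = 10.0 ** log10_gamma
        w = gamma * self.eigvals + 1.0          # H = se2 * diag(w)
        Xw = Xs / w[:, None]
        XtX = Xs.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (r / w))
        n = self.n
        se2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * se2) + np.log(w).sum() + n)
        return ll, beta, se2, XtX

    def fit(self, g, y) -> LmmResult:
        """Wald test of the SNP effect; monomorphic SNPs are flagged NaN."""
        g = np.asarray(g, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(g)
        if ok.sum() != self.n:
            raise ValueError("missing values: subset K and refit")
        if np.ptp(g) == 0:
            return LmmResult(np.nan, np.nan, np.nan, np.nan, np.nan)
        ys = self.eigvecs.T @ y
        Xs = self.eigvecs.T @ np.column_stack([np.ones(self.n), g])
        res = optimize.minimize_scalar(
            lambda lg: -self._profile_ll(lg, ys, Xs)[0],
            bounds=(-6.0, 6.0), method="bounded",
            options={"xatol": 1e-8})
        lg = float(res.x)
        # The boundary gamma -> 0 (pure OLS) competes with the interior optimum.
        if self._profile_ll(-12.0, ys, Xs)[0] > self._profile_ll(lg, ys, Xs)[0]:
            lg = -12.0
        ll, beta, se2, XtX = self._profile_ll(lg, ys, Xs)
        gamma = 10.0 ** lg
        # Wald variance with the unbiased residual scale, so the model
        # collapses exactly onto the OLS t-test when K carries no signal.
        cov = se2 * self.n / (self.n - 2) * np.linalg.inv(XtX)
        se = float(np.sqrt(cov[1, 1]))
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), df=self.n - 2)
        return LmmResult(beta=float(beta[1]), se=se, pvalue=float(p),
                         sigma_g2=gamma * se2, sigma_e2=se2)


def lmm_assoc(genotypes, phenotype, kinship: np.ndarray) -> pd.DataFrame:
    """Test each SNP column (0/1/2 dosages) against one corrected phenotype.

    Returns a DataFrame with beta, se and p per SNP; monomorphic SNPs are
    flagged with NaN and no test.
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    model = LinearMixedModel(kinship)
    rows = []
    for j in range(G.shape[1]):
        res = model.fit(G[:, j], phenotype)
        rows.append((j, res.beta, res.se, res.pvalue))
    return pd.DataFrame(rows, columns=["snp", "beta", "se", "p"])


def adjust_and_call(pvalues: pd.DataFrame, suggestive: float = 0.05,
                    strict: float = 0.01) -> pd.DataFrame:
    """BH-adjust p across SNPs within each phenotype and tier the calls.

    ``pvalues`` has columns snp, phenotype, p.  Adjusted p < 0.05 is
    "suggestive"; adjusted p < 0.01 (0.05 over 5 correlated phenotype
    groups) is "strict".
    """
    out = []
    for phen, sub in pvalues.groupby("phenotype", sort=False):
        sub = sub.copy()
        ok = sub["p"].notna()
        adj = np.full(len(sub), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(sub.loc[ok, "p"], method="fdr_bh")[1]
        sub["p_adjusted"] = adj
        sub["call"] = np.select(
            [sub["p_adjusted"] < strict, sub["p_adjusted"] < suggestive],
            ["strict", "suggestive"], default="ns")
        out.append(sub)
    return pd.concat(out, ignore_index=True)
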