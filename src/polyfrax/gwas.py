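"""Per-variant association testing with covariate adjustment.

Each variant is tested by ordinary least squares of the phenotype on
(dosage, covariates, intercept); the per-variant fits are computed jointly
via Frisch-Waugh-Lovell residualization, which is algebraically identical
to fitting every variant's full OLS model but runs as a handful of matrix
products. Genetic principal components are computed from the
column-standardized dosage matrix and passed in as fixed covariates — the
synthetic cohorts carry no relatedness, so a mixed model's random effect
would be unidentifiable and the adjustment reduces to fixed-effects OLS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GenotypeMatrix


def compute_pcs(G: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Top-k principal-component scores of the standardized dosage matrix.

    Columns are ordered by decreasing explained variance and are mutually
    orthogonal (left singular vectors scaled by singular values).
    """
    n, m = G.dosages.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n_individuals, n_variants)={min(n, m)}")
    X = G.dosages - G.dosages.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank {rank} of the standardized dosages")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k] * s[:k]


def run_gwas(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS association of ``y`` with each variant, adjusted for covariates.

    Returns one row per variant with variant metadata plus beta (effect per
    dosage unit of the effect allele), se, two-sided p from the t
    distribution, and n. Monomorphic variants are reported with beta 0 and
    infinite se so p-value thresholding naturally drops them.
    """
    y = np.asarray(y, dtype=float)
    n, m = G.dosages.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    if np.isnan(y).any() or np.isnan(G.dosages).any():
        raise ValueError("missing values are not supported")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        C = np.column_stack([np.ones(n), covariates])
        rank = np.linalg.matrix_rank(C)
        if rank < C.shape[1]:
            # identify an offending column for the error message
            bad = None
            for j in range(1, C.shape[1]):
                if np.linalg.matrix_rank(C[:, : j + 1]) < j + 1:
                    bad = j - 1
                    break
            raise ValueError(
                f"covariate matrix is rank-deficient (covariate column {bad})"
            )
    p_cov = C.shape[1]
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough observations for the covariate-adjusted fit")

    # residualize phenotype and dosages on the covariates (incl. intercept)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = G.dosages - Q @ (Q.T @ G.dosages)

    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    syy = float(y_r @ y_r)
    if syy <= 1e-12 * max(1.0, float(y @ y)):
        # covariates explain the phenotype exactly: nothing left to test
        out = G.variant_meta.copy().reset_index(drop=True)
        out["beta"] = 0.0
        out["se"] = np.inf
        out["pvalue"] = 1.0
        out["n"] = n
        return out
    mono = sxx <= 1e-12
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    ok = ~mono
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta[ok] * sxy[ok]
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    tstat = np.zeros(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat[ok] = beta[ok] / se[ok]
    # perfectly explained phenotype (zero residual variance): no evidence
    tstat[~np.isfinite(tstat)] = 0.0
    pval = np.ones(m)
    pval[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    out = G.variant_meta.copy().reset_index(drop=True)
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = pval
    out["n"] = n
    return out


def write_summary_stats(summaries: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]
    summaries[cols].rename(columns={"id": "variant_id"}).to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.rename(columns={"variant_id": "id"})
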