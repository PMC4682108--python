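"""PCA of the genomic relationship matrix and single-marker GWAS.

PCA operates on the GRM (equivalent, up to scaling, to a PCA of the
standardized genotype matrix); eigenvector signs follow the convention that
each column's largest-magnitude element is positive, for reproducible
output.  GWAS is plain per-SNP ordinary least squares of the phenotype on
[covariates, dosage] with complete-case handling per SNP; no polygenic
adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeMatrix
from .grm import GRM, eigendecompose_grm


@dataclass
class PCAResult:
    """Top-k spectral pairs of a GRM with variance proportions.

    Proportions are eigenvalue shares of the positive part of the full
    spectrum (negative round-off eigenvalues clipped at zero).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    proportions: np.ndarray


def pca_grm(grm: GRM, k: int) -> PCAResult:
    """Top-k principal components of a genomic relationship matrix."""
    n = grm.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    eig = eigendecompose_grm(grm)
    vals = eig.values[:k].copy()
    vecs = eig.vectors[:, :k].copy()
    # sign convention: largest-magnitude element of each PC positive
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    clipped = eig.clipped_values()
    total = clipped.sum()
    props = np.maximum(vals, 0.0) / total if total > 0 else np.zeros(k)
    return PCAResult(vals, vecs, props)


def gwas_linear(
    g: GenotypeMatrix, y, x_cov: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-SNP OLS association: y ~ [covariates, dosage].

    ``x_cov`` must contain an intercept column if one is wanted; the
    default is intercept-only.  Samples missing a SNP are dropped for that
    SNP.  Returns a tidy frame with snp_id, chrom, bp, a1, beta, se, t, p
    and n (samples used).  Monomorphic-in-sample SNPs are flagged with NaN
    effect estimates rather than raising.  At an exact fit the p-value is
    reported at the smallest positive float.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = g.n_samples
    if y.size != n:
        raise ValueError("phenotype length does not match genotypes")
    if x_cov is None:
        x_cov = np.ones((n, 1))
    x_cov = np.asarray(x_cov, dtype=np.float64)
    if x_cov.ndim == 1:
        x_cov = x_cov[:, None]
    c = x_cov.shape[1]
    if n < c + 2:
        raise ValueError("need at least c + 2 samples")

    d = g.dosages
    obs = d != MISSING
    out = np.full((g.n_snps, 5), np.nan)  # beta, se, t, p, n

    # fast path: SNPs with complete data share one covariate projection
    q, _ = np.linalg.qr(x_cov)
    y_res_full = y - q @ (q.T @ y)
    rss0_full = float(y_res_full @ y_res_full)

    complete = obs.all(axis=0)
    tiny = np.finfo(np.float64).tiny

    if complete.any():
        s = d[:, complete].astype(np.float64)
        s_res = s - q @ (q.T @ s)
        ss = (s_res**2).sum(axis=0)
        poly = (np.ptp(s, axis=0) > 0) & (ss > 0)
        sy = s_res.T @ y_res_full
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(poly, sy / ss, np.nan)
        df = n - c - 1
        rss = rss0_full - np.where(poly, beta**2 * ss, 0.0)
        rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / df / ss)
            t = beta / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p = np.clip(p, tiny, 1.0)
        block = np.column_stack([beta, se, t, p, np.full(beta.size, n)])
        block[~poly, :4] = np.nan
        out[complete] = block

    for j in np.flatnonzero(~complete):
        keep = obs[:, j]
        nj = int(keep.sum())
        if nj < c + 2:
            out[j, 4] = nj
            continue
        sj = d[keep, j].astype(np.float64)
        if np.ptp(sj) == 0:
            out[j, 4] = nj
            continue
        xj = np.column_stack([x_cov[keep], sj])
        yj = y[keep]
        coef, _, rank, _ = np.linalg.lstsq(xj, yj, rcond=None)
        if rank < c + 1:
            out[j, 4] = nj
            continue
        resid = yj - xj @ coef
        df = nj - c - 1
        rss = float(resid @ resid)
        xtx_inv = np.linalg.inv(xj.T @ xj)
        se_j = float(np.sqrt(max(rss, 0.0) / df * xtx_inv[-1, -1]))
        beta_j = float(coef[-1])
        t_j = beta_j / se_j if se_j > 0 else np.inf * np.sign(beta_j)
        p_j = max(2.0 * float(sps.t.sf(abs(t_j), df)), tiny)
        out[j] = [beta_j, se_j, t_j, p_j, nj]

    return pd.DataFrame({
        "snp_id": g.snps["snp_id"],
        "chrom": g.snps["chrom"],
        "bp": g.snps["bp"],
        "a1": g.snps["a1"],
        "beta": out[:, 0],
        "se": out[:, 1],
        "t": out[:, 2],
        "p": out[:, 3],
        "n": out[:, 4].astype(int),
    })
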