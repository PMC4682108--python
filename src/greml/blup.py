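"""BLUP of genetic values and SNP effects; polygenic scoring of new cohorts.

Given a REML fit with V = G sigma2_g + I sigma2_e and GLS residual
r = y - X beta, the best linear unbiased predictions are

    g_hat = sigma2_g * G * V^-1 r          (individual genetic values)
    a_hat = (sigma2_g / M) * Z' * V^-1 r   (per-SNP effects)

which satisfy g_hat = Z a_hat exactly because G = Z Z' / M.  A SNP-effect
table carries the training-cohort allele mean and s.d. so a new cohort can
be scored as P_i = sum_j a_j * (s_ij - mean_j) / sd_j using *training*
statistics only.  Scores are centred; no intercept is added (correlation
accuracy measures are translation invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .genotype_io import MISSING, GenotypeMatrix, StandardizedGenotypes
from .mlm import MLMData, VarianceComponents


class AlleleMismatchError(ValueError):
    """A table SNP's reference allele matches neither A1 nor A2 of the cohort."""


class SnpAbsentError(KeyError):
    """A SNP in the effect table is absent from the cohort to score."""


@dataclass
class SNPEffectTable:
    """Per-SNP BLUP effects plus training allele statistics.

    ``table`` columns: snp_id, a1 (reference allele the effect refers to),
    mean (training mean dosage), sd (training scaling s.d.), effect (trait
    units per s.d. of standardized genotype).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "a1", "mean", "sd", "effect"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"effect table missing columns: {missing}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("snp_ids in effect table must be unique")
        if (self.table["sd"] <= 0).any():
            raise ValueError("effect table s.d. must be positive")
        self.table = self.table.reset_index(drop=True)

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "SNPEffectTable":
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "a1": str})
        return cls(df)


@dataclass
class PolygenicScores:
    """Centred polygenic scores, one per sample."""

    scores: np.ndarray
    n_snps_used: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


def _v_inv_times(data: MLMData, vc: VarianceComponents, r: np.ndarray) -> np.ndarray:
    """V^-1 r with V = (sigma2_g/M) Z Z' + sigma2_e I.

    Uses the Woodbury identity through Z when available (an M x M solve),
    otherwise a dense Cholesky solve on the explicit GRM.
    """
    sg, se = vc.sigma2_g, vc.sigma2_e
    if data.z is not None:
        zmat = data.z.values
        m = data.z.n_snps
        if sg <= 0:
            return r / se
        ztz = zmat.T @ zmat
        core = ztz + (m * se / sg) * np.eye(m)
        try:
            cho = sla.cho_factor(core)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular V in BLUP") from err
        return (r - zmat @ sla.cho_solve(cho, zmat.T @ r)) / se
    v = sg * data.grm.values + se * np.eye(data.n)
    try:
        cho = sla.cho_factor(v)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular V in BLUP") from err
    return sla.cho_solve(cho, r)


def blup_genetic_values(
    data: MLMData, vc: VarianceComponents, beta: np.ndarray
) -> np.ndarray:
    """BLUP of individual genetic values: g_hat = sigma2_g G V^-1 (y - X beta)."""
    r = data.y - data.x @ np.asarray(beta, dtype=np.float64).ravel()
    vir = _v_inv_times(data, vc, r)
    if data.z is not None:
        zmat = data.z.values
        return (vc.sigma2_g / data.z.n_snps) * (zmat @ (zmat.T @ vir))
    return vc.sigma2_g * (data.grm.values @ vir)


def blup_snp_effects(
    z: StandardizedGenotypes,
    data: MLMData,
    vc: VarianceComponents,
    beta: np.ndarray,
    snps: pd.DataFrame | None = None,
) -> SNPEffectTable:
    """BLUP of SNP effects: a_hat = (sigma2_g / M) Z' V^-1 (y - X beta).

    ``snps`` (a .bim-style DataFrame with snp_id and a1) supplies the
    reference-allele labels for the table; without it the allele column is
    "." and scoring will skip allele reconciliation for those SNPs.
    """
    m = z.n_snps
    if data.grm is not None and data.grm.n_snps != m:
        raise ValueError(
            f"GRM was built from {data.grm.n_snps} SNPs but Z has {m}"
        )
    if data.z is not None and data.z.n_snps != m:
        raise ValueError("Z in data does not match the Z passed for effects")
    r = data.y - data.x @ np.asarray(beta, dtype=np.float64).ravel()
    vir = _v_inv_times(data, vc, r)
    effects = (vc.sigma2_g / m) * (z.values.T @ vir)
    if snps is not None:
        lookup = snps.set_index("snp_id")["a1"]
        a1 = lookup.reindex(z.snp_ids).to_numpy()
    else:
        a1 = np.full(m, ".", dtype=object)
    return SNPEffectTable(pd.DataFrame({
        "snp_id": z.snp_ids,
        "a1": a1,
        "mean": z.stats.mean,
        "sd": z.stats.sd,
        "effect": effects,
    }))


def polygenic_score(
    g_new: GenotypeMatrix, effects: SNPEffectTable
) -> PolygenicScores:
    """Score a cohort with a SNP-effect table: P_i = sum_j a_j (s_ij - mean_j)/sd_j.

    Training mean/sd from the table are always used (never the scored
    cohort's own statistics).  Allele reconciliation per SNP: if the
    cohort's A1 equals the table's reference allele the dosage is used
    as-is; if the cohort's A2 equals it the dosage is flipped to 2 - s;
    otherwise an error is raised.  Missing genotypes contribute 0 (training
    mean imputation).
    """
    tab = effects.table
    pos = pd.Index(g_new.snps["snp_id"]).get_indexer(tab["snp_id"])
    if (pos < 0).any():
        absent = tab["snp_id"].to_numpy()[pos < 0]
        raise SnpAbsentError(f"SNPs absent from cohort: {list(absent[:5])}")
    cohort_a1 = g_new.snps["a1"].to_numpy()[pos]
    cohort_a2 = g_new.snps["a2"].to_numpy()[pos]
    ref = tab["a1"].to_numpy()
    as_is = (ref == cohort_a1) | (ref == ".")
    flip = ~as_is & (ref == cohort_a2)
    bad = ~(as_is | flip)
    if bad.any():
        raise AlleleMismatchError(
            f"irreconcilable alleles for SNPs: {list(tab['snp_id'][bad][:5])}"
        )
    d = g_new.dosages[:, pos].astype(np.float64)
    obs = g_new.dosages[:, pos] != MISSING
    d = np.where(flip, 2.0 - d, d)
    zval = (d - tab["mean"].to_numpy()) / tab["sd"].to_numpy()
    zval[~obs] = 0.0
    scores = zval @ tab["effect"].to_numpy()
    return PolygenicScores(
        scores=scores,
        n_snps_used=obs.sum(axis=1),
        samples=g_new.samples[["fid", "iid"]].copy(),
    )


def prediction_accuracy(scores, y_true, h2: float):
    """Pearson accuracy of polygenic scores and its ratio to sqrt(h2).

    Returns (r, r / sqrt(h2)); sqrt(h2) is the theoretical maximum
    correlation between a genetic predictor and the phenotype.
    """
    s = np.asarray(getattr(scores, "scores", scores), dtype=np.float64).ravel()
    t = np.asarray(y_true, dtype=np.float64).ravel()
    if s.size != t.size:
        raise ValueError("scores and y_true must be the same length")
    if s.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if np.var(s) == 0 or np.var(t) == 0:
        raise ValueError("zero variance in scores or phenotypes")
    r = float(np.corrcoef(s, t)[0, 1])
    return r, r / float(np.sqrt(h2))
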