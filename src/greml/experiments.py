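"""Desk-scale genomic-prediction experiments.

Drives the full pipeline — simulate genotypes and trait, build an array
scenario, split into training and validation, fit REML on the training
GRM, BLUP the SNP effects, score the validation cohort — over a grid of
training sizes and replicates, and summarizes accuracy as the correlation
of the polygenic score with the validation phenotypes (r_pheno) and with
the true genetic values (r_gen).

Two theory-backed summaries are provided: the ratio of an achieved
correlation to its ceiling sqrt(h2), and the regression of 1/r_gen^2 on
1/N_train, whose intercept is expected to be one when accuracy follows the
classical N*h2/(N*h2 + M) law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blup import blup_snp_effects, polygenic_score, prediction_accuracy
from .genotype_io import compute_snp_stats, standardize
from .mlm import MLMData, gls_fixed_effects, reml_fit_eigen
from .simulate import (
    GenotypeSimSpec,
    TraitSimSpec,
    build_array_scenario,
    simulate_genotypes,
    simulate_trait,
    train_validation_split,
)


@dataclass
class InverseRegressionResult:
    """OLS of mean 1/r_gen^2 on 1/N_train."""

    intercept: float
    slope: float
    points: pd.DataFrame


def _child_seed(master: int, cell: int, replicate: int) -> int:
    """Deterministic per-cell seed: (master * 1000003 + 10007*cell + replicate)
    reduced mod 2^31 - 1.  Documented so any cell can be re-run alone."""
    return (master * 1000003 + 10007 * cell + replicate) % (2**31 - 1)


def run_prediction_experiment(
    genospec: GenotypeSimSpec,
    traitspec: TraitSimSpec,
    scenario: str,
    n_train_grid,
    n_replicates: int,
    seed: int,
    n_validation: int | None = None,
    qtn_on_array_frac: float = 0.2,
) -> pd.DataFrame:
    """One pipeline run per (n_train, replicate) cell.

    For each cell a fresh cohort of n_train + n_validation individuals is
    simulated (n_validation defaults to one ninth of n_train, i.e. a 90/10
    split).  ``genospec.n_snps``/``maf_range``/``ld_rho`` set the genome;
    ``genospec.n_samples`` is overridden by the cell's cohort size.  SNPs
    monomorphic in the training part are dropped before fitting.  REML uses
    the eigen-rotation fast path.  REML non-convergence flags the row and
    the run continues.

    Returns a tidy frame with one row per cell: n_train, h2, scenario,
    replicate, r_pheno, r_gen, r_over_max, sigma2_g, sigma2_e, h2_hat,
    m_array, converged.
    """
    grid = list(n_train_grid)
    if max(grid) > 10_000:
        raise ValueError("desk-scale driver: n_train capped at 10,000")
    rows = []
    for i, n_train in enumerate(grid):
        n_val = n_validation if n_validation is not None else max(
            1, int(round(n_train / 9))
        )
        for rep in range(n_replicates):
            cseed = _child_seed(seed, i, rep)
            gspec = GenotypeSimSpec(
                n_samples=n_train + n_val,
                n_snps=genospec.n_snps,
                maf_range=genospec.maf_range,
                ld_rho=genospec.ld_rho,
                seed=cseed,
            )
            geno = simulate_genotypes(gspec)
            trait = simulate_trait(
                geno, TraitSimSpec(traitspec.n_qtn, traitspec.h2, seed=cseed + 1)
            )
            array_idx = build_array_scenario(
                geno, trait, scenario, qtn_on_array_frac, seed=cseed + 2
            )
            geno_arr = geno.subset_snps(array_idx)
            train, valid = train_validation_split(
                geno_arr, trait, seed=cseed + 3, n_train=n_train
            )
            stats = compute_snp_stats(train.genotypes)
            poly = np.flatnonzero(stats.sd > 0)
            gt = train.genotypes.subset_snps(poly)
            z = standardize(gt, compute_snp_stats(gt))
            data = MLMData(y=train.phenotypes, z=z)
            vc = reml_fit_eigen(data)
            beta, _ = gls_fixed_effects(data, vc)
            effects = blup_snp_effects(z, data, vc, beta, snps=gt.snps)
            scores = polygenic_score(valid.genotypes, effects)
            r_pheno, r_over = prediction_accuracy(
                scores, valid.phenotypes, traitspec.h2
            )
            r_gen = float(np.corrcoef(scores.scores, valid.genetic_values)[0, 1])
            rows.append({
                "n_train": n_train, "h2": traitspec.h2, "scenario": scenario,
                "replicate": rep, "r_pheno": r_pheno, "r_gen": r_gen,
                "r_over_max": r_over, "sigma2_g": vc.sigma2_g,
                "sigma2_e": vc.sigma2_e, "h2_hat": vc.h2,
                "m_array": int(array_idx.size), "converged": vc.converged,
            })
    return pd.DataFrame(rows)


def inverse_r2_regression(results: pd.DataFrame) -> InverseRegressionResult:
    """Regress mean 1/r_gen^2 on 1/N_train across the training-size grid.

    Theory for additive traits with M independent markers predicts
    1/r_gen^2 = 1 + (M/h2) * (1/N): a unit intercept and positive slope.
    """
    if (results["r_gen"] == 0).any():
        raise ValueError("r_gen = 0 in some cell; inverse accuracy undefined")
    pts = (
        results.assign(inv_r2=lambda d: 1.0 / d["r_gen"] ** 2)
        .groupby("n_train", as_index=False)["inv_r2"].mean()
    )
    if len(pts) < 3:
        raise ValueError("need at least 3 distinct n_train values")
    x = 1.0 / pts["n_train"].to_numpy(dtype=np.float64)
    yv = pts["inv_r2"].to_numpy(dtype=np.float64)
    slope, intercept = np.polyfit(x, yv, 1)
    pts = pts.rename(columns={"inv_r2": "mean_inv_r_gen2"})
    pts["inv_n"] = x
    return InverseRegressionResult(float(intercept), float(slope), pts)


def theoretical_max_ratio(r: float, h2: float) -> int:
    """Achieved correlation as an integer percentage of its ceiling sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    return int(round(100.0 * r / float(np.sqrt(h2))))
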