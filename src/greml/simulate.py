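"""Synthetic genotypes and additive quantitative traits.

The generator emulates a cohort of unrelated individuals typed on a
biallelic SNP array: allele frequencies drawn uniformly from a MAF range,
genotypes in Hardy-Weinberg proportions, and (optionally) a one-parameter
AR(1) haplotype model for linkage disequilibrium between adjacent SNPs.

Traits follow the additive model used in genomic-prediction studies: a
chosen number of quantitative trait nucleotides (QTNs) receive independent
standard-normal effects on the *standardized* genotype scale (so each QTN
contributes equal expected variance regardless of allele frequency); the
genetic values and an orthogonalized Gaussian residual are rescaled so that
the realized heritability var(g)/var(y) equals the target h2 exactly, not
merely in expectation.  This exactness is a deliberate design choice: it
gives downstream estimators a sharp truth to be compared against.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, compute_snp_stats, standardize


@dataclass
class GenotypeSimSpec:
    """Cohort dimensions and allele-frequency model for genotype simulation.

    ``ld_rho`` is the adjacent-SNP haplotype correlation of the AR(1) LD
    model; 0 means linkage equilibrium (independent SNPs).
    """

    n_samples: int
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    ld_block_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_samples < 1 or self.n_snps < 1:
            raise ValueError("n_samples and n_snps must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be positive")


@dataclass
class TraitSimSpec:
    """Additive trait architecture: QTN count, heritability, seed."""

    n_qtn: int
    h2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be strictly inside (0, 1)")
        if self.n_qtn < 1:
            raise ValueError("n_qtn must be positive")


@dataclass
class SimulatedTrait:
    """Phenotypes with their true genetic decomposition.

    ``effects`` are the QTN effects on the standardized-genotype scale;
    ``realized_h2`` equals var(g)/var(y) computed from the simulated values
    and matches the requested h2 exactly by construction.
    """

    phenotypes: np.ndarray
    genetic_values: np.ndarray
    qtn_indices: np.ndarray
    effects: np.ndarray
    realized_h2: float
    h2_target: float


@dataclass
class Cohort:
    """A sample subset carrying aligned genotypes, phenotypes and truths."""

    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    genetic_values: np.ndarray
    indices: np.ndarray


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Simulate biallelic genotypes for unrelated individuals.

    With ``ld_rho = 0`` each SNP's A1 frequency is uniform on ``maf_range``
    and dosages are Binomial(2, p), independent across SNPs
    (Hardy-Weinberg).  With ``ld_rho > 0`` the genome is split into
    independent LD blocks of ``ld_block_size`` SNPs sharing one allele
    frequency (correlated markers have similar frequencies; blocks model
    recombination hotspots): within a block each individual's two
    haplotypes follow a stationary first-order Markov chain with
    adjacent-site correlation exactly ``ld_rho``; dosage = haplotype sum.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_snps

    if spec.ld_rho == 0.0:
        p = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
        dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    else:
        bs = spec.ld_block_size
        n_blocks = (m + bs - 1) // bs
        p_block = rng.uniform(spec.maf_range[0], spec.maf_range[1],
                              size=n_blocks)
        p = np.repeat(p_block, bs)[:m]
        rho = spec.ld_rho
        h = np.empty((2 * n, m), dtype=bool)
        start = 0
        for b in range(n_blocks):
            stop = min(start + bs, m)
            pb = p_block[b]
            h[:, start] = rng.random(2 * n) < pb
            for j in range(start + 1, stop):
                # equal-frequency chain: P(1|a) = p + rho*(a - p) stays in [0,1]
                cond = pb + rho * (h[:, j - 1] - pb)
                h[:, j] = rng.random(2 * n) < cond
            start = stop
        dos = (h[0::2].astype(np.int8) + h[1::2].astype(np.int8))

    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
    })
    snps = pd.DataFrame({
        "chrom": "1",
        "snp_id": [f"snp{j}" for j in range(m)],
        "cm": 0.0,
        "bp": np.arange(1, m + 1),
        "a1": "A",
        "a2": "B",
    })
    return GenotypeMatrix(dos, samples, snps)


def simulate_trait(g: GenotypeMatrix, spec: TraitSimSpec) -> SimulatedTrait:
    """Simulate an additive trait from randomly placed QTNs.

    QTN indices are drawn uniformly without replacement; effects are
    standard normal on the self-standardized genotype scale.  Genetic
    values are rescaled to variance h2; the Gaussian residual is centred,
    projected orthogonal to the genetic values and rescaled to variance
    1 - h2, so var(g)/var(y) = h2 holds exactly for every seed.
    """
    m = g.n_snps
    if spec.n_qtn > m:
        raise ValueError(f"n_qtn={spec.n_qtn} exceeds {m} available SNPs")
    rng = np.random.default_rng(spec.seed)
    qtn = np.sort(rng.choice(m, size=spec.n_qtn, replace=False))
    g_qtn = g.subset_snps(qtn)
    stats = compute_snp_stats(g_qtn)
    if (stats.sd == 0).any():
        bad = g_qtn.snps["snp_id"][stats.sd == 0]
        raise ValueError(f"selected QTNs are monomorphic: {list(bad[:5])}")
    z = standardize(g_qtn, stats)
    u = rng.standard_normal(spec.n_qtn)
    g_raw = z.values @ u
    g_raw = g_raw - g_raw.mean()
    sd_raw = np.sqrt(np.var(g_raw))
    if sd_raw == 0:
        raise ValueError("degenerate genetic values (zero variance)")
    scale = np.sqrt(spec.h2) / sd_raw
    gval = g_raw * scale
    e = rng.standard_normal(g.n_samples)
    e = e - e.mean()
    e = e - (e @ gval) / (gval @ gval) * gval  # exact orthogonality to g
    e *= np.sqrt((1.0 - spec.h2) / np.var(e))
    y = gval + e
    realized = float(np.var(gval) / np.var(y))
    return SimulatedTrait(
        phenotypes=y, genetic_values=gval, qtn_indices=qtn,
        effects=u * scale, realized_h2=realized, h2_target=spec.h2,
    )


def train_validation_split(
    g: GenotypeMatrix, trait: SimulatedTrait, train_frac: float = 0.9,
    seed: int = 0, n_train: int | None = None,
):
    """Random partition of a cohort into training and validation parts.

    ``n_train`` overrides the fraction when the split sizes are given
    explicitly (as for very large cohorts where a round number of training
    samples is wanted).  Both parts carry aligned genotypes, phenotypes and
    true genetic values.
    """
    n = g.n_samples
    if n_train is None:
        if not 0.0 < train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError("split leaves an empty training or validation set")
    perm = np.random.default_rng(seed).permutation(n)
    tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    def part(idx):
        return Cohort(
            genotypes=g.subset_samples(idx),
            phenotypes=trait.phenotypes[idx],
            genetic_values=trait.genetic_values[idx],
            indices=idx,
        )
    return part(tr), part(va)


SCENARIOS = ("partial_qtn", "all_qtn", "qtn_only")


def build_array_scenario(
    g: GenotypeMatrix,
    trait: SimulatedTrait,
    scenario: str,
    qtn_on_array_frac: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """SNP indices genotyped under an array scenario.

    ``partial_qtn``: every non-QTN SNP plus a random ``qtn_on_array_frac``
    of the QTNs (imperfect tagging); ``all_qtn``: all SNPs; ``qtn_only``:
    exactly the causal set.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    m = g.n_snps
    qtn = trait.qtn_indices
    if scenario == "all_qtn":
        return np.arange(m)
    if scenario == "qtn_only":
        return qtn.copy()
    rng = np.random.default_rng(seed)
    n_on = int(round(qtn_on_array_frac * qtn.size))
    on_array = rng.choice(qtn, size=n_on, replace=False)
    non_qtn = np.setdiff1d(np.arange(m), qtn)
    return np.sort(np.concatenate([non_qtn, on_array]))
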