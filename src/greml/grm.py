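"""Genomic relationship matrices: computation, GCTA binary I/O, eigendecomposition.

The GRM is G = Z Z' / M over M standardized SNPs, so that the polygenic
covariance is G * sigma2_g with sigma2_g = M * sigma2_a (the summed variance
of the per-SNP effects on the standardized scale).  The denominator is the
fixed SNP count M, not per-pair non-missing counts: missing genotypes are
mean-imputed upstream, which keeps the identity g_hat = Z a_hat exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import StandardizedGenotypes


class GrmSizeMismatchError(ValueError):
    """.grm.bin length is inconsistent with the number of ids in .grm.id."""


@dataclass
class GRM:
    """Symmetric N x N genomic relationship matrix.

    ``n_snps`` records the SNP count M used in the denominator.  The full
    eigendecomposition is computed lazily and cached.
    """

    values: np.ndarray
    samples: pd.DataFrame
    n_snps: int
    _eigen: "GRMEigen | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.samples) != n:
            raise ValueError("sample count does not match GRM dimension")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"GRM not symmetric (max asymmetry {asym:g})")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class GRMEigen:
    """Full spectral decomposition of a GRM, eigenvalues descending."""

    values: np.ndarray      # (N,) descending
    vectors: np.ndarray     # (N, N) orthonormal columns

    def clipped_values(self) -> np.ndarray:
        """Eigenvalues with small negative values (round-off) clipped to 0."""
        return np.maximum(self.values, 0.0)


def compute_grm(
    z: StandardizedGenotypes, samples: pd.DataFrame | None = None
) -> GRM:
    """G = Z Z' / M from standardized genotypes.

    ``samples`` (fid/iid DataFrame) is attached when given; otherwise
    placeholder ids 0..N-1 are used.
    """
    m = z.n_snps
    if m == 0:
        raise ValueError("cannot compute a GRM from zero SNPs")
    g = z.values @ z.values.T / m
    g = (g + g.T) / 2.0  # enforce exact symmetry against round-off
    if samples is None:
        samples = pd.DataFrame(
            {"fid": [str(i) for i in range(z.n_samples)],
             "iid": [str(i) for i in range(z.n_samples)]}
        )
    return GRM(g, samples[["fid", "iid"]], m)


def eigendecompose_grm(grm: GRM) -> GRMEigen:
    """Full symmetric eigendecomposition, cached on the GRM object.

    Eigenvector sign/order within ties is whatever LAPACK returns;
    consumers must not depend on it.
    """
    if grm._eigen is None:
        w, u = np.linalg.eigh(grm.values)
        grm._eigen = GRMEigen(w[::-1].copy(), u[:, ::-1].copy())
    return grm._eigen


def write_grm_gcta(grm: GRM, prefix: str) -> None:
    """Write the GCTA binary triplet .grm.bin/.grm.N.bin/.grm.id.

    .grm.bin holds the lower triangle (diagonal included) row-major as
    little-endian float32; .grm.N.bin replicates the SNP count per pair.
    """
    n = grm.n_samples
    tri = grm.values[np.tril_indices(n)].astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, grm.n_snps, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    grm.samples[["fid", "iid"]].to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str) -> GRM:
    """Read a GCTA binary GRM triplet written by :func:`write_grm_gcta`."""
    import os

    ids = pd.read_csv(
        f"{prefix}.grm.id", sep=r"\s+", header=None, names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise GrmSizeMismatchError(
            f"{prefix}.grm.bin holds {tri.size} values; "
            f"{n} ids require {n * (n + 1) // 2}"
        )
    g = np.zeros((n, n))
    g[np.tril_indices(n)] = tri
    g = g + np.tril(g, -1).T
    n_path = f"{prefix}.grm.N.bin"
    m = 0
    if os.path.exists(n_path):
        counts = np.fromfile(n_path, dtype="<f4")
        if counts.size:
            m = int(round(float(counts[0])))
    return GRM(g, ids, m)
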