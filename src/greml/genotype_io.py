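"""PLINK 1 binary genotype I/O, allele statistics and genotype standardization.

Genotypes are stored as reference-allele (A1) dosages in {0, 1, 2} with a
``MISSING`` sentinel.  Standardization follows the GCTA convention by
default: each SNP column is centred at its mean dosage ``2*p`` and scaled by
the Hardy-Weinberg standard deviation ``sqrt(2*p*(1-p))``; the empirical
standard deviation is available as an option.  Missing genotypes are
mean-imputed, i.e. set to zero after standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in a dosage matrix.
MISSING: int = -1

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK codes, LSB-first within a byte:
#   00 -> 2 copies of A1, 10 -> 1 copy, 11 -> 0 copies, 01 -> missing
_DECODE_LUT = np.array([2, MISSING, 1, 0], dtype=np.int8)
# inverse map indexed by dosage + 1 (-1, 0, 1, 2) -> 2-bit code
_ENCODE_LUT = np.array([1, 3, 2, 0], dtype=np.uint8)


class PlinkFileMissingError(FileNotFoundError):
    """A member of the .bed/.bim/.fam triplet does not exist."""


class BadMagicError(ValueError):
    """The .bed file does not start with the PLINK magic bytes 0x6C 0x1B."""


class UnsupportedBedModeError(ValueError):
    """The .bed mode byte is not 0x01 (SNP-major)."""


class TruncatedBedError(ValueError):
    """The .bed payload length does not equal ceil(N/4) * M bytes."""


class MonomorphicSNPError(ValueError):
    """An operation requiring polymorphic SNPs met a zero-variance column."""


class AllMissingSNPError(ValueError):
    """A SNP has no non-missing genotype calls."""


class SnpMismatchError(ValueError):
    """SNP identifiers of two objects that must align do not match."""


@dataclass
class GenotypeMatrix:
    """N x M reference-allele dosage matrix with sample and SNP metadata.

    Parameters
    ----------
    dosages
        Integer matrix of shape (n_samples, n_snps) with entries in
        {0, 1, 2} or :data:`MISSING`.
    samples
        DataFrame with columns ``fid``, ``iid`` (one row per sample).
    snps
        DataFrame with columns ``chrom``, ``snp_id``, ``cm``, ``bp``,
        ``a1``, ``a2`` (one row per SNP; bp positions 1-based).
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} dosage rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP rows for {m} dosage columns")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosage entries must be in {0, 1, 2} or MISSING")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_ids must be unique")
        if self.samples.duplicated(subset=["fid", "iid"]).any():
            raise ValueError("(fid, iid) pairs must be unique")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx], self.samples.iloc[idx], self.snps
        )

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.samples, self.snps.iloc[idx]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.samples[["fid", "iid"]].astype(str).equals(
                other.samples[["fid", "iid"]].astype(str)
            )
            and self.snps.astype(str).equals(other.snps.astype(str))
        )


@dataclass
class SnpStats:
    """Per-SNP reference-allele statistics of a (training) cohort.

    ``mean`` is the average dosage over non-missing calls (equals ``2*freq``);
    ``sd`` is the scaling used for standardization: ``sqrt(2*p*(1-p))`` under
    the default Hardy-Weinberg convention, or the empirical standard
    deviation when requested.
    """

    snp_ids: np.ndarray
    freq: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_obs: np.ndarray
    hwe_sd: bool = True

    @property
    def monomorphic(self) -> np.ndarray:
        return self.sd == 0.0


@dataclass
class StandardizedGenotypes:
    """Real-valued standardized genotype matrix Z with the stats that built it.

    Missing genotypes are represented by zeros (mean imputation), so columns
    standardized against their own cohort have mean zero.
    """

    values: np.ndarray
    stats: SnpStats
    snp_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.snp_ids = np.asarray(self.stats.snp_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


def _bytes_per_snp(n_samples: int) -> int:
    return (n_samples + 3) // 4


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a PLINK 1 binary triplet ``prefix.bed/.bim/.fam`` (SNP-major)."""
    paths = {ext: f"{prefix}.{ext}" for ext in ("bed", "bim", "fam")}
    import os

    for ext, path in paths.items():
        if not os.path.exists(path):
            raise PlinkFileMissingError(f"missing PLINK file: {path}")

    fam = pd.read_csv(
        paths["fam"], sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    try:
        bim = pd.read_csv(
            paths["bim"], sep=r"\s+", header=None,
            names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
            dtype={"chrom": str, "snp_id": str, "cm": float, "bp": int,
                   "a1": str, "a2": str},
        )
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame({
            "chrom": pd.Series(dtype=str), "snp_id": pd.Series(dtype=str),
            "cm": pd.Series(dtype=float), "bp": pd.Series(dtype=int),
            "a1": pd.Series(dtype=str), "a2": pd.Series(dtype=str),
        })
    n, m = len(fam), len(bim)

    with open(paths["bed"], "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if len(header) < 3 or header[:2] != _PLINK_MAGIC:
        raise BadMagicError(f"{paths['bed']}: bad magic bytes {header[:2]!r}")
    if header[2] != _SNP_MAJOR:
        raise UnsupportedBedModeError(
            f"{paths['bed']}: mode byte 0x{header[2]:02X}; only SNP-major "
            "(0x01) is supported"
        )
    bps = _bytes_per_snp(n)
    if len(payload) != bps * m:
        raise TruncatedBedError(
            f"{paths['bed']}: expected {bps * m} payload bytes "
            f"(ceil({n}/4)*{m}), found {len(payload)}"
        )

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bps)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts) & 0x03  # (M, bps, 4)
    codes = codes.reshape(m, bps * 4)[:, :n]
    dosages = _DECODE_LUT[codes].T  # (N, M)

    return GenotypeMatrix(dosages, fam[["fid", "iid"]], bim)


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write ``g`` as a SNP-major PLINK 1 binary triplet.

    Trailing pad bits of each per-SNP byte block are zero, so
    ``read_plink(write_plink(g)) == g`` bit-exactly.
    """
    n, m = g.n_samples, g.n_snps
    bps = _bytes_per_snp(n)

    codes = np.zeros((m, bps * 4), dtype=np.uint8)
    codes[:, :n] = _ENCODE_LUT[(g.dosages.T + 1).astype(np.intp)]
    codes = codes.reshape(m, bps, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)

    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    fam = g.samples.copy()
    for col, default in (("father", "0"), ("mother", "0"), ("sex", "0"),
                         ("phenotype", "-9")):
        if col not in fam.columns:
            fam[col] = default
    fam[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        f"{prefix}.fam", sep="\t", header=False, index=False
    )
    g.snps[["chrom", "snp_id", "cm", "bp", "a1", "a2"]].to_csv(
        f"{prefix}.bim", sep="\t", header=False, index=False
    )


def compute_snp_stats(g: GenotypeMatrix, empirical_sd: bool = False) -> SnpStats:
    """Per-SNP A1 frequency, mean dosage and standardization s.d.

    The default s.d. is the Hardy-Weinberg value ``sqrt(2 p (1-p))``; with
    ``empirical_sd=True`` the observed standard deviation over non-missing
    calls (ddof=0) is used instead.
    """
    d = g.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = g.snps["snp_id"].values[n_obs == 0]
        raise AllMissingSNPError(f"SNPs with no genotype calls: {list(bad[:5])}")
    dz = np.where(obs, d, 0).astype(np.float64)
    mean = dz.sum(axis=0) / n_obs
    freq = mean / 2.0
    if empirical_sd:
        var = (dz**2).sum(axis=0) / n_obs - mean**2
        sd = np.sqrt(np.maximum(var, 0.0))
    else:
        sd = np.sqrt(2.0 * freq * (1.0 - freq))
    return SnpStats(
        snp_ids=g.snps["snp_id"].to_numpy(),
        freq=freq, mean=mean, sd=sd, n_obs=n_obs,
        hwe_sd=not empirical_sd,
    )


def standardize(g: GenotypeMatrix, stats: SnpStats) -> StandardizedGenotypes:
    """Centre and scale dosages: z_ij = (s_ij - mean_j) / sd_j.

    ``stats`` may come from a different (training) cohort than ``g``; the
    SNP identifiers must match positionally.  Missing genotypes become zero
    (training-mean imputation).
    """
    if not np.array_equal(np.asarray(stats.snp_ids), g.snps["snp_id"].to_numpy()):
        raise SnpMismatchError("SNP set of stats does not match genotype matrix")
    if (stats.sd <= 0).any():
        bad = np.asarray(stats.snp_ids)[stats.sd <= 0]
        raise MonomorphicSNPError(
            f"cannot standardize SNPs with zero s.d.: {list(bad[:5])}"
        )
    d = g.dosages
    obs = d != MISSING
    z = (np.where(obs, d, 0).astype(np.float64) - stats.mean) / stats.sd
    z[~obs] = 0.0
    return StandardizedGenotypes(z, stats)


def filter_snps(
    g: GenotypeMatrix, min_maf: float = 0.0, max_missing_rate: float = 1.0
) -> GenotypeMatrix:
    """Keep SNPs with minor-allele frequency >= ``min_maf`` and missing
    fraction <= ``max_missing_rate``; SNP order is preserved."""
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    stats = compute_snp_stats(g)
    maf = np.minimum(stats.freq, 1.0 - stats.freq)
    miss = 1.0 - stats.n_obs / g.n_samples
    keep = (maf >= min_maf) & (miss <= max_missing_rate)
    if not keep.any():
        raise ValueError("all SNPs removed by filter")
    return g.subset_snps(np.flatnonzero(keep))


def read_phenotype(path: str) -> pd.DataFrame:
    """Read a PLINK-style phenotype/covariate file: FID IID value1 [value2 ...].

    ``NA`` and ``-9`` are treated as missing.  Returns a DataFrame with
    ``fid``, ``iid`` (str) and float value columns ``v1``, ``v2``, ...
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError("phenotype file needs at least 3 columns (FID IID value)")
    out = df.iloc[:, :2].copy()
    out.columns = ["fid", "iid"]
    for k in range(2, df.shape[1]):
        vals = pd.to_numeric(df.iloc[:, k].replace("NA", np.nan), errors="raise")
        vals = vals.where(vals != -9, np.nan)
        out[f"v{k - 1}"] = vals.astype(float)
    return out
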