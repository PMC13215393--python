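"""Core domain types for private SNP-dataset release.

Genotypes follow the standard minor-allele dosage convention: each entry of
an n x m matrix is 0, 1 or 2, the number of minor alleles the individual
carries at that SNP.  The binary working representation uses two bits per
SNP — SNP ``j`` (0-based) owns bit columns ``2j`` and ``2j+1`` throughout
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

CASE = "case"
CONTROL = "control"


class ValidationError(ValueError):
    """Raised when a domain object would violate its invariants."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = set()
    for name in names:
        if name in seen:
            raise ValidationError(f"duplicate {what}: {name!r}")
        seen.add(name)


@dataclass
class SnpDataset:
    """An n x m genotype matrix with sample IDs, rsIDs and optional phenotype.

    Parameters
    ----------
    genotypes
        Integer matrix with entries in {0, 1, 2} (minor-allele dosage).
    sample_ids
        ``n`` unique sample identifiers.
    rsids
        ``m`` unique SNP identifiers.
    phenotype
        Optional length-``n`` sequence of ``"case"`` / ``"control"`` labels.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    rsids: list[str]
    phenotype: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        if not np.issubdtype(self.genotypes.dtype, np.integer):
            g = self.genotypes
            if not np.array_equal(g, np.round(g)):
                raise ValidationError("genotypes must be integers")
            self.genotypes = g.astype(np.int8)
        else:
            self.genotypes = self.genotypes.astype(np.int8)
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype at row {i}, column {j} is "
                f"{self.genotypes[i, j]}, expected 0/1/2"
            )
        n, m = self.genotypes.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.rsids = [str(r) for r in self.rsids]
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample IDs for {n} rows")
        if len(self.rsids) != m:
            raise ValidationError(f"{len(self.rsids)} rsIDs for {m} columns")
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.rsids, "rsID")
        if self.phenotype is not None:
            self.phenotype = [str(p) for p in self.phenotype]
            if len(self.phenotype) != n:
                raise ValidationError("phenotype length does not match sample count")
            bad_labels = set(self.phenotype) - {CASE, CONTROL}
            if bad_labels:
                raise ValidationError(f"unknown phenotype labels: {sorted(bad_labels)}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def subset_rows(self, mask: np.ndarray) -> "SnpDataset":
        """Return the row-subset dataset selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        pheno = None
        if self.phenotype is not None:
            pheno = [p for p, keep in zip(self.phenotype, mask) if keep]
        return SnpDataset(
            genotypes=self.genotypes[mask],
            sample_ids=[s for s, keep in zip(self.sample_ids, mask) if keep],
            rsids=list(self.rsids),
            phenotype=pheno,
        )

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency, dosage sum over 2n alleles."""
        return self.genotypes.sum(axis=0) / (2.0 * self.n_samples)


@dataclass
class BinaryDataset:
    """An n x 2m bit matrix; bit columns ``2j``/``2j+1`` belong to SNP ``j``."""

    bits: np.ndarray
    rsids: list[str]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValidationError("bits must be a 2-D matrix")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("bit matrix entries must be 0/1")
        self.bits = self.bits.astype(np.int8)
        self.rsids = [str(r) for r in self.rsids]
        _check_unique(self.rsids, "rsID")
        if self.bits.shape[1] != 2 * len(self.rsids):
            raise ValidationError(
                f"{self.bits.shape[1]} bit columns for {len(self.rsids)} SNPs; "
                "expected exactly two bit columns per SNP"
            )

    @property
    def n_samples(self) -> int:
        return self.bits.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.rsids)


@dataclass
class PrivacyBudget:
    """Privacy budget of a release: ε_e for the dataset, optional ε_m for MAFs.

    ``sensitivity`` is the query sensitivity in bits: one individual's record
    can differ in every bit of its encoded row, i.e. 2 x (number of SNPs).
    Jointly releasing the dataset and Laplace-protected MAFs consumes
    ε_e + ε_m by sequential composition.
    """

    epsilon_e: float
    sensitivity: int
    epsilon_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.epsilon_e > 0:
            raise ValidationError("epsilon_e must be positive")
        if self.epsilon_m is not None and not self.epsilon_m > 0:
            raise ValidationError("epsilon_m, when set, must be positive")
        if int(self.sensitivity) != self.sensitivity or self.sensitivity <= 0:
            raise ValidationError("sensitivity must be a positive integer (bits)")
        self.sensitivity = int(self.sensitivity)

    @property
    def total_epsilon(self) -> float:
        return self.epsilon_e + (self.epsilon_m or 0.0)


@dataclass
class FindingsRecord:
    rsid: str
    p_value: float
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1] for {self.rsid}")
        if not 0.0 <= self.maf <= 1.0:
            raise ValidationError(f"MAF {self.maf} outside [0, 1] for {self.rsid}")


@dataclass
class Findings:
    """Published per-SNP findings: rsID, p-value and MAF, plus the test used.

    The researcher's reported significant set is the rsIDs with
    ``p_value < alpha`` (strict inequality).
    """

    records: list[FindingsRecord]
    test_name: str = "chi2"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.test_name not in ("chi2", "odds_ratio"):
            raise ValidationError(f"unknown test name {self.test_name!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        self.records = [
            r if isinstance(r, FindingsRecord) else FindingsRecord(*r)
            for r in self.records
        ]
        _check_unique([r.rsid for r in self.records], "rsID")

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def significant_rsids(self) -> list[str]:
        return [r.rsid for r in self.records if r.p_value < self.alpha]

    def maf_vector(self, rsids: Sequence[str]) -> np.ndarray:
        """MAFs in the given rsID order; every rsID must be present."""
        table: Mapping[str, float] = {r.rsid: r.maf for r in self.records}
        missing = [r for r in rsids if r not in table]
        if missing:
            raise ValidationError(f"rsIDs absent from findings: {missing[:5]}")
        return np.array([table[r] for r in rsids], dtype=float)


@dataclass
class ContingencyTable:
    """2x3 genotype contingency table: case counts S_i, control counts R_i."""

    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for counts in (self.case_counts, self.control_counts):
            if len(counts) != 3 or any(c < 0 or int(c) != c for c in counts):
                raise ValidationError("counts must be three nonnegative integers")
        self.case_counts = tuple(int(c) for c in self.case_counts)
        self.control_counts = tuple(int(c) for c in self.control_counts)

    @property
    def total(self) -> int:
        return sum(self.case_counts) + sum(self.control_counts)

    def as_array(self) -> np.ndarray:
        return np.array([self.case_counts, self.control_counts], dtype=float)


@dataclass
class ThetaMatrix:
    """Symmetric 2m x 2m SNP-bit association matrix with cached eigen-norm.

    ``eig_l2`` caches the l2 norm of the eigenvalue vector, which for a
    symmetric matrix equals the Frobenius norm.
    """

    theta: np.ndarray
    pseudocount: float = 0.0
    eig_l2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != self.theta.shape[1]:
            raise ValidationError("theta must be square")
        if not np.allclose(self.theta, self.theta.T, atol=1e-9):
            raise ValidationError("theta must be symmetric within 1e-9")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")
        if self.eig_l2 is None:
            from .correlation import eig_l2_norm

            self.eig_l2 = eig_l2_norm(self.theta)

    @property
    def n_bits(self) -> int:
        return self.theta.shape[0]


@dataclass
class NoiseCalibration:
    """Per-bit-column flip probabilities of the element-wise binary noise.

    Because the vectorised noise parameter is the Kronecker product
    ``I_n (x) Theta`` (no kinship blocks), the calibration statistic
    ``kappa`` and the flip probability are identical across individuals and
    depend only on the bit column; both vectors have length 2m.
    """

    kappa: np.ndarray
    flip_prob: np.ndarray
    lambda_norm: float
    epsilon_e: float
    sensitivity: int

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.flip_prob = np.asarray(self.flip_prob, dtype=float)
        if self.kappa.shape != self.flip_prob.shape or self.kappa.ndim != 1:
            raise ValidationError("kappa and flip_prob must be 1-D of equal length")
        if self.lambda_norm < 0:
            raise ValidationError("lambda_norm must be nonnegative")
        if not ((self.flip_prob > 0) & (self.flip_prob < 1)).all():
            raise ValidationError("flip probabilities must lie in (0, 1)")
        capped = np.abs(self.kappa) > self.lambda_norm
        if not np.allclose(self.flip_prob[capped], 0.5):
            raise ValidationError("capped columns must have flip probability 1/2")

    @property
    def n_bits(self) -> int:
        return self.kappa.shape[0]
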