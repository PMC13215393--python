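"""Synthetic reference panels and case/control cohorts with planted effects.

Every stage of the release and validation pipeline is testable without
external downloads: the generator emulates a public reference panel (for
association-matrix estimation and membership-inference calibration) and a
case/control study cohort with planted per-allele multiplicative effects at
chosen causal SNPs.

Haplotypes are drawn through a first-order Gaussian-copula chain: a latent
AR(1) standard-normal sequence is thresholded at each SNP's target MAF, so
per-SNP marginals are exact while adjacent SNPs carry tunable linkage
disequilibrium (``ld_rho`` is the latent autocorrelation; the induced
allele correlation equals it when adjacent MAFs match and is monotone in
it otherwise).  Genotypes are sums of two independent haplotypes, hence in
Hardy–Weinberg equilibrium at every SNP, and rows are exchangeable (no
kinship structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import SnpDataset, ValidationError


def _haplotypes(
    n_haplotypes: int, maf: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    m = maf.size
    z = np.empty((n_haplotypes, m))
    z[:, 0] = rng.standard_normal(n_haplotypes)
    if m > 1:
        innovations = rng.standard_normal((n_haplotypes, m - 1))
        scale = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + scale * innovations[:, j - 1]
    thresholds = stats.norm.ppf(maf)
    return (z < thresholds).astype(np.int8)


def _draw_genotypes(
    n: int, maf: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    return _haplotypes(n, maf, ld_rho, rng) + _haplotypes(n, maf, ld_rho, rng)


def generate_panel(
    m: int,
    n: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "panel",
    maf: np.ndarray | None = None,
) -> SnpDataset:
    """Generate an n x m reference panel.

    Target MAFs are Uniform(maf_low, maf_high) per SNP unless an explicit
    length-m ``maf`` vector is given (e.g. to draw extra individuals from
    the same population as an existing cohort); haplotypes follow the
    copula chain above and genotypes are Hardy–Weinberg sums of two
    haplotypes.
    """
    if not 0.0 <= maf_low <= maf_high <= 0.5:
        raise ValidationError("need 0 <= maf_low <= maf_high <= 0.5")
    if not 0.0 <= ld_rho < 1.0:
        raise ValidationError("need 0 <= ld_rho < 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if maf is None:
        maf = rng.uniform(maf_low, maf_high, size=m)
    else:
        maf = np.asarray(maf, dtype=float)
        if maf.shape != (m,) or ((maf < 0) | (maf > 1)).any():
            raise ValidationError("explicit maf must be length m within [0, 1]")
    geno = _draw_genotypes(n, maf, ld_rho, rng)
    return SnpDataset(
        geno,
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        rsids=[f"rs{j}" for j in range(m)],
    )


@dataclass
class CaseControlStudy:
    """A simulated cohort plus its generating truth."""

    dataset: SnpDataset
    causal_indices: list[int]
    control_maf: np.ndarray
    case_maf: np.ndarray


def generate_case_control(
    m: int,
    n_case: int,
    n_control: int,
    causal_indices: list[int] | tuple[int, ...] = (),
    effect_or: float = 1.0,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_rho: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> CaseControlStudy:
    """Generate a labelled case/control cohort with planted associations.

    Controls are drawn at the panel MAFs.  At each causal SNP the case
    minor-allele odds are multiplied by ``effect_or`` (a per-allele
    log-additive disease model): f_case = OR*f/(1-f) / (1 + OR*f/(1-f)).
    Non-causal SNPs are identically distributed in both groups.
    """
    if effect_or < 1.0:
        raise ValidationError("effect_or must be >= 1")
    causal_indices = sorted(int(c) for c in causal_indices)
    if causal_indices and not (0 <= causal_indices[0] and causal_indices[-1] < m):
        raise ValidationError("causal indices out of range")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    control_maf = rng.uniform(maf_low, maf_high, size=m)
    case_maf = control_maf.copy()
    for j in causal_indices:
        odds = effect_or * control_maf[j] / (1.0 - control_maf[j])
        case_maf[j] = odds / (1.0 + odds)

    geno_case = _draw_genotypes(n_case, case_maf, ld_rho, rng)
    geno_control = _draw_genotypes(n_control, control_maf, ld_rho, rng)
    ds = SnpDataset(
        np.vstack([geno_case, geno_control]),
        sample_ids=[f"case{i}" for i in range(n_case)]
        + [f"ctrl{i}" for i in range(n_control)],
        rsids=[f"rs{j}" for j in range(m)],
        phenotype=["case"] * n_case + ["control"] * n_control,
    )
    return CaseControlStudy(
        dataset=ds,
        causal_indices=list(causal_indices),
        control_maf=control_maf,
        case_maf=case_maf,
    )
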