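"""Verifier-side GWAS: association tests, retention rate and error models.

The verifier reproduces the researcher's per-SNP association tests on the
shared dataset and measures the SNP retention rate — the fraction of
reported-significant rsIDs that remain significant in the reproduction,
under a threshold relaxed by a tolerance factor (alpha / tolerance).
Deviations of the retention rate between error-free and error-injected
findings expose unintentional errors in the published p-values; two
injected-error models are provided (uniform replacement of a fraction of
p-values, and additive Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import ContingencyTable, Findings, SnpDataset, ValidationError


def build_table(ds: SnpDataset, snp_index: int) -> ContingencyTable:
    """2x3 genotype contingency table for one SNP of a case/control dataset."""
    if ds.phenotype is None:
        raise ValidationError("dataset has no phenotype labels")
    labels = np.asarray(ds.phenotype)
    column = ds.genotypes[:, snp_index]
    case = column[labels == "case"]
    control = column[labels == "control"]
    s = tuple(int((case == g).sum()) for g in (0, 1, 2))
    r = tuple(int((control == g).sum()) for g in (0, 1, 2))
    return ContingencyTable(s, r)


def chi_square_p(table: ContingencyTable) -> float:
    """Pearson chi-square p-value on the 2x3 genotype table.

    Genotype columns with zero total are dropped (reducing the degrees of
    freedom); monomorphic SNPs — a single non-empty column — return p = 1.
    """
    arr = table.as_array()
    if arr[0].sum() == 0 or arr[1].sum() == 0:
        raise ValidationError("both case and control groups must be non-empty")
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[1] < 2:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p)


def odds_ratio_p(table: ContingencyTable) -> tuple[float, float]:
    """Allelic odds ratio and two-sided Wald p-value.

    The genotype table is collapsed to allele counts: case minor
    a = S1 + 2*S2, case major b = 2*S0 + S1, and likewise c, d for
    controls.  When any cell is zero, the Haldane–Anscombe correction adds
    0.5 to every cell.  OR = ad/bc; p is two-sided normal on
    log(OR) / sqrt(1/a + 1/b + 1/c + 1/d).
    """
    s0, s1, s2 = table.case_counts
    r0, r1, r2 = table.control_counts
    a = s1 + 2 * s2
    b = 2 * s0 + s1
    c = r1 + 2 * r2
    d = 2 * r0 + r1
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(or_), float(min(p, 1.0))


def run_gwas(ds: SnpDataset, test: str = "chi2") -> np.ndarray:
    """Per-SNP association p-values, in the dataset's rsID order."""
    if test not in ("chi2", "odds_ratio"):
        raise ValidationError(f"unknown test {test!r}")
    p_values = np.empty(ds.n_snps)
    for j in range(ds.n_snps):
        table = build_table(ds, j)
        if test == "chi2":
            p_values[j] = chi_square_p(table)
        else:
            if _monomorphic(table):
                p_values[j] = 1.0
            else:
                p_values[j] = odds_ratio_p(table)[1]
    return p_values


def _monomorphic(table: ContingencyTable) -> bool:
    counts = np.asarray(table.case_counts) + np.asarray(table.control_counts)
    return int((counts > 0).sum()) < 2


def relaxed_threshold(alpha: float, tolerance: float) -> float:
    """Relaxed verification threshold alpha / tolerance.

    With the default tolerance 0.8, alpha = 0.05 relaxes to 0.0625.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if not 0.0 < tolerance <= 1.0:
        raise ValidationError("tolerance must be in (0, 1]")
    return alpha / tolerance


def retention_rate(
    reported: Findings,
    reproduced_p: Mapping[str, float],
    threshold: float,
) -> float:
    """Fraction of reported-significant rsIDs still significant on reproduction."""
    significant = reported.significant_rsids()
    if not significant:
        raise ValidationError("the reported significant set is empty")
    missing = [r for r in significant if r not in reproduced_p]
    if missing:
        raise ValidationError(f"rsIDs missing from reproduced results: {missing[:5]}")
    retained = sum(1 for r in significant if reproduced_p[r] < threshold)
    return retained / len(significant)


def inject_flipping_error(
    p: np.ndarray, delta_f: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Replace a fraction delta_f of p-values with Uniform(0,1) draws.

    Exactly ``round(delta_f * m)`` entries, chosen uniformly without
    replacement, are replaced.
    """
    if not 0.0 <= delta_f <= 1.0:
        raise ValidationError("delta_f must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.asarray(p, dtype=float).copy()
    k = int(round(delta_f * p.size))
    if k:
        idx = rng.choice(p.size, size=k, replace=False)
        p[idx] = rng.random(k)
    return p


def inject_noise_error(
    p: np.ndarray, delta_n: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Add Normal(0, delta_n^2) noise to every p-value, clipped to [0, 1]."""
    if delta_n < 0:
        raise ValidationError("delta_n must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.asarray(p, dtype=float)
    return np.clip(p + rng.normal(0.0, delta_n, size=p.size), 0.0, 1.0)


@dataclass
class ValidationRow:
    error_rate: float
    mean_difference: float
    ci_low: float
    ci_high: float
    n_valid_repeats: int


def validation_experiment(
    original: SnpDataset,
    released: SnpDataset,
    test: str = "chi2",
    alpha: float = 0.05,
    tolerance: float = 0.8,
    error_model: str = "flip",
    error_rates: Sequence[float] = (0.0, 0.1, 0.5, 1.0),
    repeats: int = 10,
    seed: int = 0,
) -> list[ValidationRow]:
    """Retention-rate difference between error-free and error-injected findings.

    The researcher's p-values come from ``original``; the reported
    significant set is recomputed from the (possibly error-injected)
    p-values at ``alpha``.  The verifier reproduces the test once on
    ``released`` and evaluates retention under the relaxed threshold.  Each
    row reports the mean of (error-free retention - error-injected
    retention) over ``repeats`` injections with a normal 95% CI.  An
    injected replicate whose reported significant set is empty is skipped.
    """
    if original.rsids != released.rsids:
        raise ValidationError("datasets must share rsIDs in order")
    if error_model not in ("flip", "noise"):
        raise ValidationError(f"unknown error model {error_model!r}")
    rng = np.random.default_rng(seed)
    inject = inject_flipping_error if error_model == "flip" else inject_noise_error

    p_researcher = run_gwas(original, test)
    p_verifier = run_gwas(released, test)
    reproduced = dict(zip(original.rsids, p_verifier))
    threshold = relaxed_threshold(alpha, tolerance)
    maf = original.maf()

    def _retention(p_reported: np.ndarray) -> float:
        findings = Findings(
            records=[
                (rs, float(np.clip(pv, 0.0, 1.0)), float(fq))
                for rs, pv, fq in zip(original.rsids, p_reported, maf)
            ],
            test_name=test,
            alpha=alpha,
        )
        if not findings.significant_rsids():
            return np.nan
        return retention_rate(findings, reproduced, threshold)

    base_retention = _retention(p_researcher)
    rows = []
    for rate in error_rates:
        diffs = []
        for _ in range(repeats):
            r = _retention(inject(p_researcher, rate, rng))
            if not np.isnan(r):
                diffs.append(base_retention - r)
        diffs = np.asarray(diffs)
        mean = float(diffs.mean()) if diffs.size else np.nan
        if diffs.size > 1:
            half = 1.96 * diffs.std(ddof=1) / np.sqrt(diffs.size)
        else:
            half = 0.0
        rows.append(ValidationRow(rate, mean, mean - half, mean + half, diffs.size))
    return rows
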