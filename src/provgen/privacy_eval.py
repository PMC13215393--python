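"""Fidelity metrics, Hamming-distance membership inference, and baselines.

Fidelity between an original and a shared genotype matrix is summarised by
four symmetric metrics: the fraction of mismatched entries (point error),
the mean absolute entry difference (sample error), and the mean absolute
difference of per-SNP means and population variances.  The
membership-inference side implements the Hamming-distance test (HDT): a
victim is called a member when their minimum genotype Hamming distance to
the shared dataset falls below a threshold calibrated to a chosen false
positive rate on known non-members.  Two alternatives to the main release
mechanism are included for comparison: Laplace-protected MAF release and a
3-ary randomized-response local-DP baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import SnpDataset, ValidationError


def fidelity_report(
    d: SnpDataset, d_star: SnpDataset
) -> tuple[float, float, float, float]:
    """(point_error, sample_error, mean_error, variance_error) of two datasets.

    * point error: fraction of entries that differ;
    * sample error: mean |difference| per entry (l1, normalised by n*m);
    * mean / variance error: mean over SNPs of the absolute difference of
      per-SNP means / population variances.
    """
    if d.genotypes.shape != d_star.genotypes.shape:
        raise ValidationError("datasets must share their shape")
    if d.rsids != d_star.rsids:
        raise ValidationError("datasets must share rsIDs in order")
    a = d.genotypes.astype(float)
    b = d_star.genotypes.astype(float)
    point = float((a != b).mean())
    sample = float(np.abs(a - b).mean())
    mean_err = float(np.abs(a.mean(axis=0) - b.mean(axis=0)).mean())
    var_err = float(np.abs(a.var(axis=0) - b.var(axis=0)).mean())
    return point, sample, mean_err, var_err


def _min_hamming(queries: np.ndarray, panel: np.ndarray) -> np.ndarray:
    """Minimum genotype Hamming distance from each query row to the panel."""
    out = np.empty(queries.shape[0], dtype=int)
    for i, row in enumerate(queries):
        out[i] = int((panel != row).sum(axis=1).min())
    return out


@dataclass
class HdtResult:
    gamma: float
    calls: np.ndarray          # boolean member calls per victim
    accuracy: float
    min_distances: np.ndarray  # per-victim minimum distance to the shared set


def hdt_attack(
    shared: SnpDataset,
    reference: SnpDataset,
    victims: SnpDataset,
    membership: np.ndarray,
    fpr: float = 0.05,
    gamma_from: str = "reference_split",
    seed: int = 0,
) -> HdtResult:
    """Hamming-distance membership-inference attack against a shared dataset.

    Each victim's statistic is the minimum Hamming distance between their
    genotype vector and the rows of ``shared``.  The threshold gamma is, by
    default, the ``fpr``-quantile of the same statistic over a held-out
    half of the reference panel (known non-members), so that roughly a
    fraction ``fpr`` of non-members is falsely called member.  A victim is
    called a member iff their statistic is strictly below gamma.
    ``gamma_from="case_quantile"`` instead calibrates gamma on the shared
    individuals' minimum distances to the reference panel and scores
    victims by their distance to the reference panel.

    ``membership`` holds the ground-truth labels used only to compute the
    reported accuracy.
    """
    for other in (reference, victims):
        if other.rsids != shared.rsids:
            raise ValidationError("all datasets must share rsIDs in order")
    if not 0.0 < fpr < 1.0:
        raise ValidationError("fpr must be in (0, 1)")
    membership = np.asarray(membership, dtype=bool)
    if membership.shape != (victims.n_samples,):
        raise ValidationError("membership labels must match the victim count")

    if gamma_from == "reference_split":
        if reference.n_samples < 4:
            raise ValidationError("reference panel too small to split")
        rng = np.random.default_rng(seed)
        order = rng.permutation(reference.n_samples)
        calib_rows = reference.genotypes[order[: reference.n_samples // 2]]
        calib = _min_hamming(calib_rows, shared.genotypes)
        gamma = float(np.quantile(calib, fpr))
        stats = _min_hamming(victims.genotypes, shared.genotypes)
    elif gamma_from == "case_quantile":
        calib = _min_hamming(shared.genotypes, reference.genotypes)
        gamma = float(np.quantile(calib, fpr))
        stats = _min_hamming(victims.genotypes, reference.genotypes)
    else:
        raise ValidationError(f"unknown gamma_from {gamma_from!r}")

    calls = stats < gamma
    accuracy = float((calls == membership).mean())
    return HdtResult(gamma=gamma, calls=calls, accuracy=accuracy, min_distances=stats)


def laplace_maf_release(
    maf: np.ndarray,
    epsilon_m: float,
    n: int,
    seed: int | np.random.Generator = 0,
    per_snp: bool = False,
) -> np.ndarray:
    """Laplace-mechanism release of the length-m MAF vector, clipped to [0,1].

    One individual shifts each SNP's MAF by at most 1/n, so the vector l1
    sensitivity is m/n and the noise scale is (m/n)/epsilon_m (sequential
    composition folded into the sensitivity).  With ``per_snp=True``
    epsilon_m is interpreted per SNP instead (scale (1/n)/epsilon_m).
    """
    if epsilon_m <= 0:
        raise ValidationError("epsilon_m must be positive")
    if n <= 0:
        raise ValidationError("n must be positive")
    maf = np.asarray(maf, dtype=float)
    if ((maf < 0) | (maf > 1)).any():
        raise ValidationError("MAFs must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sensitivity = (1.0 if per_snp else maf.size) / n
    noisy = maf + rng.laplace(0.0, sensitivity / epsilon_m, size=maf.size)
    return np.clip(noisy, 0.0, 1.0)


def ldp_randomized_response(
    ds: SnpDataset, epsilon_per_snp: float, seed: int | np.random.Generator = 0
) -> SnpDataset:
    """3-ary randomized response on every genotype entry (per-entry LDP).

    Each entry keeps its true value with probability e^eps / (e^eps + 2)
    and otherwise becomes one of the two other genotypes uniformly.
    """
    if epsilon_per_snp <= 0:
        raise ValidationError("epsilon_per_snp must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keep_prob = np.exp(epsilon_per_snp) / (np.exp(epsilon_per_snp) + 2.0)
    geno = ds.genotypes.copy()
    replace = rng.random(geno.shape) >= keep_prob
    # the two alternatives to value v are (v+1)%3 and (v+2)%3, equally likely
    offset = rng.integers(1, 3, size=geno.shape)
    geno[replace] = (geno[replace] + offset[replace]) % 3
    return SnpDataset(
        geno, list(ds.sample_ids), list(ds.rsids),
        list(ds.phenotype) if ds.phenotype is not None else None,
    )
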