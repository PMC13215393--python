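"""Utility restoration: align per-SNP MAFs to published values, then decode.

The XOR noise leaves per-SNP minor-allele frequencies near 1/2; utility for
association testing is restored by transporting each SNP's empirical allele
distribution (2n bits on {0,1}) onto the published MAF.  On a two-point
space the earth mover's distance between Bernoulli laws with means a and b
is |a - b| and the optimal plan is unique: move that much mass from the
over-represented value to the other.  The integer flip count is
``floor(|a - b| * 2n)``, leaving each restored MAF within 1/(2n) of its
target.  Restoration reads only the noisy matrix and public MAFs, so by
post-processing it does not weaken the differential-privacy guarantee.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np

from .correlation import estimate_theta, scale_to_budget
from .datamodel import (
    BinaryDataset,
    PrivacyBudget,
    SnpDataset,
    ValidationError,
)
from .ebng import perturb
from .encoding import decode, encode

MafRef = Union[np.ndarray, Mapping[str, np.ndarray]]


def compute_maf(bd: BinaryDataset) -> np.ndarray:
    """Per-SNP MAF of a bit matrix: 1-bits in the SNP's two columns / 2n.

    "Minor" refers to the designated minor allele, not min(f, 1-f); after
    noise a frequency may exceed 0.5.
    """
    if bd.n_samples < 1:
        raise ValidationError("need at least one individual")
    ones = bd.bits[:, 0::2].sum(axis=0) + bd.bits[:, 1::2].sum(axis=0)
    return ones / (2.0 * bd.n_samples)


def transport_plan(
    maf_noisy: float, maf_ref: float, num_alleles: int
) -> tuple[int, str]:
    """Optimal-transport flip plan for one SNP on the two-point allele space.

    Returns ``(flip_count, direction)`` with direction one of
    ``"one_to_zero"``, ``"zero_to_one"``, ``"none"``.  The EMD between the
    two Bernoulli laws is ``|maf_noisy - maf_ref|``; the flip count is the
    floor of that fraction of the ``num_alleles = 2n`` alleles.
    """
    if not (0.0 <= maf_noisy <= 1.0 and 0.0 <= maf_ref <= 1.0):
        raise ValidationError("MAFs must lie in [0, 1]")
    if num_alleles <= 0 or num_alleles % 2 != 0:
        raise ValidationError("num_alleles must be a positive even integer (2n)")
    delta = maf_noisy - maf_ref
    flips = int(np.floor(abs(delta) * num_alleles + 1e-12))
    if flips == 0:
        return 0, "none"
    return flips, ("one_to_zero" if delta > 0 else "zero_to_one")


def restore(
    bd_noisy: BinaryDataset,
    maf_ref: np.ndarray,
    seed: int | np.random.Generator,
) -> BinaryDataset:
    """Flip randomly chosen alleles per SNP so each MAF matches its target.

    For each SNP the plan's flip count is drawn uniformly without
    replacement from the bits currently holding the source value, across
    the SNP's two columns jointly.  Afterwards every restored MAF is within
    1/(2n) of the reference.
    """
    maf_ref = np.asarray(maf_ref, dtype=float)
    if maf_ref.shape != (bd_noisy.n_snps,):
        raise ValidationError("maf_ref must have one entry per SNP")
    if ((maf_ref < 0) | (maf_ref > 1)).any():
        raise ValidationError("reference MAFs must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = bd_noisy.n_samples
    bits = bd_noisy.bits.copy()
    maf_noisy = compute_maf(bd_noisy)
    for j in range(bd_noisy.n_snps):
        flips, direction = transport_plan(maf_noisy[j], maf_ref[j], 2 * n)
        if flips == 0:
            continue
        pair = bits[:, 2 * j : 2 * j + 2]
        source = 1 if direction == "one_to_zero" else 0
        rows, cols = np.nonzero(pair == source)
        chosen = rng.choice(rows.size, size=flips, replace=False)
        pair[rows[chosen], cols[chosen]] = 1 - source
    return BinaryDataset(bits, list(bd_noisy.rsids))


def release(
    ds: SnpDataset,
    reference: BinaryDataset,
    maf_ref: MafRef,
    budget: PrivacyBudget,
    seed: int,
    pseudocount: float = 0.5,
) -> SnpDataset:
    """Full release pipeline: encode, calibrate, perturb, restore, decode.

    ``maf_ref`` is either a length-m vector (whole-dataset restoration) or,
    when the dataset carries phenotype labels, a mapping from label to
    length-m vector; in the mapping form each phenotype group is restored to
    its own published MAFs.  Group-wise restoration is still pure
    post-processing of the perturbed matrix — the noise is sampled once for
    the whole dataset and the targets are public — so the epsilon_e
    guarantee is unchanged, while the case/control allele contrast that
    association tests rely on is preserved.
    """
    if reference.n_snps != ds.n_snps:
        raise ValidationError("reference panel must cover the same SNPs")
    rng = np.random.default_rng(seed)
    db = encode(ds)
    theta_raw = estimate_theta(reference, pseudocount=pseudocount)
    theta = scale_to_budget(theta_raw, budget.sensitivity, budget.epsilon_e)
    noisy = perturb(db, theta, budget, rng)

    if isinstance(maf_ref, Mapping):
        if ds.phenotype is None:
            raise ValidationError("per-group MAFs require phenotype labels")
        bits = noisy.bits.copy()
        labels = np.asarray(ds.phenotype)
        for label, target in maf_ref.items():
            mask = labels == label
            if not mask.any():
                continue
            group = BinaryDataset(bits[mask], list(noisy.rsids))
            bits[mask] = restore(group, np.asarray(target, dtype=float), rng).bits
        restored = BinaryDataset(bits, list(noisy.rsids))
    else:
        restored = restore(noisy, np.asarray(maf_ref, dtype=float), rng)

    return decode(restored, sample_ids=list(ds.sample_ids), phenotype=ds.phenotype)
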