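"""Efficient binary noise generation (EBNG) and the XOR perturbation.

Sampling the matrix-valued Bernoulli noise of the XOR mechanism exactly
requires Monte Carlo over an intractable normalisation constant.  EBNG
instead draws each noise bit independently from a calibrated marginal: with
no kinship blocks the vectorised noise parameter is the Kronecker product
``I_n (x) Theta``, so the calibration statistic

    kappa_u = 2 * (row sum of Theta row u) - Theta_uu

depends only on the bit column, and the marginal flip probability is

    Pr(B_u = 1) = 1/2                  if kappa_u >  ||lambda(Theta)||_2
                  1 / (1 + exp(kappa_u))  if kappa_u <= ||lambda(Theta)||_2.

With Theta rescaled so ``s_f * ||lambda(Theta)||_2 = epsilon_e``, this
bit-wise mechanism satisfies epsilon_e-differential privacy on the encoded
dataset.  The normalisation constant of the exact matrix-valued law is
never evaluated.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import expit

from .datamodel import (
    BinaryDataset,
    NoiseCalibration,
    PrivacyBudget,
    ThetaMatrix,
    ValidationError,
)

log = logging.getLogger("provgen")


def compute_sensitivity(num_snps: int) -> int:
    """Worst-case bit sensitivity of the encoded release: 2 bits per SNP.

    Neighbouring datasets differ in one individual's record, which can
    differ in every one of its 2m encoded bits.
    """
    if int(num_snps) != num_snps or num_snps < 1:
        raise ValidationError("num_snps must be a positive integer")
    return 2 * int(num_snps)


def compute_kappa(theta: ThetaMatrix) -> np.ndarray:
    """Per-bit-column calibration statistic, length 2m.

    The full noise parameter is block-diagonal (``I_n (x) Theta``), so row
    ``u`` of it restricted to its block is row ``u mod 2m`` of Theta; kappa
    therefore repeats identically across individuals and only the length-2m
    vector is computed (O(m^2) instead of O((nm)^2)).
    """
    row_sums = theta.theta.sum(axis=1)
    return 2.0 * row_sums - np.diag(theta.theta)


def marginal_flip_prob(kappa_u, lambda_norm: float):
    """Two-branch marginal probability of a noise bit being 1.

    Columns with |kappa_u| > ||lambda||_2 are capped at 1/2 (zero privacy
    loss); the rest use the sigmoid 1/(1 + exp(kappa_u)).  Ties
    (|kappa| == lambda_norm) take the sigmoid branch.  The cap is symmetric
    in the sign of kappa: a sigmoid column's per-bit log-likelihood ratio
    is |kappa_u|, so a column with kappa_u < -||lambda|| would leak more
    than its ||lambda|| share of the budget — capping both tails is what
    makes the per-record loss of the bit-wise mechanism at most
    s_f * ||lambda(Theta)||_2 = epsilon_e.  Accepts scalars or arrays.
    """
    if lambda_norm < 0:
        raise ValidationError("lambda_norm must be nonnegative")
    kappa_u = np.asarray(kappa_u, dtype=float)
    p = np.where(np.abs(kappa_u) > lambda_norm, 0.5, expit(-kappa_u))
    # the sigmoid saturates for |kappa| beyond ~36; clamping moves the
    # probability toward 1/2, which only shrinks the per-bit privacy loss
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(p) if p.ndim == 0 else p


def calibrate(theta_scaled: ThetaMatrix, budget: PrivacyBudget) -> NoiseCalibration:
    """Build the per-column noise calibration from a budget-scaled Theta."""
    kappa = compute_kappa(theta_scaled)
    lam = theta_scaled.eig_l2
    return NoiseCalibration(
        kappa=kappa,
        flip_prob=marginal_flip_prob(kappa, lam),
        lambda_norm=lam,
        epsilon_e=budget.epsilon_e,
        sensitivity=budget.sensitivity,
    )


def sample_noise(
    calib: NoiseCalibration, n: int, seed: int | np.random.Generator
) -> BinaryDataset:
    """Sample the n x 2m noise matrix: independent Bernoulli per column.

    The same seed always yields the same matrix.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bits = (rng.random((n, calib.n_bits)) < calib.flip_prob).astype(np.int8)
    rsids = [f"bit{u}" for u in range(calib.n_bits // 2)]
    return BinaryDataset(bits, rsids)


def perturb(
    db: BinaryDataset,
    theta: ThetaMatrix,
    budget: PrivacyBudget,
    seed: int | np.random.Generator,
) -> BinaryDataset:
    """XOR the encoded dataset with freshly sampled calibrated noise.

    ``theta`` must already be scaled to the budget (see
    :func:`provgen.correlation.scale_to_budget`).
    """
    if theta.n_bits != db.bits.shape[1]:
        raise ValidationError(
            f"theta is {theta.n_bits} bits wide but the dataset has "
            f"{db.bits.shape[1]} bit columns"
        )
    if budget.sensitivity != db.bits.shape[1]:
        raise ValidationError("budget sensitivity must equal the bit-column count")
    calib = calibrate(theta, budget)
    noise = sample_noise(calib, db.n_samples, seed)
    noisy = np.bitwise_xor(db.bits, noise.bits)
    realized = noise.bits.mean(axis=0)
    log.info(
        "perturb: n=%d, bits=%d, eps_e=%.4g, mean flip fraction=%.4f",
        db.n_samples, db.bits.shape[1], budget.epsilon_e, float(realized.mean()),
    )
    return BinaryDataset(noisy, list(db.rsids))


def per_bit_privacy_loss(calib: NoiseCalibration) -> float:
    """Worst-case log-likelihood ratio of the bit-wise mechanism.

    Sums ``|log((1-p_u)/p_u)|`` over the 2m bit columns — the privacy loss
    when one record changes in every bit.  Columns at probability 1/2
    contribute nothing; sigmoid-branch columns contribute ``|kappa_u|``.
    """
    p = calib.flip_prob
    return float(np.abs(np.log((1.0 - p) / p)).sum())
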