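"""SNP-bit association matrix: log-linear estimation and budget rescaling.

The bit-level association matrix Theta parameterises the matrix-valued
Bernoulli noise of the XOR mechanism.  Its entries are log-linear
association values estimated from a public reference panel of the same
SNPs: diagonal entries are the log odds of a bit column being 0, and
off-diagonal entries are the log odds ratio of the 2x2 joint table of two
bit columns.  The release mechanism is epsilon-DP whenever

    s_f * ||lambda(Theta)||_2 <= epsilon_e,

where s_f is the bit sensitivity (2m) and ||lambda(.)||_2 the l2 norm of
the eigenvalue vector; any Theta satisfying the condition is admissible, so
the estimate is rescaled to meet it with equality, retaining as much
correlation signal as the budget allows.
"""

from __future__ import annotations

import numpy as np

from .datamodel import BinaryDataset, ThetaMatrix, ValidationError

DEFAULT_PSEUDOCOUNT = 0.5


def eig_l2_norm(theta: np.ndarray) -> float:
    """l2 norm of the eigenvalue vector of a square symmetric matrix.

    For symmetric matrices this equals the Frobenius norm; the eigenvalues
    are still computed explicitly so the function is usable as a check.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValidationError("eig_l2_norm requires a square matrix")
    eigenvalues = np.linalg.eigvalsh(theta)
    return float(np.linalg.norm(eigenvalues))


def _block_theta(bits: np.ndarray, pseudocount: float) -> np.ndarray:
    """Dense log-linear Theta block for a set of bit columns."""
    n, p = bits.shape
    x = bits.astype(float)
    c1 = x.sum(axis=0)
    c0 = n - c1

    n11 = x.T @ x
    n10 = c1[:, None] - n11
    n01 = c1[None, :] - n11
    n00 = n - n11 - n10 - n01

    if pseudocount == 0.0:
        off = ~np.eye(p, dtype=bool)  # the diagonal self-pair is always empty
        cells = np.stack([n00[off], n01[off], n10[off], n11[off]])
        if (cells == 0).any() or (c0 == 0).any() or (c1 == 0).any():
            raise ValidationError(
                "empty frequency cell with pseudocount 0; "
                "use a positive pseudocount"
            )

    # marginal smoothing over 2 cells, joint smoothing over 4 cells
    p0 = (c0 + pseudocount) / (n + 2 * pseudocount)
    p1 = (c1 + pseudocount) / (n + 2 * pseudocount)
    denom = n + 4 * pseudocount
    j00 = (n00 + pseudocount) / denom
    j01 = (n01 + pseudocount) / denom
    j10 = (n10 + pseudocount) / denom
    j11 = (n11 + pseudocount) / denom

    with np.errstate(divide="ignore"):  # diagonal self-pair, overwritten below
        theta = np.log(j01 * j10) - np.log(j11 * j00)
    np.fill_diagonal(theta, np.log(p0 / p1))
    return (theta + theta.T) / 2.0


def estimate_theta(
    reference: BinaryDataset,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    block_snps: int | None = None,
    max_dense_snps: int = 2000,
) -> ThetaMatrix:
    """Estimate the 2m x 2m bit association matrix from a reference panel.

    All marginal and joint frequencies are Laplace-smoothed: each cell count
    gains ``pseudocount`` and the total gains ``cells * pseudocount``, which
    keeps every log finite for a positive pseudocount.  The result is
    symmetrised to protect downstream eigenvalue routines from round-off.

    For panels beyond ``max_dense_snps`` SNPs, Theta is built block-diagonal
    over contiguous windows of ``block_snps`` SNPs (default 500): linkage
    disequilibrium is local, and the eigenvalue norm of a block-diagonal
    matrix is the l2 norm over per-block norms, so the budget condition is
    unaffected.
    """
    if reference.n_samples < 2:
        raise ValidationError("reference panel needs at least 2 rows")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    m = reference.n_snps
    if block_snps is None and m > max_dense_snps:
        block_snps = 500
    if block_snps is None:
        theta = _block_theta(reference.bits, pseudocount)
    else:
        theta = np.zeros((2 * m, 2 * m))
        for start in range(0, m, block_snps):
            stop = min(start + block_snps, m)
            sl = slice(2 * start, 2 * stop)
            theta[sl, sl] = _block_theta(reference.bits[:, sl], pseudocount)
    return ThetaMatrix(theta=theta, pseudocount=pseudocount)


def scale_to_budget(
    theta_raw: ThetaMatrix, sensitivity: int, epsilon_e: float
) -> ThetaMatrix:
    """Rescale Theta so the DP sufficient condition holds with equality.

    Returns ``c * Theta`` with ``c = epsilon_e / (sensitivity * ||lambda||)``
    so that ``sensitivity * ||lambda(c * Theta)|| == epsilon_e`` exactly (no
    kinship terms; the sample-association sums are zero).  ``c`` may exceed
    1 when the raw norm is small.
    """
    if epsilon_e <= 0:
        raise ValidationError("epsilon_e must be positive")
    if sensitivity <= 0:
        raise ValidationError("sensitivity must be positive")
    if theta_raw.eig_l2 <= 0:
        raise ValidationError(
            "cannot scale an all-zero Theta: the budget condition is vacuous"
        )
    c = epsilon_e / (sensitivity * theta_raw.eig_l2)
    return ThetaMatrix(
        theta=c * theta_raw.theta,
        pseudocount=theta_raw.pseudocount,
        eig_l2=c * theta_raw.eig_l2,
    )
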