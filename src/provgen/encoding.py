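"""Lossless 2-bit SNP encoding and the biased total decode.

Each genotype maps to an ordered bit pair — 0 -> (0,0), 1 -> (0,1),
2 -> (1,1) — mirroring the two parental alleles, so flipping one bit of the
encoded matrix is analogous to flipping one allele.  Decoding is total: the
pair (1,0), which the encoder never emits, decodes to genotype 1, keeping
every binary matrix interpretable as a genotype matrix.
"""

from __future__ import annotations

import numpy as np

from .datamodel import BinaryDataset, SnpDataset


def encode(ds: SnpDataset) -> BinaryDataset:
    """Encode an n x m genotype matrix to its n x 2m bit representation."""
    n, m = ds.genotypes.shape
    bits = np.zeros((n, 2 * m), dtype=np.int8)
    # high bit (even column) set only for genotype 2; low bit for 1 and 2
    bits[:, 0::2] = (ds.genotypes == 2)
    bits[:, 1::2] = (ds.genotypes >= 1)
    return BinaryDataset(bits, list(ds.rsids))


def decode(
    bd: BinaryDataset,
    sample_ids: list[str] | None = None,
    phenotype: list[str] | None = None,
) -> SnpDataset:
    """Decode an n x 2m bit matrix back to genotypes.

    Valid pairs invert the encoding; the invalid pair (1,0) decodes to 1, so
    the genotype equals the number of 1-bits in the pair.
    """
    high = bd.bits[:, 0::2]
    low = bd.bits[:, 1::2]
    geno = (high + low).astype(np.int8)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(bd.n_samples)]
    return SnpDataset(geno, ids, list(bd.rsids), phenotype)
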