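"""Readers and writers for genotype TSV, VCF ingestion, bit TSV and findings.

Genotype TSV dialect: tab-separated, header ``sample_id<TAB>rs...``, one row
per individual, cells in {0,1,2}.  An optional ``phenotype`` column (written
last) carries case/control labels.  VCF is read-only ingestion of biallelic
sites; the ALT allele is treated as the minor allele and GT is converted to
ALT-allele dosage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datamodel import (
    BinaryDataset,
    Findings,
    FindingsRecord,
    SnpDataset,
    ValidationError,
)

log = logging.getLogger("provgen")

PHENOTYPE_COLUMN = "phenotype"


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


def read_snp_matrix(path: Union[str, Path], format: str = "tsv") -> SnpDataset:
    """Read a genotype matrix from ``path`` as a validated :class:`SnpDataset`.

    ``format`` is ``"tsv"`` (native dialect) or ``"vcf"`` (biallelic sites
    only; GT becomes ALT-allele dosage 0/1/2).
    """
    if format == "tsv":
        return _read_tsv(Path(path))
    if format == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> SnpDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    phenotype = None
    if PHENOTYPE_COLUMN in df.columns:
        phenotype = df[PHENOTYPE_COLUMN].tolist()
        df = df.drop(columns=[PHENOTYPE_COLUMN])
    sample_ids = df["sample_id"].tolist()
    rsids = list(df.columns[1:])
    cells = df.iloc[:, 1:].to_numpy()
    geno = np.empty(cells.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(cells):
        if cell not in ("0", "1", "2"):
            raise ParseError(
                f"{path}: malformed cell {cell!r} at row {i} (sample "
                f"{sample_ids[i]!r}), column {rsids[j]!r}; expected 0/1/2"
            )
        geno[i, j] = int(cell)
    return SnpDataset(geno, sample_ids, rsids, phenotype)


def _read_vcf(path: Path) -> SnpDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rsids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            log.warning(
                "skipping multi-allelic site %s at %s:%d",
                variant.ID, variant.CHROM, variant.POS,
            )
            continue
        dosage = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                raise ParseError(
                    f"{path}: missing genotype for sample {sample_ids[i]!r} "
                    f"at {variant.ID or variant.POS}; complete matrices required"
                )
            dosage[i] = sum(int(a != 0) for a in alleles)
        rsids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(dosage)
    geno = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), np.int8)
    )
    return SnpDataset(geno, sample_ids, rsids)


def write_snp_matrix(ds: SnpDataset, path: Union[str, Path], format: str = "tsv") -> None:
    """Write ``ds`` so that :func:`read_snp_matrix` reproduces it exactly."""
    if format != "tsv":
        raise ValueError(f"unsupported output format {format!r}")
    df = pd.DataFrame(ds.genotypes, columns=ds.rsids)
    df.insert(0, "sample_id", ds.sample_ids)
    if ds.phenotype is not None:
        df[PHENOTYPE_COLUMN] = ds.phenotype
    df.to_csv(path, sep="\t", index=False)


def write_bit_matrix(bd: BinaryDataset, path: Union[str, Path],
                     sample_ids: list[str] | None = None) -> None:
    """Write a bit matrix as TSV with paired columns ``rsX_a``/``rsX_b``."""
    columns = [f"{rs}_{suffix}" for rs in bd.rsids for suffix in ("a", "b")]
    df = pd.DataFrame(bd.bits, columns=columns)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(bd.n_samples)]
    df.insert(0, "sample_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_bit_matrix(path: Union[str, Path]) -> BinaryDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    bit_cols = list(df.columns[1:])
    if len(bit_cols) % 2 != 0:
        raise ValidationError(f"{path}: odd number of bit columns")
    rsids = []
    for k in range(0, len(bit_cols), 2):
        a, b = bit_cols[k], bit_cols[k + 1]
        if not (a.endswith("_a") and b.endswith("_b") and a[:-2] == b[:-2]):
            raise ParseError(f"{path}: unpaired bit columns {a!r}, {b!r}")
        rsids.append(a[:-2])
    bits = df.iloc[:, 1:].to_numpy().astype(np.int8)
    return BinaryDataset(bits, rsids)


def read_findings(path: Union[str, Path], format: str | None = None) -> Findings:
    """Read published findings from JSON or TSV."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        payload = json.loads(path.read_text())
        records = [
            FindingsRecord(r["rsid"], float(r["p_value"]), float(r["maf"]))
            for r in payload["records"]
        ]
        return Findings(
            records,
            test_name=payload.get("test_name", "chi2"),
            alpha=float(payload.get("alpha", 0.05)),
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        records = [
            FindingsRecord(str(row.rsid), float(row.p_value), float(row.maf))
            for row in df.itertuples()
        ]
        return Findings(records)
    raise ValueError(f"unknown findings format {format!r}")


def write_findings(f: Findings, path: Union[str, Path], format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        payload = {
            "test_name": f.test_name,
            "alpha": f.alpha,
            "records": [
                {"rsid": r.rsid, "p_value": r.p_value, "maf": r.maf}
                for r in f.records
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "tsv":
        df = pd.DataFrame(
            {
                "rsid": [r.rsid for r in f.records],
                "p_value": [repr(r.p_value) for r in f.records],
                "maf": [repr(r.maf) for r in f.records],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown findings format {format!r}")
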