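"""PLINK1 binary genotype I/O (.bed/.bim/.fam).

SNP-major .bed layout: three magic bytes ``6C 1B 01`` then, per SNP, one
2-bit code per sample packed four to a byte, least-significant pair first:
``00`` = homozygous A1 (minor, additive code 2), ``10`` = heterozygous,
``11`` = homozygous A2 (major, code 0), ``01`` = missing.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeStudy

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# additive minor-allele count per 2-bit code
_CODE_TO_GENO = np.array([2, MISSING, 1, 0], dtype=np.int8)
_GENO_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def write_bed(study: GenotypeStudy, prefix: str | os.PathLike) -> None:
    """Write a study as ``prefix.bed/.bim/.fam``."""
    prefix = os.fspath(prefix)
    n_samples, n_snps = study.genotypes.shape
    codes = np.empty((n_snps, n_samples), dtype=np.uint8)
    g = study.genotypes.T
    for geno, code in _GENO_TO_CODE.items():
        codes[g == geno] = code

    n_bytes = (n_samples + 3) // 4
    padded = np.full((n_snps, n_bytes * 4), 0b01, dtype=np.uint8)
    padded[:, :n_samples] = codes
    quads = padded.reshape(n_snps, n_bytes, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": study.snp_table["chrom"],
            "snp": study.snp_table["snp"],
            "cm": 0,
            "pos": study.snp_table["pos"],
            "a1": study.snp_table["a1"],
            "a2": study.snp_table["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": study.sample_ids,
            "iid": study.sample_ids,
            "pid": 0,
            "mid": 0,
            "sex": 0,
            # .fam phenotype convention: 1 = control, 2 = case
            "pheno": np.where(study.phenotype == 1, 2, 1),
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_bed(prefix: str | os.PathLike) -> GenotypeStudy:
    """Read ``prefix.bed/.bim/.fam`` into a :class:`GenotypeStudy`."""
    prefix = os.fspath(prefix)
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    n_samples = len(fam)
    n_snps = len(bim)
    n_bytes = (n_samples + 3) // 4

    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != n_snps * n_bytes:
        raise ValueError(
            f"{prefix}.bed has {raw.size} data bytes, expected {n_snps * n_bytes}"
        )
    raw = raw.reshape(n_snps, n_bytes)
    codes = np.empty((n_snps, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    genotypes = _CODE_TO_GENO[codes[:, :n_samples]].T.copy()

    study = GenotypeStudy(
        sample_ids=list(fam["iid"]),
        phenotype=(fam["pheno"].to_numpy() == 2).astype(np.int8),
        genotypes=genotypes,
        snp_table=pd.DataFrame(
            {
                "snp": bim["snp"],
                "chrom": bim["chrom"],
                "pos": bim["pos"],
                "a1": bim["a1"],
                "a2": bim["a2"],
                "maf": np.nan,
            }
        ),
    )
    study.recompute_maf()
    return study
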