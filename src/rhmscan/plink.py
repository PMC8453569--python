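"""Bit-exact PLINK 1 bed/bim/fam reader and writer.

The ``.bed`` file is the SNP-major binary layout: three magic bytes
``0x6c 0x1b 0x01`` followed by ``ceil(n_samples / 4)`` bytes per marker, two
bits per sample in sample order (low bits first).  Two-bit codes map to
allele-B dosages as::

    0b00  homozygous A1 (allele A)  -> 0
    0b01  missing                   -> NaN
    0b10  heterozygous              -> 1
    0b11  homozygous A2 (allele B)  -> 2

i.e. dosage counts copies of the second allele column of the ``.bim`` file.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GenotypeDataset

_MAGIC = bytes([0x6C, 0x1B, 0x01])
#: 2-bit code -> dosage (index by code)
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])
_MISSING_CODE = 0b01


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triple is malformed."""


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "allele_a", "allele_b"],
        dtype={"chrom": str, "snp_id": str, "allele_a": str, "allele_b": str},
    )
    if bim["snp_id"].duplicated().any():
        dup = bim.loc[bim["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PlinkFormatError(f"{path}: duplicate SNP id {dup!r}")
    return bim


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a PLINK 1 bed/bim/fam triple into a :class:`GenotypeDataset`.

    Parameters
    ----------
    prefix
        Path without extension; ``prefix.bed``, ``.bim`` and ``.fam`` must exist.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(prefix.with_suffix(ext))

    bim = _read_bim(prefix.with_suffix(".bim"))
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:3]) != _MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes at offset 0 "
            f"(got {bytes(raw[:3]).hex() if raw.size >= 3 else raw.tobytes().hex()})"
        )
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{m} SNPs x {n} samples, found {body.size} (offset {3 + body.size})"
        )

    # unpack 2-bit codes, SNP-major: rows = SNPs, cols = samples
    blocks = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    return GenotypeDataset(
        dosages=dosages,
        sample_ids=list(fam["iid"]),
        marker_map=bim[["chrom", "snp_id", "bp", "allele_a", "allele_b"]].copy(),
    )


def write_plink(dataset: GenotypeDataset, prefix: str | os.PathLike) -> None:
    """Write a dataset as a PLINK 1 bed/bim/fam triple (SNP-major bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.n_animals, dataset.n_snps

    d = dataset.dosages
    if not np.all(np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))):
        raise ValueError("dosages must be 0/1/2 or NaN to write PLINK")
    # dosage -> 2-bit code
    codes = np.full(d.shape, _MISSING_CODE, dtype=np.uint8)
    codes[d == 0.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 2.0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = dataset.marker_map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in bim.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\t{row.allele_a}\t{row.allele_b}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in dataset.sample_ids:
            fh.write(f"0\t{iid}\t0\t0\t0\t-9\n")
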