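"""Text-table IO: test-day phenotype TSVs and scan-result TSVs."""

from __future__ import annotations

import os
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .datasets import TESTDAY_COLUMNS, TRAIT_COLUMNS, TestDayTable

if TYPE_CHECKING:  # pragma: no cover
    from .scan import WindowResult

#: Column order of a scan-results TSV.
SCAN_RESULT_COLUMNS = [
    "trait",
    "chrom",
    "window",
    "start_snp",
    "start_bp",
    "end_snp",
    "end_bp",
    "n_snps",
    "lrt",
    "p_mixture",
    "h2_v",
    "significance",
    "converged",
]


def read_testday_table(path: str | os.PathLike) -> TestDayTable:
    """Read a tab-separated test-day table.

    Mandatory header columns are those of :data:`~rhmscan.datasets.TESTDAY_COLUMNS`;
    blank trait cells become missing values; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "flock": str})
    missing = [c for c in TESTDAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return TestDayTable(df[TESTDAY_COLUMNS].copy())


def write_testday_table(table: TestDayTable, path: str | os.PathLike) -> None:
    """Write a test-day table as TSV with the canonical header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data[TESTDAY_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


def _chrom_sort_key(label: str):
    return (0, int(label)) if str(label).isdigit() else (1, str(label))


def write_scan_results(results: Iterable["WindowResult"], path: str | os.PathLike) -> None:
    """Write window scan results as a TSV sorted by (trait, chromosome, window).

    LRT and related floats are written with ``repr`` precision so a round-trip
    parse recovers them exactly.
    """
    results = list(results)
    if not results:
        raise ValueError("no scan results to write")
    rows = [r.to_row() for r in results]
    df = pd.DataFrame(rows, columns=SCAN_RESULT_COLUMNS)
    df = df.sort_values(
        by=["trait", "chrom", "window"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
        kind="stable",
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan_results(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a scan-results TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SCAN_RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def write_gcta_grm(grm, prefix: str | os.PathLike) -> None:
    """Export a GRM in the GCTA text layout (.grm.gz unzipped + .grm.id).

    One line per lower-triangle pair: ``i j n_snps value`` with 1-based indices.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = len(grm.sample_ids)
    with open(str(prefix) + ".grm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{grm.matrix[i, j]:.17g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in grm.sample_ids:
            fh.write(f"0\t{iid}\n")


def read_gcta_grm(prefix: str | os.PathLike):
    """Read a GRM written by :func:`write_gcta_grm`."""
    from .grm import GRM

    prefix = Path(prefix)
    with open(str(prefix) + ".grm.id") as fh:
        ids = [line.split()[1] for line in fh]
    n = len(ids)
    mat = np.zeros((n, n))
    n_snps = 0
    with open(str(prefix) + ".grm") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            mat[i, j] = mat[j, i] = float(v)
            n_snps = int(m)
    return GRM(matrix=mat, sample_ids=ids, n_snps=n_snps)
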