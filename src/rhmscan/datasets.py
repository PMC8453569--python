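"""Core in-memory containers: genotype matrices and test-day phenotype tables.

Conventions
-----------
* Dosages count copies of the *second* (B) allele of each marker, matching the
  last allele column of a PLINK ``.bim`` file; missing genotypes are ``NaN``.
* Marker coordinates are 1-based inclusive base pairs, as in ``.bim`` files.
* The test-day table is long format: one row per (animal, test date), with the
  fixed-effect covariates of a repeatability test-day model plus the five milk
  traits (milk yield, fat %, fat yield, protein %, protein yield).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns a test-day table must carry, in canonical order.
TESTDAY_COLUMNS = [
    "animal_id",
    "flock",
    "test_date",
    "lambing_date",
    "parity",
    "litter_size",
    "season",
    "dim",
    "my",
    "fpc",
    "fy",
    "ppc",
    "py",
]

#: The five milk traits, by table column name.
TRAIT_COLUMNS = ["my", "fpc", "fy", "ppc", "py"]

#: Ovine autosome labels (OAR 1-26).
SHEEP_AUTOSOMES = frozenset(str(i) for i in range(1, 27))


@dataclass
class GenotypeDataset:
    """SNP dosages (animals x markers) plus the marker map and sample ids.

    Parameters
    ----------
    dosages
        float array of shape ``(n_animals, n_snps)`` with entries 0/1/2 or NaN.
    sample_ids
        Unique animal identifiers, one per dosage row.
    marker_map
        DataFrame with columns ``chrom`` (str), ``snp_id`` (str), ``bp`` (int),
        ``allele_a`` (str) and ``allele_b`` (str); one row per dosage column.
        Within each chromosome positions must be non-decreasing.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-d (animals x SNPs) array")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for "
                f"{self.dosages.shape[0]} dosage rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if len(self.marker_map) != self.dosages.shape[1]:
            raise ValueError(
                f"marker map has {len(self.marker_map)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        self.marker_map = self.marker_map.reset_index(drop=True)
        self.marker_map["chrom"] = self.marker_map["chrom"].astype(str)
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) < 0):
                raise ValueError(f"bp positions decrease within chromosome {chrom}")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, samples=None, snps=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample / SNP indices."""
        samples = np.arange(self.n_animals) if samples is None else np.asarray(samples)
        snps = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeDataset(
            dosages=self.dosages[np.ix_(samples, snps)],
            sample_ids=[self.sample_ids[i] for i in samples],
            marker_map=self.marker_map.iloc[snps].reset_index(drop=True),
        )

    def snp_indices(self, chrom: str) -> np.ndarray:
        """0-based column indices of the markers on one chromosome."""
        return np.flatnonzero((self.marker_map["chrom"] == str(chrom)).to_numpy())


@dataclass
class TestDayTable:
    """Long-format repeated test-day records with covariates and traits."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TESTDAY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"test-day table is missing columns: {missing}")
        df = self.data.reset_index(drop=True).copy()
        df["animal_id"] = df["animal_id"].astype(str)
        df["flock"] = df["flock"].astype(str)
        for col in ("test_date", "lambing_date", "parity", "litter_size", "season", "dim"):
            df[col] = df[col].astype(int)
        for col in TRAIT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df["parity"] < 1).any():
            raise ValueError("parity must be >= 1")
        if (df["dim"] < 0).any():
            raise ValueError("days in milk must be >= 0")
        dup = df.duplicated(subset=["animal_id", "test_date"])
        if dup.any():
            bad = df.loc[dup, ["animal_id", "test_date"]].iloc[0]
            raise ValueError(
                "duplicate (animal, test date) record: "
                f"animal {bad['animal_id']} on day {bad['test_date']}"
            )
        self.data = df

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.data["animal_id"]))

    def describe_traits(self) -> pd.DataFrame:
        """Per-trait descriptive statistics: N, mean, SD, CV (%), min, max."""
        rows = []
        for trait in TRAIT_COLUMNS:
            v = self.data[trait].dropna().to_numpy()
            if v.size == 0:
                rows.append((trait, 0) + (np.nan,) * 5)
                continue
            mean, sd = float(v.mean()), float(v.std(ddof=1))
            rows.append(
                (trait, v.size, mean, sd, coefficient_of_variation(mean, sd),
                 float(v.min()), float(v.max()))
            )
        return pd.DataFrame(
            rows, columns=["trait", "n", "mean", "sd", "cv_pct", "min", "max"]
        )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent: 100 * sd / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean
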