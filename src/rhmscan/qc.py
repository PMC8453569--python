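"""Phenotype and genotype quality control.

Genotype filters follow standard SNP-chip practice for a small dairy-sheep
population: autosomes only, per-sample and per-SNP call rate > 95%, minor
allele frequency > 2%, and removal of SNPs in extreme Hardy-Weinberg
disequilibrium (exact-test p < 0.001).  Phenotype filters drop lactations
longer than 300 days or with fewer than three test-day records, and records
with missing trait values.  Every removal is itemized in a :class:`QCReport`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import SHEEP_AUTOSOMES, TRAIT_COLUMNS, GenotypeDataset, TestDayTable


@dataclass
class QCStage:
    stage: str
    entity: str  # "records" | "animals" | "snps" | "samples"
    n_input: int
    n_removed: int

    @property
    def n_remaining(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class QCReport:
    """Ordered per-rule removal counts; counts reconcile at every stage."""

    stages: list[QCStage] = field(default_factory=list)

    def add(self, stage: str, entity: str, n_input: int, n_removed: int) -> None:
        if not 0 <= n_removed <= n_input:
            raise ValueError(f"stage {stage}: removed {n_removed} of {n_input}")
        self.stages.append(QCStage(stage, entity, n_input, n_removed))

    def removed(self, stage: str) -> int:
        return sum(s.n_removed for s in self.stages if s.stage == stage)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "stage": s.stage,
                    "entity": s.entity,
                    "input": s.n_input,
                    "removed": s.n_removed,
                    "remaining": s.n_remaining,
                }
                for s in self.stages
            ],
            indent=2,
        )

    def lines(self) -> list[str]:
        return [
            f"QC {s.stage}: removed {s.n_removed}/{s.n_input} {s.entity} "
            f"({s.n_remaining} remaining)"
            for s in self.stages
        ]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "\n".join(self.lines())


# ---------------------------------------------------------------------------
# phenotype QC
# ---------------------------------------------------------------------------

def filter_testday_records(
    table: TestDayTable,
    max_lactation_days: int = 300,
    min_td: int = 3,
    trait: str | None = None,
) -> tuple[TestDayTable, QCReport]:
    """Apply the phenotype filters, in order, and report removals.

    1. drop lactations (animal x parity) whose last test-day DIM exceeds
       ``max_lactation_days``;
    2. drop lactations with fewer than ``min_td`` records;
    3. drop records missing the analysed ``trait`` (or missing *any* trait when
       ``trait`` is None).

    An empty surviving table is allowed and reported, never raised.
    """
    df = table.data
    report = QCReport()
    lact = list(zip(df["animal_id"], df["parity"]))
    lact_key = df["animal_id"].str.cat(df["parity"].astype(str), sep="\x00")

    max_dim = df.groupby(lact_key)["dim"].transform("max")
    keep = max_dim <= max_lactation_days
    report.add("lactation_length", "records", len(df), int((~keep).sum()))
    df = df[keep]
    lact_key = lact_key[keep]

    n_td = df.groupby(lact_key)["dim"].transform("size")
    keep = n_td >= min_td
    report.add("min_testdays", "records", len(df), int((~keep).sum()))
    df = df[keep]

    traits = [trait] if trait is not None else TRAIT_COLUMNS
    for t in traits:
        if t not in df.columns:
            raise ValueError(f"unknown trait {t!r}")
    keep = df[traits].notna().all(axis=1)
    report.add("missing_trait", "records", len(df), int((~keep).sum()))
    df = df[keep]

    n_animals_in = len(set(a for a, _ in lact))
    n_animals_out = df["animal_id"].nunique()
    report.add("animals", "animals", n_animals_in, n_animals_in - n_animals_out)
    return TestDayTable(df.reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic SNP.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (of the same parity) that are no more probable than
    the observed one.  Returns a value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)

    # log-probability of h heterozygotes, up to a constant shared by all h
    def logp(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = (max(n_a, n_b) - h) // 2
        return (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([logp(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[(n_ab - rare % 2) // 2]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def apply_genotype_qc(
    dataset: GenotypeDataset,
    sample_cr: float = 0.95,
    snp_cr: float = 0.95,
    maf_min: float = 0.02,
    hwe_p: float = 0.001,
    autosomes: frozenset[str] | set[str] = SHEEP_AUTOSOMES,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the genotype filters in fixed order and report removals.

    Order: non-autosomes -> sample call rate -> SNP call rate -> MAF -> HWE.
    Retention thresholds are strict in the stated direction: call rates
    > ``sample_cr`` / ``snp_cr``, MAF > ``maf_min``, HWE exact p >= ``hwe_p``.
    Allele frequencies are recomputed after sample removal, from observed
    (non-missing) genotypes only.
    """
    report = QCReport()
    autosomes = {str(a) for a in autosomes}

    def _check_nonempty(ds: GenotypeDataset) -> None:
        if ds.n_snps == 0:
            raise ValueError(
                "genotype QC removed every SNP; review thresholds "
                "(call rate, MAF, HWE) against the input data"
            )

    chrom = dataset.marker_map["chrom"].to_numpy()
    keep_snps = np.flatnonzero(np.isin(chrom, list(autosomes)))
    report.add("autosome", "snps", dataset.n_snps, dataset.n_snps - keep_snps.size)
    ds = dataset.subset(snps=keep_snps)
    _check_nonempty(ds)

    observed = ~np.isnan(ds.dosages)
    cr_sample = observed.mean(axis=1)
    keep_samples = np.flatnonzero(cr_sample > sample_cr)
    report.add("sample_call_rate", "samples", ds.n_animals, ds.n_animals - keep_samples.size)
    ds = ds.subset(samples=keep_samples)

    observed = ~np.isnan(ds.dosages)
    cr_snp = observed.mean(axis=0)
    keep_snps = np.flatnonzero(cr_snp > snp_cr)
    report.add("snp_call_rate", "snps", ds.n_snps, ds.n_snps - keep_snps.size)
    ds = ds.subset(snps=keep_snps)
    _check_nonempty(ds)

    with np.errstate(invalid="ignore"):
        p = np.nanmean(ds.dosages, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_snps = np.flatnonzero(maf > maf_min)
    report.add("maf", "snps", ds.n_snps, ds.n_snps - keep_snps.size)
    ds = ds.subset(snps=keep_snps)
    _check_nonempty(ds)

    keep = np.ones(ds.n_snps, dtype=bool)
    for j in range(ds.n_snps):
        col = ds.dosages[:, j]
        col = col[~np.isnan(col)]
        counts = [int((col == k).sum()) for k in (0.0, 1.0, 2.0)]
        if hwe_exact_pvalue(*counts) < hwe_p:
            keep[j] = False
    report.add("hwe", "snps", ds.n_snps, int((~keep).sum()))
    ds = ds.subset(snps=np.flatnonzero(keep))
    _check_nonempty(ds)
    return ds, report
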