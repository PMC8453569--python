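"""Synthetic genotypes and repeated test-day phenotypes with known truth.

The generator emulates the data structure of a small Mediterranean dairy-sheep
population genotyped on a 50k chip: ~26 autosomes of biallelic SNPs, a few
hundred ewes in a handful of flocks, up to five parities with a handful of
roughly monthly test-day records per lactation, and the variance structure of
a repeatability test-day animal model,

    y = Xb + Z1 u + Z1 pu + Z2 pw + Z3 h + e,

with additive genomic (u, covariance G), permanent environment across (pu) and
within (pw) lactation, flock-by-test-day (h) and residual (e) components.
Optional QTL windows add a regional genomic effect v with target variance
``sigma2_v``.  Polygenic and regional breeding values are rescaled so their
realized variance in the metric of their own GRM (``u' G^+ u / rank``) hits
the target exactly - the same quantity the REML model estimates - giving
recovery tests a fixed truth; the environmental components are plain normal
draws.

Genotypes are simulated in linkage equilibrium; an optional autoregressive
within-chromosome correlation mode is available for visual realism but the
window-level regional effect is what carries the mappable signal.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TESTDAY_COLUMNS, TRAIT_COLUMNS, GenotypeDataset, TestDayTable
from .io import write_testday_table
from .plink import write_plink

#: Default variance components: the F%-like structure of a repeatability
#: test-day model on a small dairy-sheep population (phenotypic variance
#: ~1.12 in squared percentage units).
DEFAULT_COMPONENTS = {
    "u": 0.1276,   # additive genomic
    "pu": 0.0734,  # permanent environment across lactations
    "pw": 0.0620,  # permanent environment within parity
    "h": 0.4530,   # flock x test-day
    "e": 0.4041,   # residual
}

COMPONENT_NAMES = ("u", "pu", "pw", "h", "e")


def _default_fixed_effects() -> dict[str, np.ndarray]:
    # a gently rising lactation curve for a percentage trait, small class effects
    fim = np.linspace(-0.25, 0.35, 22)
    return {
        "intercept": np.array([7.0]),
        "parity": np.array([0.0, 0.12, 0.18, 0.20, 0.16]),
        "litter_size": np.array([0.0, -0.10]),
        "season": np.array([0.0, 0.06]),
        "fim": fim,
    }


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    ``qtl_windows`` entries are ``(chrom_label, (start, stop), sigma2_v)`` with
    a 0-based half-open SNP index range *within* that chromosome.
    """

    n_animals: int = 481
    snps_per_chromosome: list[int] = field(default_factory=lambda: [1432] * 26)
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS)
    )
    qtl_windows: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    n_flocks: int = 4
    n_sire_families: int = 9  # half-sib families; 0 = unrelated animals
    parities_per_animal: int = 3
    testdays_per_lactation: tuple[int, int] = (3, 9)
    fixed_effect_coefficients: dict[str, np.ndarray] = field(
        default_factory=_default_fixed_effects
    )
    trait: str = "fpc"
    ld_rho: float = 0.0  # optional AR(1) latent correlation between adjacent SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if min(self.snps_per_chromosome, default=0) < 1:
            raise ValueError("every chromosome needs at least 1 SNP")
        for name in COMPONENT_NAMES:
            if self.true_components.get(name, 0.0) < 0:
                raise ValueError(f"variance {name} must be >= 0")
        if self.n_sire_families < 0:
            raise ValueError("n_sire_families must be >= 0")
        if not 1 <= self.parities_per_animal <= 5:
            raise ValueError("parities_per_animal must be in 1..5")
        lo, hi = self.testdays_per_lactation
        if lo < 1 or hi < lo:
            raise ValueError(
                f"testdays_per_lactation range {self.testdays_per_lactation} "
                "must satisfy 1 <= min <= max"
            )
        if self.trait not in TRAIT_COLUMNS:
            raise ValueError(f"trait must be one of {TRAIT_COLUMNS}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        labels = [str(c + 1) for c in range(len(self.snps_per_chromosome))]
        counts = dict(zip(labels, self.snps_per_chromosome))
        for chrom, (start, stop), s2v in self.qtl_windows:
            chrom = str(chrom)
            if chrom not in counts:
                raise ValueError(f"qtl window on unknown chromosome {chrom}")
            if not (0 <= start < stop <= counts[chrom]):
                raise ValueError(
                    f"qtl window [{start}, {stop}) outside chromosome {chrom} "
                    f"({counts[chrom]} SNPs)"
                )
            if s2v < 0:
                raise ValueError("regional variance must be >= 0")

    def component(self, name: str) -> float:
        return float(self.true_components.get(name, 0.0))

    def total_variance(self) -> float:
        """sigma2_p implied by the configuration (all components + QTL windows)."""
        return sum(self.component(k) for k in COMPONENT_NAMES) + sum(
            s2v for _, _, s2v in self.qtl_windows
        )


@dataclass
class TruthRecord:
    """Per-level true effects and their realized variances, for recovery tests."""

    u: np.ndarray | None = None
    regional: dict[str, np.ndarray] = field(default_factory=dict)
    pu: np.ndarray | None = None
    pw: dict[tuple[str, int], float] = field(default_factory=dict)
    h: dict[tuple[str, int], float] = field(default_factory=dict)
    realized_variances: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "u": None if self.u is None else list(self.u),
            "regional": {k: list(v) for k, v in self.regional.items()},
            "pu": None if self.pu is None else list(self.pu),
            "pw": {f"{a}|{p}": v for (a, p), v in self.pw.items()},
            "h": {f"{f}|{d}": v for (f, d), v in self.h.items()},
            "realized_variances": self.realized_variances,
        }
        return json.dumps(payload)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible generator for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw biallelic dosages with per-SNP frequency p uniform in ``maf_range``.

    With ``n_sire_families > 0`` (the default, mirroring a half-sib-structured
    dairy flock), animals inherit one allele from a shared sire and one from
    the population, giving within-family relatedness ~0.25; with 0 families
    dosages are independent binomial(2, p) draws.  With ``ld_rho > 0``,
    dosages are instead thresholded from a latent AR(1) Gaussian along each
    chromosome, giving adjacent-marker correlation ~``ld_rho``.
    """
    rng = _rng(config, 0)
    n = config.n_animals
    n_fam = min(config.n_sire_families, n)  # at most one family per animal
    fam = np.arange(n) % max(n_fam, 1)
    chunks, maps = [], []
    for c, m in enumerate(config.snps_per_chromosome):
        chrom = str(c + 1)
        p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        if config.ld_rho == 0.0:
            if n_fam > 0:
                nf = n_fam
                sire_hap = rng.random((nf, 2, m)) < p  # two haplotypes per sire
                pick = rng.integers(0, 2, size=(n, m))
                paternal = sire_hap[fam[:, None], pick, np.arange(m)[None, :]]
                maternal = rng.random((n, m)) < p
                dos = (paternal + maternal).astype(float)
            else:
                dos = rng.binomial(2, p, size=(n, m)).astype(float)
        else:
            dos = np.empty((n, m))
            z = rng.standard_normal((n, m))
            lat = np.empty_like(z)
            lat[:, 0] = z[:, 0]
            r = config.ld_rho
            for j in range(1, m):
                lat[:, j] = r * lat[:, j - 1] + math.sqrt(1 - r * r) * z[:, j]
            # per-allele thresholding: two latent copies approximated by one
            from scipy.stats import norm

            for j in range(m):
                q0 = norm.ppf((1 - p[j]) ** 2)
                q1 = norm.ppf(1 - p[j] ** 2)
                dos[:, j] = np.where(lat[:, j] < q0, 0.0, np.where(lat[:, j] < q1, 1.0, 2.0))
        chunks.append(dos)
        bp = np.cumsum(rng.integers(2_000, 120_000, size=m))
        maps.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "snp_id": [f"snp_{chrom}_{j}" for j in range(m)],
                    "bp": bp,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
    return GenotypeDataset(
        dosages=np.concatenate(chunks, axis=1),
        sample_ids=[f"ani{i:05d}" for i in range(n)],
        marker_map=pd.concat(maps, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# genetic effects
# ---------------------------------------------------------------------------

def _scaled_breeding_values(
    cols: np.ndarray, target_var: float, rng: np.random.Generator, label: str
) -> np.ndarray:
    """Sum of random per-SNP effects, rescaled in the GRM metric.

    Effects are drawn per SNP with variance proportional to 1/(2pq) (the
    method-2 weighting), so the raw breeding values are distributed with
    covariance proportional to the region's own GRM ``G``.  They are then
    rescaled so the realized variance *in the model's metric*,
    ``u' G^+ u / rank(G)``, equals ``target_var`` exactly.  This makes the
    generative variance the same quantity the REML model estimates, also in
    structured populations where the GRM diagonal is far from 1.
    """
    n = cols.shape[0]
    if target_var == 0.0:
        return np.zeros(n)
    p = np.nanmean(cols, axis=0) / 2.0
    with np.errstate(invalid="ignore"):
        poly = (p > 0.0) & (p < 1.0) & (np.nanstd(cols, axis=0) > 0.0)
    if not np.any(poly):
        raise ValueError(f"all SNPs fixed in {label}; cannot place genetic variance")
    centered = cols[:, poly] - 2.0 * p[poly]
    centered = np.where(np.isnan(centered), 0.0, centered)
    m = int(poly.sum())
    d = 1.0 / (2.0 * p[poly] * (1.0 - p[poly]))
    raw = centered @ (np.sqrt(d) * rng.standard_normal(m)) / math.sqrt(m)
    g = (centered * (d / m)) @ centered.T  # the region's method-2 GRM
    w, v = np.linalg.eigh(g)
    keep = w > 1e-8 * w.max()
    proj = v[:, keep].T @ raw
    metric_var = float(proj @ (proj / w[keep])) / int(keep.sum())
    if metric_var == 0.0:
        raise ValueError(f"degenerate breeding values in {label}")
    return raw * math.sqrt(target_var / metric_var)


def simulate_qtl_effects(dataset: GenotypeDataset, config: SimulationConfig) -> TruthRecord:
    """Polygenic and per-QTL-window breeding values with exact realized variance."""
    rng = _rng(config, 1)
    truth = TruthRecord()
    truth.u = _scaled_breeding_values(
        dataset.dosages, config.component("u"), rng, "whole genome"
    )
    truth.realized_variances["u"] = config.component("u")  # exact, in the G metric
    truth.realized_variances["u_sample"] = float(np.var(truth.u, ddof=1))
    for chrom, (start, stop), s2v in config.qtl_windows:
        chrom = str(chrom)
        idx = dataset.snp_indices(chrom)[start:stop]
        label = f"qtl window {chrom}:[{start},{stop})"
        v = _scaled_breeding_values(dataset.dosages[:, idx], s2v, rng, label)
        key = f"{chrom}:{start}-{stop}"
        truth.regional[key] = v
        truth.realized_variances[f"v[{key}]"] = s2v
        truth.realized_variances[f"v_sample[{key}]"] = float(np.var(v, ddof=1))
    return truth


# ---------------------------------------------------------------------------
# test-day records
# ---------------------------------------------------------------------------

def simulate_testday_records(
    dataset: GenotypeDataset, truth: TruthRecord, config: SimulationConfig
) -> TestDayTable:
    """Generate the repeated-records table and complete ``truth`` in place.

    Flocks share a ~monthly recording schedule, so flock-by-test-day cells are
    common to all flock members recorded that day (the FTD random effect).
    Lambing dates are staggered over a multi-year horizon; days in milk is the
    test date minus the lambing date and fortnight-in-milk is
    ``min(ceil(DIM / 14), 22)``.
    """
    if truth.u is None or len(truth.u) != dataset.n_animals:
        raise ValueError("truth does not contain breeding values for every animal")
    lo_td, hi_td = config.testdays_per_lactation
    if hi_td < 1:
        raise ValueError("zero test-days per lactation configured")

    rng = _rng(config, 2)
    comps = {k: config.component(k) for k in COMPONENT_NAMES}
    coefs = {k: np.asarray(v, dtype=float) for k, v in config.fixed_effect_coefficients.items()}
    n = dataset.n_animals
    horizon = 2160  # six years of recording
    flock_dates = {
        str(f): np.arange(7 * f, horizon, 30) for f in range(config.n_flocks)
    }
    flock_of = [str(i * config.n_flocks // n) for i in range(n)]

    sd = {k: math.sqrt(comps[k]) for k in COMPONENT_NAMES}
    truth.pu = rng.normal(0.0, sd["pu"], size=n)
    truth.realized_variances["pu"] = float(np.var(truth.pu, ddof=1))
    truth.pw.clear()
    truth.h.clear()

    total_regional = (
        np.sum(list(truth.regional.values()), axis=0)
        if truth.regional
        else np.zeros(n)
    )

    rows: list[tuple] = []
    resid: list[float] = []
    for i, animal in enumerate(dataset.sample_ids):
        flock = flock_of[i]
        dates = flock_dates[flock]
        first_lambing = int(rng.integers(0, 700))
        for parity in range(1, config.parities_per_animal + 1):
            lambing = first_lambing + (parity - 1) * 370 + int(rng.integers(-15, 16))
            in_milk = dates[(dates >= lambing + 5) & (dates <= lambing + 300)]
            n_td = int(rng.integers(lo_td, hi_td + 1))
            td = in_milk[:n_td]
            if td.size == 0:
                continue
            pw = float(rng.normal(0.0, sd["pw"]))
            truth.pw[(animal, parity)] = pw
            litter = 1 + int(rng.integers(0, 2))
            season = 1 if (lambing % 360) < 180 else 2
            for date in td:
                date = int(date)
                cell = (flock, date)
                if cell not in truth.h:
                    truth.h[cell] = float(rng.normal(0.0, sd["h"]))
                dim = date - lambing
                fim = min(math.ceil(dim / 14), 22)
                e = float(rng.normal(0.0, sd["e"]))
                resid.append(e)
                fixed = (
                    float(coefs["intercept"][0])
                    + coefs["parity"][min(parity, 5) - 1]
                    + coefs["litter_size"][litter - 1]
                    + coefs["season"][season - 1]
                    + coefs["fim"][fim - 1]
                )
                value = (
                    fixed
                    + truth.u[i]
                    + total_regional[i]
                    + truth.pu[i]
                    + pw
                    + truth.h[cell]
                    + e
                )
                rows.append((animal, flock, date, lambing, parity, litter, season, dim, value))

    truth.realized_variances["pw"] = float(
        np.var(list(truth.pw.values()), ddof=1) if len(truth.pw) > 1 else 0.0
    )
    truth.realized_variances["h"] = float(
        np.var(list(truth.h.values()), ddof=1) if len(truth.h) > 1 else 0.0
    )
    truth.realized_variances["e"] = float(
        np.var(resid, ddof=1) if len(resid) > 1 else 0.0
    )

    df = pd.DataFrame(
        rows,
        columns=TESTDAY_COLUMNS[:8] + [config.trait],
    )
    # remaining trait columns: independent placeholder noise at phenotypic scale
    sigma_p = math.sqrt(max(config.total_variance(), 1e-12))
    for t in TRAIT_COLUMNS:
        if t != config.trait:
            df[t] = float(coefs["intercept"][0]) + rng.normal(0.0, sigma_p, size=len(df))
    return TestDayTable(df[TESTDAY_COLUMNS])


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, TruthRecord, TestDayTable]:
    """Convenience wrapper: genotypes, genetic truth and test-day records."""
    dataset = simulate_genotypes(config)
    truth = simulate_qtl_effects(dataset, config)
    table = simulate_testday_records(dataset, truth, config)
    return dataset, truth, table


def write_fixture(
    dataset: GenotypeDataset,
    table: TestDayTable,
    directory: str | os.PathLike,
    truth: TruthRecord | None = None,
) -> dict[str, Path]:
    """Write a PLINK triple + test-day TSV (+ optional truth JSON) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = directory / "genotypes"
    write_plink(dataset, prefix)
    table_path = directory / "testday.tsv"
    write_testday_table(table, table_path)
    out = {
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
        "table": table_path,
    }
    if truth is not None:
        truth_path = directory / "truth.json"
        truth_path.write_text(truth.to_json())
        out["truth"] = truth_path
    return out
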