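"""Sliding-window regional heritability scan.

Each chromosome is tiled with windows of ``size`` consecutive post-QC SNPs
shifted by ``shift`` (adjacent windows overlap by half at the defaults
100/50); the SNPs after the last full window form a single non-overlapping
tail window that is kept only if it holds at least ``min_tail`` SNPs.  Every
window is tested by refitting the full test-day model plus a regional genomic
effect whose covariance is the window's own GRM, and comparing restricted
log-likelihoods with the null model (no regional effect) via

    LRT = 2 (logL_full - logL_null),

referred to the boundary mixture 1/2 chi2(0) + 1/2 chi2(1).  Multiple testing
follows the half-count heuristic for half-overlapping windows: a scan of W
windows is treated as W/2 independent tests, giving a genome-wide Bonferroni
threshold (mixture tail alpha / (W/2)) and a suggestive threshold at one
expected false positive per scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datasets import GenotypeDataset, TestDayTable
from .grm import GRM, allele_frequencies, build_grm
from .model import (
    FitResult,
    ModelFrame,
    _fit_on_workspace,
    _Workspace,
    build_model_frame,
    fit_reml,
    lrt,
    mixture_pvalue,
)

__all__ = [
    "Window",
    "WindowResult",
    "ScanThresholds",
    "ScanConfig",
    "make_windows",
    "scan_thresholds",
    "run_scan",
    "classify_results",
    "RegionalScan",
    "ScanResults",
]


@dataclass(frozen=True)
class Window:
    """A run of consecutive SNPs on one chromosome.

    ``start``/``stop`` are 0-based half-open indices into the post-QC marker
    map (global column indices); ``ordinal`` is 1-based per chromosome.
    """

    chrom: str
    ordinal: int
    start: int
    stop: int
    start_snp: str
    start_bp: int
    end_snp: str
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.stop - self.start

    @property
    def mid_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    def overlap(self, other: "Window") -> int:
        """Number of shared SNPs with another window."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.stop, other.stop) - max(self.start, other.start))


def make_windows(
    marker_map: pd.DataFrame,
    size: int = 100,
    shift: int = 50,
    min_tail: int = 25,
) -> list[Window]:
    """Tile each chromosome with sliding windows plus an optional tail.

    Full windows start at 0, shift, 2*shift, ... while ``start + size`` fits
    on the chromosome; remaining SNPs after the last full window form one tail
    window kept iff it has at least ``min_tail`` SNPs.  Windows never span
    chromosomes; a chromosome with fewer than ``min_tail`` SNPs yields none.
    """
    if shift > size:
        raise ValueError("shift must not exceed the window size")
    windows: list[Window] = []
    offset = 0
    for chrom in marker_map["chrom"].drop_duplicates():
        grp = marker_map[marker_map["chrom"] == chrom]
        m = len(grp)
        spans: list[tuple[int, int]] = []
        start = 0
        while start + size <= m:
            spans.append((start, start + size))
            start += shift
        tail_start = spans[-1][1] if spans else 0
        if m - tail_start >= min_tail:
            spans.append((tail_start, m))
        for k, (a, b) in enumerate(spans, start=1):
            rows = grp.iloc[[a, b - 1]]
            windows.append(
                Window(
                    chrom=str(chrom),
                    ordinal=k,
                    start=offset + a,
                    stop=offset + b,
                    start_snp=str(rows["snp_id"].iloc[0]),
                    start_bp=int(rows["bp"].iloc[0]),
                    end_snp=str(rows["snp_id"].iloc[1]),
                    end_bp=int(rows["bp"].iloc[1]),
                )
            )
        offset += m
    return windows


@dataclass(frozen=True)
class ScanThresholds:
    """Significance thresholds for one scan of ``n_windows`` windows."""

    n_windows: int
    effective_tests: float
    genomewide_lrt: float
    suggestive_lrt: float
    genomewide_pertest_p: float
    suggestive_pertest_p: float
    alpha: float


def scan_thresholds(
    n_windows: int, alpha: float = 0.05, consistent_mixture: bool = False
) -> ScanThresholds:
    """LRT thresholds for genome-wide and suggestive significance.

    With half-overlapping windows the scan counts half the windows as
    independent tests, ``T = ceil(n_windows / 2)`` (a whole number of tests).
    The genome-wide threshold solves the mixture tail
    ``0.5 Pr(chi2_1 >= x) = alpha / T``.  The suggestive threshold (one
    expected false positive per scan) conventionally solves the plain chi2(1)
    tail ``Pr(chi2_1 >= x) = 1 / T``; ``consistent_mixture=True`` instead puts
    the mixture tail at ``1 / T``.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t_eff = float(math.ceil(n_windows / 2.0))
    gw_p = alpha / t_eff
    gw = float(chi2.isf(min(2.0 * gw_p, 1.0), df=1))
    sug_p = 1.0 / t_eff
    if consistent_mixture:
        sug = float(chi2.isf(min(2.0 * sug_p, 1.0), df=1))
    else:
        sug = float(chi2.isf(min(sug_p, 1.0), df=1))
    return ScanThresholds(
        n_windows=n_windows,
        effective_tests=t_eff,
        genomewide_lrt=gw,
        suggestive_lrt=sug,
        genomewide_pertest_p=gw_p,
        suggestive_pertest_p=sug_p,
        alpha=alpha,
    )


@dataclass
class WindowResult:
    """Full-vs-null contrast for one window of one trait."""

    window: Window
    trait: str
    loglik_full: float
    loglik_null: float
    lrt: float
    p_mixture: float
    h2_v: float
    significance: str = "none"  # "genome-wide" | "suggestive" | "none"
    converged: bool = True
    clamped: bool = False
    sigma2_v: float = 0.0
    sigma_p: float = float("nan")

    def to_row(self) -> dict:
        w = self.window
        return {
            "trait": self.trait,
            "chrom": w.chrom,
            "window": w.ordinal,
            "start_snp": w.start_snp,
            "start_bp": w.start_bp,
            "end_snp": w.end_snp,
            "end_bp": w.end_bp,
            "n_snps": w.n_snps,
            "lrt": self.lrt,
            "p_mixture": self.p_mixture,
            "h2_v": self.h2_v,
            "significance": self.significance,
            "converged": self.converged,
        }


@dataclass
class ScanConfig:
    """Scan options: windowing, thresholds, and REML controls."""

    window_size: int = 100
    shift: int = 50
    min_tail: int = 25
    alpha: float = 0.05
    consistent_mixture_thresholds: bool = False
    exclude_region_from_background: bool = False
    warm_start_fraction: float = 0.01  # sv2 initial value as a share of sigma_p
    max_iter: int = 200
    tol: float = 1e-6
    grm_tol: float = 1e-8


def classify_results(
    results: list[WindowResult], thresholds: ScanThresholds
) -> list[WindowResult]:
    """Annotate each result with its significance class (strict inequalities)."""
    out = []
    for r in results:
        if r.lrt > thresholds.genomewide_lrt:
            cls = "genome-wide"
        elif r.lrt > thresholds.suggestive_lrt:
            cls = "suggestive"
        else:
            cls = "none"
        out.append(replace(r, significance=cls))
    return out


def run_scan(
    dataset: GenotypeDataset,
    table: TestDayTable,
    trait: str,
    windows: list[Window] | None = None,
    config: ScanConfig | None = None,
    null_fit: FitResult | None = None,
) -> "ScanResults":
    """Fit the regional model for every window and classify the results.

    The null model (no regional effect) is fitted once and reused: every
    window's full fit is warm-started from the null estimates with the
    regional variance initialized at ``warm_start_fraction x sigma_p``.
    Windows are statistically independent computations, so results do not
    depend on evaluation order; non-converged window fits are flagged and
    retained, never dropped.
    """
    config = config or ScanConfig()
    if windows is None:
        windows = make_windows(
            dataset.marker_map, config.window_size, config.shift, config.min_tail
        )
    if not windows:
        raise ValueError("no windows to scan")

    freqs = allele_frequencies(dataset)
    all_idx = np.arange(dataset.n_snps)
    grm_all = build_grm(dataset, all_idx, freqs, tol=config.grm_tol)

    frame = build_model_frame(table, trait, {"u": grm_all})
    animals = list(dict.fromkeys(frame.animal_ids))
    if null_fit is None:
        null_fit = fit_reml(frame, max_iter=config.max_iter, tol=config.tol)
    ws_null = _Workspace.from_frame(frame, frame.term_names())

    warm = dict(null_fit.components.as_dict())
    sigma_p = null_fit.sigma_p
    warm["v"] = config.warm_start_fraction * sigma_p

    u_term = frame.term("u")
    results: list[WindowResult] = []
    for w in windows:
        idx = w.indices()
        if config.exclude_region_from_background:
            bg_idx = np.setdiff1d(all_idx, idx)
            grm_bg = build_grm(dataset, bg_idx, freqs[bg_idx], tol=config.grm_tol)
            frame_w = build_model_frame(table, trait, {"u": grm_bg})
            null_w = fit_reml(frame_w, max_iter=config.max_iter, tol=config.tol)
            frame_full = frame_w.with_regional(
                build_grm(dataset, idx, freqs[idx], tol=config.grm_tol)
            )
            full = fit_reml(
                frame_full,
                init={**null_w.components.as_dict(), "v": warm["v"]},
                max_iter=config.max_iter,
                tol=config.tol,
            )
            base = null_w
        else:
            grm_v = build_grm(dataset, idx, freqs[idx], tol=config.grm_tol).align(animals)
            zv = grm_v.factor()[u_term.level_index, :]
            ws = ws_null.extend("v", zv)
            vary = float(np.var(frame.y, ddof=1))
            full = _fit_on_workspace(
                ws, frame, dict(warm), config.max_iter, config.tol, 1e-8 * vary
            )
            base = null_fit
        stat, clamped = lrt(full, base, return_clamped=True)
        results.append(
            WindowResult(
                window=w,
                trait=trait,
                loglik_full=full.loglik,
                loglik_null=base.loglik,
                lrt=stat,
                p_mixture=mixture_pvalue(stat),
                h2_v=(full.components.v or 0.0) / full.sigma_p,
                converged=full.converged and base.converged,
                clamped=clamped,
                sigma2_v=full.components.v or 0.0,
                sigma_p=full.sigma_p,
            )
        )

    thresholds = scan_thresholds(
        len(windows), config.alpha, config.consistent_mixture_thresholds
    )
    results = classify_results(results, thresholds)
    return ScanResults(results=results, thresholds=thresholds, null_fit=null_fit)


@dataclass
class ScanResults:
    """All window results of one scan plus the thresholds used."""

    results: list[WindowResult]
    thresholds: ScanThresholds
    null_fit: FitResult | None = None

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def to_tsv(self, path) -> None:
        from .io import write_scan_results

        write_scan_results(self.results, path)

    def significant(self) -> list[WindowResult]:
        return [r for r in self.results if r.significance != "none"]

    def max_lrt(self) -> WindowResult:
        return max(self.results, key=lambda r: r.lrt)

    def plot_data(self) -> pd.DataFrame:
        """Window midpoint (bp) vs LRT, for Manhattan-style plots."""
        return pd.DataFrame(
            {
                "trait": [r.trait for r in self.results],
                "chrom": [r.window.chrom for r in self.results],
                "mid_bp": [r.window.mid_bp for r in self.results],
                "lrt": [r.lrt for r in self.results],
            }
        )

    def plot(self, ax=None):
        """Manhattan-style LRT plot with both significance thresholds."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        df = self.plot_data()
        offset = 0.0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
            x = grp["mid_bp"].to_numpy() + offset
            ax.scatter(x, grp["lrt"], s=12, color=f"C{i % 2}")
            ticks.append(x.mean())
            labels.append(chrom)
            offset = x.max() + 1e6
        ax.axhline(self.thresholds.genomewide_lrt, color="k", ls="-", lw=1)
        ax.axhline(self.thresholds.suggestive_lrt, color="k", ls="--", lw=1)
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("LRT")
        return ax


class RegionalScan:
    """Object front end: build once, scan one or more traits.

    Examples
    --------
    >>> scan = RegionalScan(dataset, table)             # doctest: +SKIP
    >>> res = scan.run("fpc")                           # doctest: +SKIP
    >>> res.to_tsv("scan_fpc.tsv")                      # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        table: TestDayTable,
        config: ScanConfig | None = None,
    ):
        self.dataset = dataset
        self.table = table
        self.config = config or ScanConfig()
        self.windows = make_windows(
            dataset.marker_map, self.config.window_size, self.config.shift, self.config.min_tail
        )

    def run(self, trait: str) -> ScanResults:
        return run_scan(self.dataset, self.table, trait, self.windows, self.config)
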