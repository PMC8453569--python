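"""Genomic relationship matrices (whole-genome and regional).

The estimator is the per-SNP-standardized ("method 2") form

    G = (1/m) * sum_i  z_i z_i' / (2 p_i (1 - p_i)),      z_i = x_i - 2 p_i,

where ``x_i`` is the dosage column of SNP ``i`` and ``p_i`` its allele-B
frequency.  Each SNP is weighted by the reciprocal of its expected binomial
variance, so rare and common markers contribute equally.  Missing dosages are
replaced by ``2 p_i`` (a zero contribution to ``z_i``), which keeps G positive
semi-definite.  Regional GRMs are built the same way from a SNP subset, using
frequencies computed once from the full post-QC data.

When frequencies are estimated from the same data with no missingness, each
``z_i`` sums to zero, so the vector of ones lies in the null space of G; GRMs
are therefore routinely singular and downstream code works with the spectral
factorization and Moore-Penrose pseudo-inverse rather than a plain inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datasets import GenotypeDataset


def allele_frequencies(
    dataset: GenotypeDataset, snp_subset: np.ndarray | None = None
) -> np.ndarray:
    """Allele-B frequencies ``p_i = mean(dosage)/2`` over non-missing entries."""
    cols = dataset.dosages if snp_subset is None else dataset.dosages[:, snp_subset]
    n_obs = (~np.isnan(cols)).sum(axis=0)
    if np.any(n_obs == 0):
        idx = np.flatnonzero(n_obs == 0)[0]
        snp_ids = dataset.marker_map["snp_id"]
        which = snp_ids.iloc[snp_subset[idx] if snp_subset is not None else idx]
        raise ValueError(f"SNP {which!r} has no observed genotypes")
    with np.errstate(invalid="ignore"):
        return np.nanmean(cols, axis=0) / 2.0


@dataclass
class GRM:
    """A symmetric genomic relationship matrix with lazy spectral factorization."""

    matrix: np.ndarray
    sample_ids: list[str]
    n_snps: int
    tol: float = 1e-8
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n != len(self.sample_ids):
            raise ValueError("GRM must be square with one row per sample id")
        with np.errstate(invalid="ignore"):  # inf - inf caught later as non-finite
            asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if np.isfinite(asym) and asym > 1e-10 * max(1.0, np.nanmax(np.abs(self.matrix))):
            raise ValueError(f"GRM is not symmetric (max asymmetry {asym:g})")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors, with small/negative
        eigenvalues (< tol * max eigenvalue) zeroed."""
        if self._eig is None:
            if not np.all(np.isfinite(self.matrix)):
                raise ValueError("GRM contains non-finite entries")
            w, v = scipy.linalg.eigh(self.matrix)
            w = np.where(w > self.tol * max(w.max(), 0.0), w, 0.0)
            self._eig = (w, v)
        return self._eig

    @property
    def rank(self) -> int:
        w, _ = self.eigendecomposition()
        return int(np.count_nonzero(w))

    def factor(self) -> np.ndarray:
        """An ``n x rank`` matrix L with ``L L' = G`` (spectral square root)."""
        w, v = self.eigendecomposition()
        nz = w > 0
        return v[:, nz] * np.sqrt(w[nz])

    def pinv(self) -> np.ndarray:
        """Moore-Penrose pseudo-inverse from the truncated eigendecomposition."""
        w, v = self.eigendecomposition()
        winv = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        return (v * winv) @ v.T

    def log_pseudo_determinant(self) -> float:
        """Sum of log nonzero eigenvalues."""
        w, _ = self.eigendecomposition()
        return float(np.log(w[w > 0]).sum())

    def align(self, sample_ids: list[str]) -> "GRM":
        """Reorder/subset rows and columns to the given sample ids."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples absent from GRM: {missing[:10]}")
        idx = np.array([pos[s] for s in sample_ids])
        return GRM(self.matrix[np.ix_(idx, idx)], list(sample_ids), self.n_snps, self.tol)


def build_grm(
    dataset: GenotypeDataset,
    snp_subset: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    tol: float = 1e-8,
) -> GRM:
    """Build a (whole-genome or regional) GRM from a dosage matrix.

    Parameters
    ----------
    snp_subset
        0-based SNP column indices; all SNPs when None.
    freqs
        Allele-B frequencies for the subset SNPs.  When None they are
        estimated from ``dataset`` itself.  Every subset SNP must be
        polymorphic (0 < p < 1): monomorphic markers carry no relationship
        information and should have been removed by QC.
    """
    if snp_subset is None:
        snp_subset = np.arange(dataset.n_snps)
    snp_subset = np.asarray(snp_subset)
    if freqs is None:
        freqs = allele_frequencies(dataset, snp_subset)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (snp_subset.size,):
        raise ValueError("freqs length must match the SNP subset")
    mono = (freqs <= 0.0) | (freqs >= 1.0)
    if mono.any():
        which = dataset.marker_map["snp_id"].iloc[snp_subset[np.flatnonzero(mono)[0]]]
        raise ValueError(f"monomorphic SNP {which!r} in GRM subset (run QC first)")

    x = dataset.dosages[:, snp_subset]
    z = x - 2.0 * freqs
    z = np.where(np.isnan(z), 0.0, z)  # mean-impute missing dosages
    w = 1.0 / (2.0 * freqs * (1.0 - freqs))
    m = snp_subset.size
    g = (z * (w / m)) @ z.T
    g = 0.5 * (g + g.T)
    return GRM(matrix=g, sample_ids=list(dataset.sample_ids), n_snps=m, tol=tol)


def spectral_factorization(grm: GRM, tol: float = 1e-8):
    """Eigendecomposition with truncation: returns (eigenvalues, eigenvectors,
    rank).  Reconstruction ``V diag(w) V'`` matches G to ~tol * max|G|."""
    if tol != grm.tol:
        grm = GRM(grm.matrix, grm.sample_ids, grm.n_snps, tol)
    w, v = grm.eigendecomposition()
    return w, v, int(np.count_nonzero(w))
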