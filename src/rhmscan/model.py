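"""REML engine for the repeatability test-day animal model.

Model
-----
For one trait, with records stacked in ``y``:

    y = X b + Z1 u + Z1 pu + Z2 pw + Z3 h [+ Z1 v] + e

* ``X``: parity (5 levels, higher parities collapsed to 5), litter size (2),
  lambing season (2) and fortnight-in-milk (22 levels, ``min(ceil(DIM/14), 22)``),
  dummy-coded with an intercept; linearly dependent columns are dropped and
  recorded.
* ``u ~ N(0, G su2)``: additive genomic, whole-genome GRM ``G``.
* ``pu ~ N(0, I spu2)``: permanent environment across lactations (per animal).
* ``pw ~ N(0, I spw2)``: permanent environment within parity (animal x parity).
* ``h ~ N(0, I sh2)``: flock x test-day interaction.
* ``v ~ N(0, Gv sv2)``: optional regional genomic effect with a regional GRM.
* ``e ~ N(0, I se2)``: residual.

Computation
-----------
GRM-structured effects are reparametrized through the spectral square root
``G = L L'`` (``L`` is ``n_animals x rank``), so every random effect has an
identity covariance and possibly singular GRMs need no inversion.  The
restricted likelihood, its gradient, the average-information (AI) matrix and
EM updates are all evaluated from one Cholesky factorization of the
mixed-model-equations coefficient matrix

    C = [[X'X, X'Z], [Z'X, Z'Z + diag(se2 / sk2)]]

per iteration, using the standard identities

    log|V| + log|X' V^-1 X| = (n - p) log se2 - sum_k q_k log(lambda_k) + log|C|
    y'Py = (y'y - theta_hat' W'y) / se2.

The optimizer is AI-REML with EM fallback steps whenever an AI step would
leave the non-negative orthant or decrease the likelihood; variances that are
repeatedly driven negative are pinned to a small boundary value
(1e-8 x var(y)) and stay in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from .datasets import TestDayTable
from .grm import GRM

__all__ = [
    "ModelFrame",
    "RandomTerm",
    "VarianceComponents",
    "FitResult",
    "build_model_frame",
    "restricted_loglik",
    "fit_reml",
    "derived_ratios",
    "lrt",
    "mixture_pvalue",
    "TestDayREML",
    "REMLResults",
]

LOG2PI = math.log(2.0 * math.pi)

#: canonical component order for covariance matrices and reports
COMPONENT_ORDER = ("u", "v", "pu", "pw", "h", "e")

RATIO_DEFS = {
    # ratio -> component names summed in the numerator (denominator: sigma_p)
    "h2": ("u",),
    "h2_v": ("v",),
    "r_acr": ("u", "pu"),
    "r_wit": ("u", "pu", "pw"),
    "ftd2": ("h",),
}


# ---------------------------------------------------------------------------
# model frame
# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random effect: a record -> level map plus its covariance structure."""

    name: str
    level_index: np.ndarray  # (n_records,) int
    n_levels: int
    grm: GRM | None = None  # identity structure when None

    def design(self) -> np.ndarray:
        """Dense reparametrized design: one-hot Z (identity) or Z1 L (GRM)."""
        if self.grm is None:
            z = np.zeros((self.level_index.size, self.n_levels))
            z[np.arange(self.level_index.size), self.level_index] = 1.0
            return z
        return self.grm.factor()[self.level_index, :]

    def incidence(self) -> np.ndarray:
        """Plain one-hot incidence matrix Z (n_records x n_levels)."""
        z = np.zeros((self.level_index.size, self.n_levels))
        z[np.arange(self.level_index.size), self.level_index] = 1.0
        return z


@dataclass
class ModelFrame:
    """Response, fixed-effect design and random terms for one trait."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    dropped_columns: list[str]
    terms: list[RandomTerm]
    trait: str
    animal_ids: list[str]  # per record
    n_dropped_records: int = 0

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def with_regional(self, grm: GRM) -> "ModelFrame":
        """A copy of this frame with a regional genomic term ``v`` added."""
        animal_term = self.term("u")
        animals = list(dict.fromkeys(self.animal_ids))
        aligned = grm.align(animals)
        v = RandomTerm("v", animal_term.level_index, animal_term.n_levels, aligned)
        terms = [self.terms[0], v] + self.terms[1:]
        return replace(self, terms=terms)


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy left-to-right selection of a full-rank column subset."""
    n = X.shape[0]
    kept: list[int] = []
    q = np.zeros((n, 0))
    for j in range(X.shape[1]):
        col = X[:, j].astype(float)
        norm0 = np.linalg.norm(col)
        resid = col - q @ (q.T @ col)
        # re-orthogonalize once for stability
        resid = resid - q @ (q.T @ resid)
        if np.linalg.norm(resid) > tol * max(norm0, 1.0):
            kept.append(j)
            q = np.hstack([q, (resid / np.linalg.norm(resid))[:, None]])
    return kept


def fortnight_in_milk(dim: np.ndarray | int) -> np.ndarray | int:
    """Fortnight class: ``min(ceil(DIM / 14), 22)`` with a floor of 1."""
    fim = np.ceil(np.asarray(dim) / 14.0).astype(int)
    return np.minimum(np.maximum(fim, 1), 22)


def build_model_frame(
    table: TestDayTable,
    trait: str,
    grms: dict[str, GRM],
) -> ModelFrame:
    """Assemble the design for one trait.

    ``grms`` must contain the whole-genome GRM under key ``"u"`` and may carry
    a regional GRM under ``"v"``.  GRMs are aligned to the animals appearing
    in the table; animals missing from a GRM raise an error listing them.
    """
    if trait not in table.data.columns:
        raise ValueError(f"unknown trait {trait!r}")
    if "u" not in grms:
        raise ValueError('grms must provide the whole-genome GRM under key "u"')
    df = table.data
    ok = df[trait].notna()
    n_dropped = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no records with observed {trait}")

    animals = list(dict.fromkeys(df["animal_id"]))
    missing = set(df["animal_id"]) - set(grms["u"].sample_ids)
    if missing:
        raise ValueError(f"animals in table absent from GRM: {sorted(missing)[:10]}")
    g_u = grms["u"].align(animals)

    y = df[trait].to_numpy(dtype=float)

    # fixed effects: intercept + dummy coding, first level as reference
    parity = np.minimum(df["parity"].to_numpy(), 5)
    fim = fortnight_in_milk(df["dim"].to_numpy())
    factors = {
        "parity": parity,
        "litter_size": df["litter_size"].to_numpy(),
        "season": df["season"].to_numpy(),
        "fim": fim,
    }
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for fname, values in factors.items():
        levels = np.unique(values)
        for lev in levels[1:]:
            cols.append((values == lev).astype(float))
            names.append(f"{fname}[{lev}]")
    X_full = np.column_stack(cols)
    kept = _independent_columns(X_full)
    dropped = [names[j] for j in range(len(names)) if j not in set(kept)]
    X = X_full[:, kept]
    x_names = [names[j] for j in kept]

    animal_pos = {a: i for i, a in enumerate(animals)}
    animal_idx = df["animal_id"].map(animal_pos).to_numpy()

    pw_levels = list(dict.fromkeys(zip(df["animal_id"], df["parity"])))
    pw_pos = {lv: i for i, lv in enumerate(pw_levels)}
    pw_idx = np.array([pw_pos[k] for k in zip(df["animal_id"], df["parity"])])

    ftd_levels = list(dict.fromkeys(zip(df["flock"], df["test_date"])))
    ftd_pos = {lv: i for i, lv in enumerate(ftd_levels)}
    ftd_idx = np.array([ftd_pos[k] for k in zip(df["flock"], df["test_date"])])

    terms = [RandomTerm("u", animal_idx, len(animals), g_u)]
    if "v" in grms:
        terms.append(RandomTerm("v", animal_idx, len(animals), grms["v"].align(animals)))
    terms += [
        RandomTerm("pu", animal_idx, len(animals), None),
        RandomTerm("pw", pw_idx, len(pw_levels), None),
        RandomTerm("h", ftd_idx, len(ftd_levels), None),
    ]
    return ModelFrame(
        y=y,
        X=X,
        x_names=x_names,
        dropped_columns=dropped,
        terms=terms,
        trait=trait,
        animal_ids=list(df["animal_id"]),
        n_dropped_records=n_dropped,
    )


# ---------------------------------------------------------------------------
# likelihood workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed cross-products for MME-based REML on a fixed term set."""

    def __init__(self, X: np.ndarray, designs: list[tuple[str, np.ndarray]], y: np.ndarray):
        self.p = X.shape[1]
        self.names = [name for name, _ in designs]
        self.q = [z.shape[1] for _, z in designs]
        self.W = np.hstack([X] + [z for _, z in designs]) if designs else X.copy()
        self.n = X.shape[0]
        self.WtW = self.W.T @ self.W
        self.Wty = self.W.T @ y
        self.yty = float(y @ y)
        self.y = y
        self.slices: dict[str, slice] = {}
        off = self.p
        for name, qk in zip(self.names, self.q):
            self.slices[name] = slice(off, off + qk)
            off += qk
        self.dim = off

    @classmethod
    def from_frame(cls, frame: ModelFrame, active: list[str]) -> "_Workspace":
        designs = [(t.name, t.design()) for t in frame.terms if t.name in active]
        return cls(frame.X, designs, frame.y)

    def extend(self, name: str, z: np.ndarray) -> "_Workspace":
        """New workspace with one extra random term, reusing cached blocks."""
        ws = object.__new__(_Workspace)
        ws.p = self.p
        ws.names = self.names + [name]
        ws.q = self.q + [z.shape[1]]
        ws.n = self.n
        ws.y = self.y
        ws.W = np.hstack([self.W, z])
        cross = self.W.T @ z
        ws.WtW = np.block([[self.WtW, cross], [cross.T, z.T @ z]])
        ws.Wty = np.concatenate([self.Wty, z.T @ self.y])
        ws.yty = self.yty
        ws.slices = dict(self.slices)
        ws.slices[name] = slice(self.dim, self.dim + z.shape[1])
        ws.dim = self.dim + z.shape[1]
        return ws


@dataclass
class _State:
    loglik: float
    sigma2: dict[str, float]
    chol: tuple
    theta_hat: np.ndarray
    e_quad: float  # y'Py * se2 = y'y - theta' W'y


def _evaluate(ws: _Workspace, sigma2: dict[str, float], n_rank_p: int) -> _State:
    """Restricted log-likelihood and MME solution at one point."""
    se2 = sigma2["e"]
    if se2 <= 0:
        raise ValueError("residual variance must be positive")
    C = ws.WtW.copy()
    logdet_lambda = 0.0
    for name in ws.names:
        sk2 = sigma2[name]
        if sk2 <= 0:
            raise ValueError(f"variance {name} must be positive in evaluation")
        lam = se2 / sk2
        sl = ws.slices[name]
        C[sl, sl] += np.eye(sl.stop - sl.start) * lam
        logdet_lambda += (sl.stop - sl.start) * math.log(lam)
    cf = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
    theta = scipy.linalg.cho_solve(cf, ws.Wty, check_finite=False)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    e_quad = ws.yty - float(theta @ ws.Wty)
    n_p = n_rank_p
    loglik = -0.5 * (
        n_p * (math.log(se2) + LOG2PI) - logdet_lambda + logdet_C + e_quad / se2
    )
    return _State(loglik, dict(sigma2), cf, theta, e_quad)


def restricted_loglik(frame: ModelFrame, components: dict[str, float]) -> float:
    """REML log-likelihood of the frame at given variance components.

    Components with value 0 are dropped from the covariance (their term
    contributes nothing to V); the residual variance must be positive.  The
    constant convention is the full textbook one,
    ``-1/2 [log|V| + log|X'V^-1 X| + y'Py + (n - p) log 2pi]``,
    so likelihood differences between nested models are exact.
    """
    if components.get("e", 0.0) <= 0.0:
        raise ValueError("residual variance must be > 0")
    for name, val in components.items():
        if val < 0:
            raise ValueError(f"negative variance for {name}")
    active = [t.name for t in frame.terms if components.get(t.name, 0.0) > 0.0]
    ws = _Workspace.from_frame(frame, active)
    return _evaluate(ws, {**components, "e": components["e"]}, frame.n - frame.p).loglik


# ---------------------------------------------------------------------------
# variance components and derived ratios
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """The model's variances, their SEs, and the derived variance ratios."""

    u: float
    pu: float
    pw: float
    h: float
    e: float
    v: float | None = None
    se: dict[str, float] = field(default_factory=dict)
    covariance: pd.DataFrame | None = None  # sampling covariance of estimates

    @classmethod
    def from_total(
        cls, u: float, pu: float, pw: float, h: float, total: float, v: float = 0.0
    ) -> "VarianceComponents":
        """Recover the residual from a printed phenotypic total (table layout)."""
        e = total - (u + pu + pw + h + v)
        if e < 0:
            raise ValueError("components exceed the stated phenotypic variance")
        return cls(u=u, pu=pu, pw=pw, h=h, e=e, v=v if v else None)

    def as_dict(self) -> dict[str, float]:
        d = {"u": self.u, "pu": self.pu, "pw": self.pw, "h": self.h, "e": self.e}
        if self.v is not None:
            d["v"] = self.v
        return d

    @property
    def sigma_p(self) -> float:
        """Phenotypic variance: the sum of all fitted components."""
        return sum(self.as_dict().values())

    def ratios(self) -> dict[str, float]:
        p = self.sigma_p
        if p <= 0:
            raise ValueError("phenotypic variance must be > 0")
        d = self.as_dict()
        out = {}
        for name, parts in RATIO_DEFS.items():
            if "v" in parts and self.v is None:
                continue
            out[name] = sum(d[c] for c in parts) / p
        return out


def derived_ratios(
    components: VarianceComponents,
    covariance: pd.DataFrame | None = None,
) -> dict[str, tuple[float, float]]:
    """Variance ratios with first-order (delta-method) standard errors.

    ``covariance`` is the sampling covariance of the variance estimates
    (typically the inverse AI matrix), indexed by component name; when absent
    the one attached to ``components`` is used, and SEs are NaN if neither
    exists.
    """
    cov = covariance if covariance is not None else components.covariance
    d = components.as_dict()
    p = components.sigma_p
    if p <= 0:
        raise ValueError("phenotypic variance must be > 0")
    ratios = components.ratios()
    out: dict[str, tuple[float, float]] = {}
    for name, value in ratios.items():
        if cov is None:
            out[name] = (value, float("nan"))
            continue
        names = list(cov.index)
        g = np.array(
            [((c in RATIO_DEFS[name]) - value) / p if c in d else 0.0 for c in names]
        )
        var = float(g @ cov.to_numpy() @ g)
        out[name] = (value, math.sqrt(max(var, 0.0)))
    return out


# ---------------------------------------------------------------------------
# AI-REML fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Converged (or flagged) REML fit: estimates, likelihood, diagnostics."""

    components: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    ai_matrix: pd.DataFrame | None
    pinned: list[str]
    n_records: int
    rank_x: int
    trait: str
    dropped_columns: list[str]

    @property
    def sigma_p(self) -> float:
        return self.components.sigma_p


def _gradient_em(ws, state, n, p, floor):
    """Gradient, block traces and EM proposal at the current state."""
    se2 = state.sigma2["e"]
    # diag of C^-1 from the triangular inverse: (C^-1)_jj = sum_k (L^-1)_kj^2.
    # cho_factor leaves garbage in the unreferenced triangle, so mask it.
    linv, info = scipy.linalg.lapack.dtrtri(state.chol[0], lower=1)
    if info != 0:  # pragma: no cover - fallback for degenerate factors
        Cinv_diag = np.diag(
            scipy.linalg.cho_solve(state.chol, np.eye(ws.dim), check_finite=False)
        )
    else:
        linv = np.tril(linv)
        Cinv_diag = np.einsum("ij,ij->j", linv, linv)
    ehat = ws.y - ws.W @ state.theta_hat
    grad = {}
    em = {}
    tr_lam = 0.0
    for name in ws.names:
        sl = ws.slices[name]
        sk2 = state.sigma2[name]
        lam = se2 / sk2
        qk = sl.stop - sl.start
        uk = state.theta_hat[sl]
        tr_kk = float(Cinv_diag[sl].sum())
        tr_lam += lam * tr_kk
        tr_PM = (qk - lam * tr_kk) / sk2
        grad[name] = -0.5 * (tr_PM - float(uk @ uk) / sk2**2)
        em[name] = max((float(uk @ uk) + se2 * tr_kk) / qk, floor)
    q_tot = ws.dim - p
    tr_P = (n - p - q_tot + tr_lam) / se2
    grad["e"] = -0.5 * (tr_P - float(ehat @ ehat) / se2**2)
    em["e"] = max(state.e_quad / (n - p), floor)
    return grad, em, ehat


def _ai_matrix(ws, state, ehat, names_free):
    """Average-information matrix over the free components (incl. residual)."""
    se2 = state.sigma2["e"]
    Py = ehat / se2
    Fcols = []
    for name in names_free:
        if name == "e":
            Fcols.append(Py)
        else:
            sl = ws.slices[name]
            zk = ws.W[:, sl]
            Fcols.append(zk @ (zk.T @ Py))
    F = np.column_stack(Fcols)
    WtF = ws.W.T @ F
    tau = scipy.linalg.cho_solve(state.chol, WtF, check_finite=False)
    PF = (F - ws.W @ tau) / se2
    ai = 0.5 * (F.T @ PF)
    return 0.5 * (ai + ai.T)


def fit_reml(
    frame: ModelFrame,
    init: dict[str, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    verbose: bool = False,
) -> FitResult:
    """Maximize the restricted likelihood over the non-negative orthant.

    Average-information updates with EM fallback; a component that repeatedly
    tries to go below the boundary (1e-8 x var(y)) is pinned there and stays
    in the model.  Non-convergence within ``max_iter`` is flagged on the
    result, not raised.
    """
    names = frame.term_names()
    vary = float(np.var(frame.y, ddof=1))
    if vary <= 0:
        raise ValueError("response has zero variance")
    floor = 1e-8 * vary
    n, p = frame.n, frame.p

    if init is None:
        k = len(names) + 1
        theta = {name: vary / k for name in names + ["e"]}
    else:
        theta = {name: max(float(init.get(name, vary / (len(names) + 1))), floor)
                 for name in names + ["e"]}

    ws = _Workspace.from_frame(frame, names)
    return _fit_on_workspace(ws, frame, theta, max_iter, tol, floor, verbose)


def _fit_on_workspace(ws, frame, theta, max_iter, tol, floor, verbose=False):
    n, p = frame.n, frame.p
    names = ws.names
    state = _evaluate(ws, theta, n - p)
    pinned: set[str] = set()
    below_count = {name: 0 for name in names}
    converged = False
    grad_norm = math.inf
    it = 0
    last_ai = None
    free_names_last: list[str] = []

    for it in range(1, max_iter + 1):
        grad, em, ehat = _gradient_em(ws, state, n, p, floor)

        # KKT pinning: a variance sitting on the boundary whose gradient points
        # further down is optimal there; freeze it so the rest can converge.
        for nm in names:
            if nm not in pinned and state.sigma2[nm] <= floor * (1 + 1e-9) and grad[nm] < 0:
                pinned.add(nm)

        free = [nm for nm in names if nm not in pinned] + ["e"]
        ai = _ai_matrix(ws, state, ehat, free)
        last_ai, free_names_last = ai, free
        gvec = np.array([grad[nm] for nm in free])
        grad_norm = float(np.linalg.norm(gvec))

        new_state = None
        try:
            delta = np.linalg.solve(ai, gvec)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(6):
                # projected AI step: components pushed below the boundary are
                # clamped at the floor rather than blocking the update
                cand = dict(state.sigma2)
                for nm, dv in zip(free, delta):
                    cand[nm] = max(state.sigma2[nm] + step * dv, floor)
                try:
                    trial = _evaluate(ws, cand, n - p)
                except scipy.linalg.LinAlgError:
                    trial = None  # numerically singular at this point
                if trial is not None and trial.loglik >= state.loglik - 1e-10:
                    new_state = trial
                    break
                step *= 0.5

        if new_state is None:  # EM fallback: uphill by construction, feasible
            cand = dict(state.sigma2)
            for nm in free:
                cand[nm] = em[nm]
            em_state = _evaluate(ws, cand, n - p)
            if em_state.loglik < state.loglik - 1e-8:
                # neither AI nor EM can improve: numerically stationary
                converged = True
                break
            new_state = em_state

        for nm in names:
            if nm in pinned:
                continue
            if new_state.sigma2[nm] <= floor * (1 + 1e-12):
                below_count[nm] += 1
                if below_count[nm] >= 3:
                    pinned.add(nm)
                    new_state.sigma2[nm] = floor
            else:
                below_count[nm] = 0

        dl = new_state.loglik - state.loglik
        state = new_state
        if verbose:  # pragma: no cover - debug aid
            print(f"iter {it}: logL={state.loglik:.6f} dlogL={dl:.2e} {state.sigma2}")
        if abs(dl) < tol:
            converged = True
            break

    ai_df = None
    se: dict[str, float] = {}
    cov_df = None
    if last_ai is not None:
        ai_df = pd.DataFrame(last_ai, index=free_names_last, columns=free_names_last)
        try:
            cov = np.linalg.inv(last_ai)
            cov_df = pd.DataFrame(cov, index=free_names_last, columns=free_names_last)
            se = {nm: math.sqrt(max(cov[i, i], 0.0)) for i, nm in enumerate(free_names_last)}
        except np.linalg.LinAlgError:
            pass
    for nm in names + ["e"]:
        se.setdefault(nm, float("nan"))

    sig = state.sigma2
    vc = VarianceComponents(
        u=sig.get("u", 0.0),
        pu=sig.get("pu", 0.0),
        pw=sig.get("pw", 0.0),
        h=sig.get("h", 0.0),
        e=sig["e"],
        v=sig.get("v") if "v" in names else None,
        se=se,
        covariance=cov_df,
    )
    return FitResult(
        components=vc,
        loglik=state.loglik,
        converged=converged,
        n_iter=it,
        grad_norm=grad_norm,
        ai_matrix=ai_df,
        pinned=sorted(pinned),
        n_records=n,
        rank_x=p,
        trait=frame.trait,
        dropped_columns=frame.dropped_columns,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio machinery
# ---------------------------------------------------------------------------

def lrt(full: FitResult, null: FitResult, return_clamped: bool = False):
    """LRT = 2 (logL_full - logL_null), clamped at zero.

    The two fits must be on the same records and trait, differing only in the
    regional term.
    """
    if (full.n_records, full.trait) != (null.n_records, null.trait):
        raise ValueError("LRT requires fits on the same records and trait")
    if full.rank_x != null.rank_x:
        raise ValueError("LRT requires identical fixed-effect structure")
    raw = 2.0 * (full.loglik - null.loglik)
    clamped = raw < 0.0
    stat = max(raw, 0.0)
    return (stat, clamped) if return_clamped else stat


def mixture_pvalue(stat: float) -> float:
    """P-value under the boundary null, a 50:50 mixture of chi2(0) and chi2(1).

    The point mass at zero makes p = 1 for a zero statistic; otherwise
    p = 0.5 * Pr(chi2_1 >= LRT).
    """
    if stat < 0:
        raise ValueError("LRT statistic must be >= 0")
    if stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class TestDayREML:
    """Repeatability test-day animal model for one trait.

    Parameters
    ----------
    table
        QC'd test-day records.
    trait
        Trait column to analyse (``my``, ``fpc``, ``fy``, ``ppc``, ``py``).
    grm
        Whole-genome GRM for the additive genomic effect.
    regional_grm
        Optional regional GRM; adds the regional effect ``v``.

    Examples
    --------
    >>> model = TestDayREML(table, "fpc", grm)          # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest class

    def __init__(
        self,
        table: TestDayTable,
        trait: str,
        grm: GRM,
        regional_grm: GRM | None = None,
    ):
        grms = {"u": grm}
        if regional_grm is not None:
            grms["v"] = regional_grm
        self.frame = build_model_frame(table, trait, grms)
        self.trait = trait

    def loglike(self, components: dict[str, float]) -> float:
        """Restricted log-likelihood at the given variance components."""
        return restricted_loglik(self.frame, components)

    def fit(self, init=None, max_iter: int = 200, tol: float = 1e-6) -> "REMLResults":
        return REMLResults(self, fit_reml(self.frame, init=init, max_iter=max_iter, tol=tol))


class REMLResults:
    """Results wrapper: estimates, SEs, ratios, likelihood, summary table."""

    def __init__(self, model: TestDayREML, fit: FitResult):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> dict[str, float]:
        return self.fit_result.components.as_dict()

    @property
    def bse(self) -> dict[str, float]:
        return self.fit_result.components.se

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def sigma_p(self) -> float:
        return self.fit_result.sigma_p

    def ratios(self) -> dict[str, tuple[float, float]]:
        return derived_ratios(self.fit_result.components)

    def lrt_against(self, null: "REMLResults") -> tuple[float, float]:
        """(LRT, mixture p-value) against a nested null fit."""
        stat = lrt(self.fit_result, null.fit_result)
        return stat, mixture_pvalue(stat)

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            "Repeatability test-day animal model (REML)",
            "=" * 58,
            f"trait: {fr.trait}    records: {fr.n_records}    rank(X): {fr.rank_x}",
            f"logL: {fr.loglik:.4f}    converged: {fr.converged} "
            f"({fr.n_iter} iterations, |grad| = {fr.grad_norm:.2e})",
        ]
        if fr.pinned:
            lines.append(f"components at boundary: {', '.join(fr.pinned)}")
        if fr.dropped_columns:
            lines.append(f"dropped fixed-effect columns: {', '.join(fr.dropped_columns)}")
        lines.append("-" * 58)
        lines.append(f"{'component':<12}{'estimate':>14}{'SE':>14}")
        d = self.params
        for name in COMPONENT_ORDER:
            if name in d:
                se = self.bse.get(name, float("nan"))
                lines.append(f"{name:<12}{d[name]:>14.6g}{se:>14.3g}")
        lines.append(f"{'sigma_p':<12}{self.sigma_p:>14.6g}")
        lines.append("-" * 58)
        lines.append(f"{'ratio':<12}{'estimate':>14}{'SE':>14}")
        for name, (val, se) in self.ratios().items():
            lines.append(f"{name:<12}{val:>14.4f}{se:>14.3g}")
        return "\n".join(lines)
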