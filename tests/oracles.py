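"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's computational shortcuts: the REML
oracle builds the dense record-space covariance V and evaluates the textbook
restricted likelihood; the HWE oracle enumerates every heterozygote
configuration with exact rational-free log-factorial arithmetic.
"""

from __future__ import annotations

import math

import numpy as np


def dense_restricted_loglik(frame, components: dict[str, float]) -> float:
    """-1/2 [log|V| + log|X'V^-1X| + y'Py + (n-p) log 2pi] with dense V."""
    n, p = frame.n, frame.p
    V = components["e"] * np.eye(n)
    for t in frame.terms:
        s2 = components.get(t.name, 0.0)
        if s2 == 0.0:
            continue
        Z = t.incidence()
        C = t.grm.matrix if t.grm is not None else np.eye(t.n_levels)
        V += s2 * Z @ C @ Z.T
    X, y = frame.X, frame.y
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtViX)
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y) + (n - p) * math.log(2 * math.pi))


def residual_only_reml(frame) -> tuple[float, float]:
    """Closed-form REML for the fixed-effects-only model.

    Returns (sigma2_e_hat, loglik at the optimum) with
    sigma2_e_hat = RSS / (n - p).
    """
    X, y = frame.X, frame.y
    n, p = frame.n, frame.p
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    loglik = -0.5 * (
        (n - p) * (1.0 + math.log(s2) + math.log(2 * math.pi)) + logdet_xtx
    )
    return s2, loglik


def hwe_enumeration_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value by full enumeration over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def log_prob(h: int) -> float:
        # Pr(h hets | allele counts) = n! 2^h / (naa! h! nbb!) * na! nb! / (2n)!
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            math.lgamma(n + 1)
            + h * math.log(2.0)
            - math.lgamma(naa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(nbb + 1)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))
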