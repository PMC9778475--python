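"""Survival association and multi-source evidence integration.

Kaplan-Meier product-limit curves per expression stratum, a univariate
Cox proportional-hazards fit (Newton-Raphson on the Breslow partial
likelihood) with a Wald test, Fisher's method for combining p-values
across datasets, and the TF-level evidence table that ranks candidate
master regulators by integrated support for "repressed by treatment
and associated with poor prognosis".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "km_estimate",
    "stratify_expression",
    "cox_wald",
    "fisher_integrate",
    "integrate_evidence",
    "nes_to_onesided_p",
    "wald_to_onesided_p",
]

log = logging.getLogger(__name__)


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator for one group.

    Returns a step table with columns time, n_at_risk, n_events,
    survival; S(0) = 1 and the curve is right-continuous and
    non-increasing.  Censored-only times do not add steps but do shrink
    the risk set.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no records")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = [(0.0, time.size, 0, 1.0)]
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_by_group(records: pd.DataFrame, groups: pd.Series) -> dict:
    """km_estimate per group label; records need time and event columns."""
    groups = pd.Series(groups)
    out = {}
    for g in pd.unique(groups):
        sub = records.loc[groups.to_numpy() == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no records")
        out[g] = km_estimate(sub["time"], sub["event"])
    return out


def stratify_expression(expr, n_groups: int = 4) -> pd.Series:
    """Quantile bins of near-equal size, labelled 0 (low) .. k-1 (high)."""
    expr = pd.Series(expr, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(expr) < n_groups:
        raise ValueError("need at least as many samples as groups")
    if expr.nunique() == 1:
        raise ValueError("expression is constant; cannot stratify")
    ranks = expr.rank(method="first")
    labels = pd.qcut(ranks, n_groups, labels=False)
    return pd.Series(labels, index=expr.index, name="stratum")


def _cox_derivatives(beta: float, time, event, x):
    """Breslow log partial likelihood and its first two derivatives."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, d, xv = time[order], event[order], x[order]
    eta = beta * xv
    # cumulative sums over the risk set {j : t_j >= t_i}
    r0 = np.cumsum(np.exp(eta))
    r1 = np.cumsum(xv * np.exp(eta))
    r2 = np.cumsum(xv**2 * np.exp(eta))
    # ties: all records with equal time share the largest risk set
    last = np.searchsorted(-t, -t, side="right") - 1
    s0, s1, s2 = r0[last], r1[last], r2[last]
    ev = d == 1
    loglik = float((eta[ev] - np.log(s0[ev])).sum())
    score = float((xv[ev] - s1[ev] / s0[ev]).sum())
    info = float((s2[ev] / s0[ev] - (s1[ev] / s0[ev]) ** 2).sum())
    return loglik, score, info


def cox_wald(
    records: pd.DataFrame, max_iter: int = 50, tol: float = 1e-9
) -> dict:
    """Univariate Cox PH fit with a Wald test.

    Newton-Raphson with step-halving on the Breslow partial likelihood;
    returns beta, se, wald_z and the two-sided normal p.  Requires at
    least 2 events and a non-constant covariate.
    """
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=int)
    x = np.asarray(records["expr"], dtype=float)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if int(event.sum()) < 2:
        raise ValueError("fewer than 2 events: cannot fit Cox model")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: cannot fit Cox model")

    beta = 0.0
    loglik, score, info = _cox_derivatives(beta, time, event, x)
    for _ in range(max_iter):
        if info <= 0:
            raise ValueError("singular information matrix in Cox fit")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(new_beta, time, event, x)
        halvings = 0
        while new_ll < loglik and halvings < 30:  # keep the likelihood non-decreasing
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(new_beta, time, event, x)
            halvings += 1
        converged = abs(new_beta - beta) < tol
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if converged:
            break
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    return {
        "beta": float(beta),
        "se": se,
        "wald_z": float(z),
        "pval": float(2.0 * stats.norm.sf(abs(z))),
        "loglik": loglik,
        "score_residual": score,
    }


def fisher_integrate(pvals) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 sum(ln p), df = 2k, upper-tail chi2 p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return x2, df, float(stats.chi2.sf(x2, df))


def nes_to_onesided_p(nes) -> np.ndarray:
    """One-sided p for the repression direction: small when NES << 0."""
    return stats.norm.cdf(np.asarray(nes, dtype=float))


def wald_to_onesided_p(wald_z) -> np.ndarray:
    """One-sided p for poor prognosis with high expression (beta > 0)."""
    return stats.norm.sf(np.asarray(wald_z, dtype=float))


def integrate_evidence(table: pd.DataFrame, p_floor: float = 1e-300) -> pd.DataFrame:
    """Fisher-integrate a TFs x sources matrix of one-sided p-values.

    Missing entries (NaN) are dropped per TF and the degrees of freedom
    shrink accordingly; TFs with no sources at all are excluded with a
    logged reason.  Output has columns n_sources, x2, df, integrated_p
    and rank (1 = strongest evidence), with ties broken by TF ID.
    """
    vals = table.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] > 1) or np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("evidence p-values must lie in [0, 1]")
    rows = []
    for tf in table.index:
        p = table.loc[tf].dropna().to_numpy(dtype=float)
        if p.size == 0:
            log.warning("TF %r has no evidence sources; excluded", tf)
            continue
        p = np.maximum(p, p_floor)
        x2, df, combined = fisher_integrate(p)
        rows.append((tf, p.size, x2, df, combined))
    if not rows:
        raise ValueError("no TF has any evidence source")
    out = pd.DataFrame(
        rows, columns=["tf", "n_sources", "x2", "df", "integrated_p"]
    ).set_index("tf")
    out = out.sort_values(["integrated_p", "tf"], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
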