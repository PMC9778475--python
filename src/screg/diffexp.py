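"""Two-group differential expression on log-normalized data.

Per gene: a two-sided Wilcoxon rank-sum test (normal approximation with
tie and continuity corrections — exact enumeration is hopeless at
single-cell sample sizes and ties are pervasive because of zero
inflation), Benjamini-Hochberg adjustment across genes, a fold change
computed on de-logged group means, and the signed-significance score

    -log10(adjusted p) * sign(log2FC)

used as the per-gene signature value for ranking, enrichment and
cross-experiment comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix

__all__ = [
    "wilcoxon_de",
    "bh_adjust",
    "log2_fold_change",
    "signed_significance",
    "build_signature",
    "de_summary",
]

_CHUNK = 512  # genes densified per block


def _rank_sum_p(block: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p for each row of ``block`` (genes x cells)."""
    n1, n2 = g1.size, g2.size
    n = n1 + n2
    data = block[:, np.concatenate([g1, g2])]
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction: sum over tie groups of (t^3 - t) per row
    srt = np.sort(data, axis=1)
    new = np.ones_like(srt, dtype=bool)
    new[:, 1:] = srt[:, 1:] != srt[:, :-1]
    grp = np.cumsum(new, axis=1)  # tie-group ids per row, 1..k
    offset = (np.arange(block.shape[0]) * (n + 1))[:, None]
    counts = np.bincount((grp + offset).ravel(), minlength=block.shape[0] * (n + 1))
    counts = counts.reshape(block.shape[0], n + 1).astype(float)
    tie_term = (counts**3 - counts).sum(axis=1)

    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sd = np.sqrt(np.maximum(var, 0.0))
    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(sd > 0, np.minimum(p, 1.0), 1.0)  # fully tied rows carry no signal
    return p


def wilcoxon_de(nm: NormalizedMatrix, groups: pd.Series) -> pd.Series:
    """Per-gene two-sided Wilcoxon rank-sum raw p-values.

    ``groups`` must take exactly two values across the cells; both
    groups need at least 3 cells.
    """
    groups = pd.Series(groups)
    if len(groups) != nm.n_cells:
        raise ValueError("groups must cover all cells")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1 = np.flatnonzero(groups.to_numpy() == levels[0])
    g2 = np.flatnonzero(groups.to_numpy() == levels[1])
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs at least 3 cells")

    n_genes = nm.shape[0]
    p = np.empty(n_genes)
    for start in range(0, n_genes, _CHUNK):
        stop = min(start + _CHUNK, n_genes)
        block = nm.X[start:stop].toarray()
        p[start:stop] = _rank_sum_p(block, g1, g2)
    return pd.Series(p, index=nm.genes, name="pval")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def log2_fold_change(
    nm: NormalizedMatrix, groups: pd.Series, treated: str, control: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2 of the ratio of de-logged group means (pseudocounted).

    De-logging maps the normalized value back to scaled counts via
    expm1; the pseudocount keeps the ratio finite for dropout genes.
    """
    groups = pd.Series(groups)
    idx_t = np.flatnonzero(groups.to_numpy() == treated)
    idx_c = np.flatnonzero(groups.to_numpy() == control)
    if idx_t.size == 0 or idx_c.size == 0:
        raise ValueError("both groups must be non-empty")

    def delogged_mean(idx):
        sub = nm.X[:, idx]
        expm1 = sub.copy()
        expm1.data = np.expm1(expm1.data)
        return np.asarray(expm1.sum(axis=1)).ravel() / idx.size

    mt = delogged_mean(idx_t)
    mc = delogged_mean(idx_c)
    lfc = np.log2((mt + pseudocount) / (mc + pseudocount))
    return pd.Series(lfc, index=nm.genes, name="log2fc")


def signed_significance(padj, log2fc, p_floor: float = 1e-300) -> np.ndarray:
    """-log10(max(padj, floor)) * sign(log2FC); sign(0) gives 0."""
    padj = np.asarray(padj, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    return -np.log10(np.maximum(padj, p_floor)) * np.sign(log2fc)


def build_signature(
    nm: NormalizedMatrix, groups: pd.Series, treated: str, control: str,
    pseudocount: float = 1.0, p_floor: float = 1e-300,
) -> pd.DataFrame:
    """Full per-gene signature: log2fc, pval, padj, signed_score."""
    two = pd.Series(groups)
    mask = two.isin([treated, control]).to_numpy()
    sub = NormalizedMatrix(nm.X[:, mask], nm.genes, nm.barcodes[mask], nm.scale_factor)
    sub_groups = two[mask]
    p = wilcoxon_de(sub, sub_groups)
    padj = bh_adjust(p.to_numpy())
    lfc = log2_fold_change(sub, sub_groups, treated, control, pseudocount)
    score = signed_significance(padj, lfc.to_numpy(), p_floor)
    return pd.DataFrame(
        {"log2fc": lfc, "pval": p, "padj": padj, "signed_score": score},
        index=nm.genes,
    )


def de_summary(
    sig: pd.DataFrame, padj_max: float = 0.01, lfc_min: float = 1.0,
    n_detected: int | None = None,
) -> dict:
    """Count significant up/down genes at the adjusted-p and |log2FC| cutoffs.

    ``fraction_of_detected`` is a percentage of ``n_detected`` genes
    (defaults to the number of genes in the signature).
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    if n_detected is None:
        n_detected = len(sig)
    if len(sig) == 0:
        return {"n_up": 0, "n_down": 0, "n_total": 0, "fraction_of_detected": 0.0}
    signif = sig["padj"] <= padj_max
    n_up = int((signif & (sig["log2fc"] > lfc_min)).sum())
    n_down = int((signif & (sig["log2fc"] < -lfc_min)).sum())
    n_total = n_up + n_down
    frac = 100.0 * n_total / n_detected if n_detected else 0.0
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_total": n_total,
        "fraction_of_detected": frac,
    }
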