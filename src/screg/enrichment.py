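"""Gene-set enrichment against a ranked signature, bulk and per cell.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov
running sum: genes are ranked by decreasing signature score, members of
the set ("hits") push the sum up in proportion to |score|^weight
(normalized so all hits sum to 1), non-members pull it down by
1/(N - set size), and the ES is the extremum of largest magnitude.  The
null is built by scoring random gene sets of the same size against the
same signature; NES divides the observed ES by the mean |null ES| of
matching sign and the permutation p-value carries a plus-one correction
so it is never exactly zero.

Per-cell enrichment scores each cell's signature — its normalized
expression centered against the dataset mean — against every set,
producing the cells x pathways NES matrix used for projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = [
    "EnrichmentResult",
    "gsea_es",
    "gsea_nes",
    "per_cell_signatures",
    "per_cell_enrichment",
]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pval: float
    leading_edge: list[str] = field(default_factory=list)
    set_size: int = 0


def _rank_scores(scores: pd.Series) -> pd.Series:
    """Sort by decreasing score, ties broken by gene ID for determinism."""
    # stable sort on score after an ID sort gives a deterministic order
    df = (
        pd.DataFrame({"score": scores})
        .sort_index()
        .sort_values("score", ascending=False, kind="stable")
    )
    return df["score"]


def _es_from_hits(ranked_scores: np.ndarray, hit_mask: np.ndarray, weight: float):
    """ES, running sum and extremum index from a boolean hit mask."""
    n = ranked_scores.size
    n_hit = int(hit_mask.sum())
    w = np.abs(ranked_scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit weights zero (e.g. zero scores): fall back to equal steps
        hit_w = hit_mask.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if abs(running[imax]) >= abs(running[imin]):
        return float(running[imax]), running, imax
    return float(running[imin]), running, imin


def gsea_es(signature: pd.Series, gene_set, weight: float = 1.0):
    """Enrichment score of one gene set.

    Returns ``(es, running_sum, leading_edge)`` where the running sum is
    indexed by the ranked gene order and the leading edge is the list of
    set members up to (positive ES) or from (negative ES) the extremum.
    """
    ranked = _rank_scores(pd.Series(signature, dtype=float))
    members = set(gene_set)
    hit_mask = ranked.index.isin(members)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the signature universe")
    if n_hit == ranked.size:
        raise ValueError("gene set equals the whole universe")
    es, running, iext = _es_from_hits(ranked.to_numpy(), hit_mask, weight)
    genes = ranked.index.to_numpy()
    if es >= 0:
        le = [g for g in genes[: iext + 1] if g in members]
    else:
        le = [g for g in genes[iext:] if g in members]
    running_sum = pd.Series(running, index=ranked.index)
    return es, running_sum, le


def gsea_nes(
    signature: pd.Series,
    gene_set,
    name: str = "",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """ES plus gene-permutation NES and p-value for one set."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    signature = pd.Series(signature, dtype=float)
    es, _, le = gsea_es(signature, gene_set, weight)
    ranked = _rank_scores(signature)
    members = set(gene_set)
    n_hit = int(ranked.index.isin(members).sum())
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.to_numpy(), n_hit, weight, n_perm, rng)
    return _result_from_null(name, es, le, null, n_perm, n_hit)


def _null_es(
    ranked_scores: np.ndarray, n_hit: int, weight: float, n_perm: int,
    rng: np.random.Generator, chunk: int = 256,
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets, vectorized in chunks."""
    n = ranked_scores.size
    w = np.abs(ranked_scores) ** weight
    out = np.empty(n_perm)
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        pick = rng.random((m, n)).argpartition(n_hit - 1, axis=1)[:, :n_hit]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, pick, True, axis=1)
        hit_w = np.where(mask, w, 0.0)
        denom = hit_w.sum(axis=1, keepdims=True)
        zero = denom.ravel() == 0
        if zero.any():
            hit_w[zero] = mask[zero].astype(float)
            denom[zero] = float(n_hit)
        steps = hit_w / denom - (~mask) / (n - n_hit)
        running = np.cumsum(steps, axis=1)
        vmax = running.max(axis=1)
        vmin = running.min(axis=1)
        out[start : start + m] = np.where(np.abs(vmax) >= np.abs(vmin), vmax, vmin)
    return out


def _result_from_null(name, es, le, null, n_perm, n_hit) -> EnrichmentResult:
    if np.all(null == 0):
        raise ValueError("degenerate permutation null (all zero)")
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones_like(null, dtype=bool)
    if same_sign.any():
        nes = es / np.abs(null[same_sign]).mean() if es != 0 else 0.0
    else:
        nes = es / np.abs(null).mean()
    extreme = int((np.abs(null) >= abs(es)).sum())
    p = (1 + extreme) / (1 + n_perm)
    return EnrichmentResult(name, float(es), float(nes), float(p), le, n_hit)


def per_cell_signatures(nm: NormalizedMatrix) -> pd.DataFrame:
    """Per-cell gene scores: normalized expression minus the dataset mean.

    Returns a genes x cells DataFrame; each gene's scores sum to zero
    across cells by construction.
    """
    if nm.n_cells < 2:
        raise ValueError("per-cell signatures need at least 2 cells")
    dense = nm.dense()
    centered = dense - dense.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=nm.genes, columns=nm.barcodes)


def per_cell_enrichment(
    signatures: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells x pathways NES matrix.

    One permutation test per (cell, set); cells whose signature is all
    zero get NES = 0 by convention.  Null distributions are shared
    between sets of equal effective size within a cell, which keeps the
    cost at one null per (cell, set size).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    out = pd.DataFrame(
        0.0, index=signatures.columns, columns=list(gene_sets), dtype=float
    )
    universe = signatures.index
    sizes = {
        name: int(universe.isin(set(genes)).sum()) for name, genes in gene_sets.items()
    }
    for name, k in sizes.items():
        if k == 0:
            raise ValueError(f"gene set {name!r} does not intersect the universe")
        if k == len(universe):
            raise ValueError(f"gene set {name!r} equals the whole universe")
    for ci, cell in enumerate(signatures.columns):
        sig = signatures.iloc[:, ci]
        if not np.any(sig.to_numpy()):
            continue  # all-zero signature: NES row stays 0
        ranked = _rank_scores(sig)
        ranked_arr = ranked.to_numpy()
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        null_by_size: dict[int, np.ndarray] = {}
        for name, genes in gene_sets.items():
            k = sizes[name]
            if k not in null_by_size:
                null_by_size[k] = _null_es(ranked_arr, k, weight, n_perm, rng)
            mask = ranked.index.isin(set(genes))
            es, _, _ = _es_from_hits(ranked_arr, mask, weight)
            res = _result_from_null(name, es, [], null_by_size[k], n_perm, k)
            out.loc[cell, name] = res.nes
    return out
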