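"""Marker-based cell-cycle phase scoring and assignment.

Scoring follows the binned-control scheme popularised for tumor
single-cell data: genes are binned by their dataset-average expression,
each marker gene draws control genes from its own bin, and a cell's
program score is the mean centered expression of the marker genes minus
that of the controls.  Working on centered expression (each gene minus
its dataset mean) makes the score 0 for a cell that looks exactly like
the dataset average.  A cell is S or G2M if that program's score is
positive and largest; G1 is the default phase when neither program
scores positive (G1 has no dedicated marker program).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

__all__ = ["phase_scores", "assign_phase", "phase_fractions", "PHASES"]

PHASES = ("G1", "S", "G2M")


def _program_score(
    centered: np.ndarray,
    gene_index: pd.Index,
    genes: list[str],
    bins: np.ndarray,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    pos = gene_index.get_indexer(genes)
    pos = pos[pos >= 0]
    if pos.size == 0:
        raise ValueError("marker set does not intersect the gene universe")
    ctrl_pos: list[np.ndarray] = []
    for p in pos:
        pool = np.flatnonzero(bins == bins[p])
        take = min(n_ctrl, pool.size)
        ctrl_pos.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.unique(np.concatenate(ctrl_pos))
    return centered[pos].mean(axis=0) - centered[ctrl].mean(axis=0)


def phase_scores(
    nm: NormalizedMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M scores against expression-matched controls."""
    dense = nm.dense()
    centered = dense - dense.mean(axis=1, keepdims=True)
    avg = dense.mean(axis=1)
    # equal-occupancy bins of dataset-average expression
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.arange(len(avg)) * n_bins // len(avg)
    rng = np.random.default_rng(seed)
    s = _program_score(centered, nm.genes, list(s_genes), bins, n_ctrl, rng)
    g2m = _program_score(centered, nm.genes, list(g2m_genes), bins, n_ctrl, rng)
    return pd.DataFrame({"s_score": s, "g2m_score": g2m}, index=nm.barcodes)


def assign_phase(scores: pd.DataFrame) -> pd.Series:
    """G1 unless a program scores positive; ties go to S."""
    s = scores["s_score"].to_numpy()
    g2m = scores["g2m_score"].to_numpy()
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(g2m))):
        raise ValueError("phase scores must be finite")
    phase = np.full(len(scores), "G1", dtype=object)
    phase[(s > 0) & (s >= g2m)] = "S"
    phase[(g2m > 0) & (g2m > s)] = "G2M"
    return pd.Series(phase, index=scores.index, name="phase")


def phase_fractions(phases: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group phase counts and percentages (2 decimals).

    Output rows indexed by (group, phase) over {G1, S, G2M}; the
    percentage is 100 * count / group size rounded to 2 decimals.
    """
    phases = pd.Series(phases)
    groups = pd.Series(groups)
    if len(phases) != len(groups):
        raise ValueError("phase and group labels must be aligned")
    rows = []
    for g in pd.unique(groups):
        sub = phases[groups.to_numpy() == g]
        total = len(sub)
        for ph in PHASES:
            count = int((sub == ph).sum())
            pct = round(100.0 * count / total, 2) if total else 0.0
            rows.append((g, ph, count, pct))
    return pd.DataFrame(rows, columns=["group", "phase", "count", "percent"]).set_index(
        ["group", "phase"]
    )
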