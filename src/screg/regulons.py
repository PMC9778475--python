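"""Master-regulator analysis: analytic regulon enrichment of a signature.

Each transcription factor's regulon (signed, weighted target list) is
scored against the differential-expression signature.  Gene-level
signed-significance scores are first rank-transformed to standard
normal quantiles, z = Phi^-1((rank - 0.5)/N), which makes the statistic
robust to the p-value floor.  The regulon NES is then a
likelihood-weighted Stouffer combination of the mode-signed target
z-scores:

    NES = sum_i(mor_i * lik_i * z_i) / sqrt(sum_i lik_i^2)

which is standard normal when targets behave like independent null
genes, giving an analytic two-sided p-value per TF.  A negative NES
means the regulon's activated targets fall among the genes repressed by
the treatment (and vice versa), i.e. predicted TF activity loss.

Two independently derived networks can be combined TF-by-TF with an
equal-weight Stouffer consensus, and the same statistic projected onto
per-cell signatures yields a cells x TFs activity matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Regulon
from .diffexp import bh_adjust

__all__ = [
    "signature_to_z",
    "regulon_nes",
    "mra",
    "consensus",
    "per_cell_tf_activity",
]

log = logging.getLogger(__name__)


def signature_to_z(signed_scores: pd.Series) -> pd.Series:
    """Rank-based inverse-normal transform of per-gene signed scores.

    Ties share mid-ranks, so equal scores map to equal z; the transform
    is order-preserving.
    """
    s = pd.Series(signed_scores, dtype=float)
    if len(s) < 100:
        raise ValueError("signature must cover at least 100 genes")
    ranks = stats.rankdata(s.to_numpy())  # average ranks for ties
    q = (ranks - 0.5) / len(s)
    return pd.Series(stats.norm.ppf(q), index=s.index, name="z")


def regulon_nes(z: pd.Series, regulon: Regulon, min_targets: int = 2):
    """Weighted-Stouffer NES and two-sided normal p for one regulon.

    Returns ``(nes, pval, n_used)``; raises if fewer than
    ``min_targets`` regulon targets are present in ``z``.
    """
    present = np.isin(regulon.targets.astype(str), z.index.to_numpy().astype(str))
    n_used = int(present.sum())
    if n_used < min_targets:
        raise ValueError(
            f"regulon {regulon.tf!r}: only {n_used} usable targets (< {min_targets})"
        )
    zt = z.loc[regulon.targets[present].astype(str)].to_numpy()
    mor = regulon.mor[present]
    lik = regulon.likelihood[present]
    nes = float((mor * lik * zt).sum() / np.sqrt((lik**2).sum()))
    pval = float(2.0 * stats.norm.sf(abs(nes)))
    return nes, max(pval, np.finfo(float).tiny), n_used


def mra(
    signature: pd.DataFrame, network: list[Regulon], min_targets: int = 2
) -> pd.DataFrame:
    """Score every regulon of a network against a DE signature.

    ``signature`` is the per-gene table with a ``signed_score`` column.
    Output columns: nes ("Act"), pval, padj (BH across TFs scored),
    exp_score (the TF's own signed-significance, "Exp"), exp_rank (the
    TF's 1-based rank in the transcriptome-wide DE, most significant
    first), n_targets.  Rows sorted by decreasing NES.  TFs with fewer
    than ``min_targets`` usable targets are skipped with a logged
    reason.
    """
    if not network:
        raise ValueError("empty network")
    z = signature_to_z(signature["signed_score"])
    abs_rank = (
        pd.Series(-signature["signed_score"].abs(), index=signature.index)
        .rank(method="min")
        .astype(int)
    )
    rows = []
    for reg in network:
        try:
            nes, pval, n_used = regulon_nes(z, reg, min_targets)
        except ValueError as exc:
            log.warning("skipping TF: %s", exc)
            continue
        if reg.tf in signature.index:
            exp_score = float(signature.loc[reg.tf, "signed_score"])
            exp_rank = int(abs_rank.loc[reg.tf])
        else:
            exp_score, exp_rank = np.nan, -1
        rows.append((reg.tf, nes, pval, exp_score, exp_rank, n_used))
    if not rows:
        raise ValueError("no regulon had enough usable targets")
    out = pd.DataFrame(
        rows, columns=["tf", "nes", "pval", "exp_score", "exp_rank", "n_targets"]
    ).set_index("tf")
    out["padj"] = bh_adjust(out["pval"].to_numpy())
    out = out[["nes", "pval", "padj", "exp_score", "exp_rank", "n_targets"]]
    return out.sort_values("nes", ascending=False)


def consensus(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight Stouffer combination of two MRA results.

    Returns a table over the shared TFs with columns nes_a, nes_b and
    combined = (nes_a + nes_b)/sqrt(2), sorted by decreasing |combined|.
    """
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("the two MRA results share no TFs")
    out = pd.DataFrame(
        {
            "nes_a": a.loc[shared, "nes"],
            "nes_b": b.loc[shared, "nes"],
        }
    )
    out["combined"] = (out["nes_a"] + out["nes_b"]) / np.sqrt(2.0)
    return out.reindex(out["combined"].abs().sort_values(ascending=False).index)


def per_cell_tf_activity(
    signatures: pd.DataFrame, network: list[Regulon], min_targets: int = 2
) -> pd.DataFrame:
    """Cells x TFs NES matrix from per-cell centered signatures.

    Cells with an all-zero signature get NES 0 for every TF (no
    evidence either way).
    """
    scored_tfs = []
    for reg in network:
        present = np.isin(reg.targets.astype(str), signatures.index.to_numpy().astype(str))
        if int(present.sum()) >= min_targets:
            scored_tfs.append(reg)
        else:
            log.warning("per-cell activity: skipping TF %r (too few targets)", reg.tf)
    if not scored_tfs:
        raise ValueError("no regulon had enough usable targets")
    out = pd.DataFrame(
        0.0, index=signatures.columns, columns=[r.tf for r in scored_tfs]
    )
    for cell in signatures.columns:
        sig = signatures[cell]
        if not np.any(sig.to_numpy()):
            continue
        z = signature_to_z(sig)
        for reg in scored_tfs:
            nes, _, _ = regulon_nes(z, reg, min_targets)
            out.loc[cell, reg.tf] = nes
    return out
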