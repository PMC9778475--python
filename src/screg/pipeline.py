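"""End-to-end orchestration: simulate/load, demux, QC, DE, enrichment,
master regulators, cell cycle, pseudobulk comparison and evidence
integration, with every stage output cached as a plain file.

The pipeline can start either from files (counts + hashtags + networks)
or from a :class:`~screg.simulate.SimConfig`, in which case the planted
ground truth is carried along and the summary reports recovery metrics
(demux accuracy, phase accuracy, whether planted regulons surface among
the top consensus master regulators).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as sio
from .cellcycle import assign_phase, phase_fractions, phase_scores
from .containers import CountMatrix
from .demux import CONTROL, MULTIPLET, TREATED, demultiplex
from .diffexp import build_signature, de_summary
from .enrichment import gsea_nes, per_cell_enrichment, per_cell_signatures
from .qc import filter_cells, filter_genes, log_normalize, pseudobulk, rpm
from .regulons import consensus, mra, per_cell_tf_activity
from .simulate import (
    SimConfig,
    generate_bulk_reference,
    generate_dataset,
    generate_network,
    generate_survival_cohort,
    resample_network,
)
from .survival import (
    cox_wald,
    integrate_evidence,
    km_by_group,
    nes_to_onesided_p,
    stratify_expression,
    wald_to_onesided_p,
)

__all__ = ["PipelineConfig", "run_pipeline", "spearman_cc"]

log = logging.getLogger(__name__)


def spearman_cc(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 shared genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class PipelineConfig:
    """Everything a full run needs: inputs (files or a simulation) and
    per-stage parameters with explicit seeds."""

    # inputs: either a simulation config ...
    sim: SimConfig | None = None
    n_tfs: int = 50
    targets_per_tf: int = 40
    network_overlap: float = 0.8
    # ... or file paths
    counts_dir: str | None = None
    counts_csv: str | None = None
    hashtags_csv: str | None = None
    network_tsv: str | None = None
    network_tsv_b: str | None = None
    gene_sets_gmt: str | None = None
    survival_csv: str | None = None
    # stage parameters
    ratio_threshold: float = 10.0
    min_genes: int = 1000
    min_cells: int = 3
    scale_factor: float = 10_000.0
    padj_max: float = 0.01
    lfc_min: float = 1.0
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    per_cell_sets_cells: int = 0  # cells to project per-cell NES on (0 = skip)
    per_cell_perm: int = 200
    cc_n_bins: int = 24
    cc_n_ctrl: int = 100
    surv_n: int = 500
    surv_censor: float = 0.3
    surv_hr_prognostic: float = 2.0
    n_evidence_tfs: int = 10
    seed: int = 0

    def validate(self) -> None:
        has_files = self.counts_dir or self.counts_csv
        if self.sim is None and not has_files:
            raise ValueError("config needs either file inputs or a simulation config")
        if has_files and self.hashtags_csv is None:
            raise ValueError("file inputs require a hashtag CSV")


def _stage(name: str, t0: float, **shapes) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in shapes.items()))


def run_pipeline(cfg: PipelineConfig, out_dir: str) -> dict:
    """Execute every stage and return the machine-readable summary.

    All stage outputs are written under ``out_dir`` as CSV/TSV/JSON; the
    summary is also written to ``summary.json``.  Any stage failure is
    re-raised annotated with the stage name.
    """
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": []}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        truth = None
        net_a = net_b = None
        gene_sets = None
        if cfg.sim is not None:
            net_a = generate_network(
                cfg.n_tfs, cfg.targets_per_tf, seed=cfg.seed, n_genes=cfg.sim.n_genes
            )
            net_b = resample_network(
                net_a, cfg.network_overlap, seed=cfg.seed + 1, n_genes=cfg.sim.n_genes
            )
            counts, hashtags, truth = generate_dataset(cfg.sim, net_a)
            sio.write_regulons(net_a, os.path.join(out_dir, "network_a.tsv"))
            sio.write_regulons(net_b, os.path.join(out_dir, "network_b.tsv"))
            sio.write_hashtags(hashtags, os.path.join(out_dir, "hashtags.csv"))
            truth.cells.to_csv(os.path.join(out_dir, "truth_cells.csv"))
            gene_sets = dict(truth.phase_programs)
            for tf in truth.perturbed_tfs:
                reg = next(r for r in net_a if r.tf == tf)
                gene_sets[f"targets_of_{tf}"] = list(reg.targets)
        else:
            counts = (
                sio.read_mtx_dir(cfg.counts_dir)
                if cfg.counts_dir
                else sio.read_counts_csv(cfg.counts_csv)
            )
            hashtags = sio.read_hashtags(cfg.hashtags_csv)
            if cfg.network_tsv:
                net_a = sio.read_regulons(cfg.network_tsv)
            if cfg.network_tsv_b:
                net_b = sio.read_regulons(cfg.network_tsv_b)
            if cfg.gene_sets_gmt:
                gene_sets = sio.read_gmt(cfg.gene_sets_gmt)
        _stage(stage, t0, genes=counts.n_genes, cells=counts.n_cells)
        summary["stages"].append(stage)

        # ---- demultiplex -------------------------------------------
        stage = "demux"
        t0 = time.perf_counter()
        hashtags = hashtags.loc[counts.barcodes]
        labels, demux_counts = demultiplex(hashtags, cfg.ratio_threshold)
        labels.to_frame().to_csv(os.path.join(out_dir, "labels.csv"))
        summary["demux"] = demux_counts
        if truth is not None:
            singlet = ~truth.cells["true_multiplet"]
            ok = labels[singlet] == truth.cells.loc[singlet, "true_group"]
            summary["demux_accuracy_pct"] = float(100.0 * ok.mean())
        keep = (labels != MULTIPLET).to_numpy()
        counts = counts.subset_cells(keep)
        labels = labels[keep]
        _stage(stage, t0, **demux_counts)
        summary["stages"].append(stage)

        # ---- QC + normalization ------------------------------------
        stage = "qc_normalize"
        t0 = time.perf_counter()
        counts = filter_cells(counts, cfg.min_genes)
        counts = filter_genes(counts, cfg.min_cells)
        labels = labels[counts.barcodes]
        if truth is not None:
            truth.cells = truth.cells.loc[counts.barcodes]
        nm = log_normalize(counts, cfg.scale_factor)
        summary["n_cells_kept"] = counts.n_cells
        summary["n_genes_detected"] = counts.n_genes
        _stage(stage, t0, genes=counts.n_genes, cells=counts.n_cells)
        summary["stages"].append(stage)

        # ---- cell cycle --------------------------------------------
        stage = "cell_cycle"
        t0 = time.perf_counter()
        if truth is not None:
            s_genes = truth.phase_programs["S"]
            g2m_genes = truth.phase_programs["G2M"]
        else:
            markers = sio.read_gmt(sio.default_cell_cycle_gmt())
            s_genes, g2m_genes = markers["S"], markers["G2M"]
        try:
            scores = phase_scores(
                nm, s_genes, g2m_genes, cfg.cc_n_bins, cfg.cc_n_ctrl, seed=cfg.seed + 2
            )
            phases = assign_phase(scores)
            pf = phase_fractions(phases, labels)
            pd.concat([scores, phases], axis=1).to_csv(
                os.path.join(out_dir, "cell_cycle.csv")
            )
            pf.to_csv(os.path.join(out_dir, "phase_fractions.csv"))
            summary["phase_fractions"] = {
                f"{g}:{p}": pct for (g, p), pct in pf["percent"].items()
            }
            if truth is not None:
                acc = (phases == truth.cells["true_phase"]).mean()
                summary["phase_accuracy_pct"] = float(100.0 * acc)
        except ValueError as exc:
            log.warning("cell-cycle stage skipped: %s", exc)
            summary["phase_fractions"] = None
        _stage(stage, t0)
        summary["stages"].append(stage)

        # ---- differential expression --------------------------------
        stage = "diffexp"
        t0 = time.perf_counter()
        sig = build_signature(nm, labels, treated=TREATED, control=CONTROL)
        sig.to_csv(os.path.join(out_dir, "signature.csv"))
        summary["de"] = de_summary(sig, cfg.padj_max, cfg.lfc_min)
        _stage(stage, t0, genes=len(sig))
        summary["stages"].append(stage)

        # ---- gene-set enrichment ------------------------------------
        stage = "enrichment"
        t0 = time.perf_counter()
        if gene_sets:
            rows = []
            for i, (name, members) in enumerate(sorted(gene_sets.items())):
                res = gsea_nes(
                    sig["signed_score"], members, name=name, weight=cfg.gsea_weight,
                    n_perm=cfg.gsea_n_perm, seed=cfg.seed + 10 + i,
                )
                rows.append((name, res.es, res.nes, res.pval, res.set_size))
            gsea_df = pd.DataFrame(
                rows, columns=["set", "es", "nes", "pval", "size"]
            ).set_index("set")
            gsea_df.to_csv(os.path.join(out_dir, "gsea.csv"))
            summary["gsea"] = gsea_df["nes"].to_dict()
            if cfg.per_cell_sets_cells > 0:
                sub = nm.barcodes[: cfg.per_cell_sets_cells]
                sub_nm = type(nm)(
                    nm.X[:, : len(sub)], nm.genes, sub, nm.scale_factor
                )
                pcs = per_cell_signatures(sub_nm)
                pce = per_cell_enrichment(
                    pcs, gene_sets, weight=cfg.gsea_weight,
                    n_perm=cfg.per_cell_perm, seed=cfg.seed + 20,
                )
                pce.to_csv(os.path.join(out_dir, "per_cell_nes.csv"))
        _stage(stage, t0)
        summary["stages"].append(stage)

        # ---- master regulators --------------------------------------
        stage = "master_regulators"
        t0 = time.perf_counter()
        cons = None
        if net_a:
            mra_a = mra(sig, net_a)
            mra_a.to_csv(os.path.join(out_dir, "mra_a.csv"))
            if net_b:
                mra_b = mra(sig, net_b)
                mra_b.to_csv(os.path.join(out_dir, "mra_b.csv"))
                cons = consensus(mra_a, mra_b)
                cons.to_csv(os.path.join(out_dir, "mra_consensus.csv"))
                summary["top_consensus_mrs"] = {
                    tf: float(v) for tf, v in cons["combined"].head(10).items()
                }
            else:
                cons = mra_a.rename(columns={"nes": "combined"})[["combined"]]
            if truth is not None and truth.perturbed_tfs:
                top5 = set(cons.head(5).index)
                rec = [
                    tf
                    for tf in truth.perturbed_tfs
                    if tf in top5 and cons.loc[tf, "combined"] * np.sign(
                        truth.perturbed_tfs[tf]
                    ) > 0
                ]
                summary["planted_tfs_recovered_top5"] = len(rec)
                summary["n_planted_tfs"] = len(truth.perturbed_tfs)
        _stage(stage, t0)
        summary["stages"].append(stage)

        # ---- pseudobulk vs bulk -------------------------------------
        stage = "pseudobulk"
        t0 = time.perf_counter()
        pb = pseudobulk(counts, labels)
        pb.to_csv(os.path.join(out_dir, "pseudobulk.csv"))
        if truth is not None:
            bulk = generate_bulk_reference(truth, seed=cfg.seed + 3)
            shared = pb.index.intersection(bulk.index)
            ctr_rpm = rpm(pb.loc[shared, CONTROL])
            bulk_rpm = rpm(bulk.loc[shared])
            summary["pseudobulk_bulk_spearman"] = spearman_cc(ctr_rpm, bulk_rpm)
        _stage(stage, t0)
        summary["stages"].append(stage)

        # ---- survival + evidence integration ------------------------
        stage = "survival_evidence"
        t0 = time.perf_counter()
        if cfg.sim is not None and cons is not None and net_b is not None:
            candidates = list(cons.head(cfg.n_evidence_tfs).index)
            evid = {}
            for k, tf in enumerate(candidates):
                hr = (
                    cfg.surv_hr_prognostic
                    if tf in truth.perturbed_tfs and truth.perturbed_tfs[tf] < 0
                    else 1.0
                )
                truth.prognostic[tf] = hr
                cohort = generate_survival_cohort(
                    cfg.surv_n, hr, cfg.surv_censor, seed=cfg.seed + 100 + k
                )
                fit = cox_wald(cohort)
                strata = stratify_expression(cohort["expr"], 4)
                km = km_by_group(cohort, strata)
                pd.concat(km, names=["stratum"]).to_csv(
                    os.path.join(out_dir, f"km_{tf}.csv")
                )
                evid[tf] = {
                    "mra_a": float(nes_to_onesided_p(mra_a.loc[tf, "nes"])),
                    "mra_b": float(nes_to_onesided_p(mra_b.loc[tf, "nes"])),
                    "survival": float(wald_to_onesided_p(fit["wald_z"])),
                }
            table = pd.DataFrame(evid).T
            ranked = integrate_evidence(table)
            ranked.to_csv(os.path.join(out_dir, "evidence_ranking.csv"))
            summary["evidence_top_tfs"] = list(ranked.head(5).index)
        elif cfg.survival_csv:
            cohort = sio.read_survival(cfg.survival_csv)
            fit = cox_wald(cohort)
            summary["cox"] = {k: fit[k] for k in ("beta", "se", "wald_z", "pval")}
            strata = stratify_expression(cohort["expr"], 4)
            km = km_by_group(cohort, strata)
            pd.concat(km, names=["stratum"]).to_csv(os.path.join(out_dir, "km.csv"))
        _stage(stage, t0)
        summary["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
        cfg_dict = asdict(cfg)
        json.dump(cfg_dict, fh, indent=2, sort_keys=True, default=str)
    return summary
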