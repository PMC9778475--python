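"""Shared fixtures: tiny hand matrices and two session-scoped synthetic
runs (one with planted regulon perturbations, one null)."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

import screg as sg
from screg.containers import CountMatrix, NormalizedMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 3 cells with simple hand-checkable counts."""
    X = np.array(
        [
            [5, 0, 1],
            [0, 3, 2],
            [2, 2, 2],
            [0, 0, 7],
        ]
    )
    return CountMatrix(sp.csr_matrix(X), [f"g{i}" for i in range(4)], ["c0", "c1", "c2"])


def _process(counts, hashtags, truth, min_genes):
    labels, demux_summary = sg.demultiplex(hashtags)
    keep = (labels != "multiplet").to_numpy()
    m = counts.subset_cells(keep)
    m = sg.filter_cells(m, min_genes)
    m = sg.filter_genes(m, 3)
    labels = labels[m.barcodes]
    nm = sg.log_normalize(m)
    sig = sg.build_signature(nm, labels, treated="pnb", control="ctr")
    return SimpleNamespace(
        counts=counts,
        filtered=m,
        hashtags=hashtags,
        truth=truth,
        labels=labels,
        demux_summary=demux_summary,
        nm=nm,
        sig=sig,
    )


@pytest.fixture(scope="session")
def planted_run() -> SimpleNamespace:
    """200 cells/group, 1000 genes, 3 regulons repressed at effect -1."""
    net_a = sg.generate_network(20, 40, seed=3, n_genes=1000)
    planted = {r.tf: -1.0 for r in net_a[:3]}
    cfg = sg.SimConfig(
        n_cells_per_group=200,
        n_genes=1000,
        library_size_log_mean=8.5,
        perturbed_tfs=planted,
        seed=3,
    )
    counts, hashtags, truth = sg.generate_dataset(cfg, net_a)
    run = _process(counts, hashtags, truth, min_genes=200)
    run.cfg = cfg
    run.net_a = net_a
    run.net_b = sg.resample_network(net_a, 0.8, seed=4, n_genes=1000)
    run.planted = planted
    return run


@pytest.fixture(scope="session")
def null_run() -> SimpleNamespace:
    """Same scale, no planted effects anywhere (flat phases too)."""
    net = sg.generate_network(10, 20, seed=7, n_genes=1000)
    cfg = sg.SimConfig(
        n_cells_per_group=200,
        n_genes=1000,
        library_size_log_mean=8.5,
        perturbed_tfs={},
        phase_effect=0.0,
        seed=7,
    )
    counts, hashtags, truth = sg.generate_dataset(cfg, net)
    run = _process(counts, hashtags, truth, min_genes=200)
    run.cfg = cfg
    run.net = net
    return run


def make_nm(values, genes=None, barcodes=None) -> NormalizedMatrix:
    """Wrap a dense array of normalized values for direct-formula tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(sp.csr_matrix(values), genes, barcodes)
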