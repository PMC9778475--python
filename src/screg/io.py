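"""Readers and writers for the plain-text formats used by the pipeline.

Count matrices travel as a 10x-style MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) or as a dense
CSV (genes as rows); gene sets as GMT; regulon networks as a four-column
TSV (tf, target, mor, likelihood); hashtag counts, survival tables and
stage outputs as CSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, Regulon

__all__ = [
    "read_mtx_dir",
    "write_mtx_dir",
    "read_counts_csv",
    "write_counts_csv",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "read_hashtags",
    "write_hashtags",
    "read_survival",
    "write_survival",
]


def read_mtx_dir(path: str) -> CountMatrix:
    """Load matrix.mtx + features.tsv + barcodes.tsv from ``path``."""
    X = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    genes = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    ).iloc[:, 0]
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    ).iloc[:, 0]
    return CountMatrix(X, pd.Index(genes), pd.Index(barcodes))


def write_mtx_dir(m: CountMatrix, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(m.X))
    pd.Series(m.genes).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(m.barcodes).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_counts_csv(path: str) -> CountMatrix:
    """Dense CSV with genes as rows (index) and barcodes as columns."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(sp.csr_matrix(df.values), pd.Index(df.index), pd.Index(df.columns))


def write_counts_csv(m: CountMatrix, path: str) -> None:
    pd.DataFrame(m.X.toarray(), index=m.genes, columns=m.barcodes).to_csv(path)


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT: one set per line, ``name <tab> description <tab> gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_regulons(path: str) -> list[Regulon]:
    """Regulon TSV with columns tf, target, mor, likelihood."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for tf, grp in df.groupby("tf", sort=True):
        out.append(
            Regulon(
                tf=str(tf),
                targets=grp["target"].to_numpy(dtype=object),
                mor=grp["mor"].to_numpy(dtype=float),
                likelihood=grp["likelihood"].to_numpy(dtype=float),
            )
        )
    return out


def write_regulons(regulons: Iterable[Regulon], path: str) -> None:
    rows = []
    for r in regulons:
        for t, m, l in zip(r.targets, r.mor, r.likelihood):
            rows.append((r.tf, t, m, l))
    pd.DataFrame(rows, columns=["tf", "target", "mor", "likelihood"]).to_csv(
        path, sep="\t", index=False
    )


def read_hashtags(path: str) -> pd.DataFrame:
    """Hashtag CSV: barcode,h1,h2 -> DataFrame indexed by barcode."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    if df.shape[1] != 2:
        raise ValueError("expected exactly two hashtag columns")
    return df


def write_hashtags(hashtags: pd.DataFrame, path: str) -> None:
    hashtags.to_csv(path, index_label="barcode")


def read_survival(path: str) -> pd.DataFrame:
    """Survival CSV: sample,time,event,expr."""
    df = pd.read_csv(path)
    required = {"sample", "time", "event", "expr"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return df


def write_survival(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def default_cell_cycle_gmt() -> str:
    """Path of the packaged S / G2M marker gene lists."""
    return os.path.join(os.path.dirname(__file__), "data", "cell_cycle_markers.gmt")
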