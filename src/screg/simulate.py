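"""Synthetic hashed two-condition single-cell experiment with known truth.

The generator emulates the study design downstream code is built for: a
control flask and a drug-treated flask, each labelled with one hashtag
antibody, pooled and sequenced together.  Defaults approximate the real
experiment's scale (~1250 cells per flask, 18,000 genes, ~7% ambiguous
droplets) but every knob is a config field so tests can run small.

Counts follow a negative-binomial model: relative gene abundances are
log-normal, each cell has a log-normal expected library size, and
counts are NB with a shared inverse-dispersion.  Treatment effects are
planted on the targets of chosen TF regulons as a log-scale shift of
``mor * effect`` in treated cells; cell-cycle structure comes from two
disjoint marker programs (S and G2M — G1 is assignment-by-default) that
are multiplicatively elevated in cells of the matching phase.  Hashtag
counts are Poisson around a signal mean for a cell's own tag and a
background mean for the other; multiplet droplets receive the signal
mean on both tags, which reproduces the three clouds of a hashtag
scatter plot.

All randomness flows from the single config seed through one named
generator, so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, Regulon
from .demux import CONTROL, TREATED

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gene_ids",
    "generate_network",
    "resample_network",
    "generate_dataset",
    "generate_bulk_reference",
    "generate_survival_cohort",
]

_PHASES = ("G1", "S", "G2M")
_CELL_CHUNK = 256  # cells simulated per block (fixed: keeps draws deterministic)


@dataclass
class SimConfig:
    """Parameters of the simulated hashed two-condition experiment."""

    n_cells_per_group: int = 1250
    n_genes: int = 18_000
    n_hashtags: int = 2
    multiplet_rate: float = 0.07
    library_size_log_mean: float = 9.2  # ~10k expected counts per cell
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 2.0  # NB inverse-dispersion (size); var = mu + mu^2/size
    perturbed_tfs: dict = field(default_factory=dict)  # tf -> signed log-scale effect
    phase_fractions: dict = field(
        default_factory=lambda: {
            CONTROL: (0.25, 0.50, 0.25),  # (G1, S, G2M), proliferating culture
            TREATED: (0.48, 0.36, 0.16),  # treatment arrests cells in G1
        }
    )
    hashtag_signal_mean: float = 200.0
    hashtag_background_mean: float = 2.0
    phase_effect: float = 1.0  # log-scale up-shift of program genes in-phase
    n_phase_genes: int = 50
    gene_abundance_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_group < 1 or self.n_genes < 1:
            raise ValueError("cell and gene counts must be positive")
        if self.n_hashtags != 2:
            raise ValueError("this design uses exactly two hashtags")
        if not 0 <= self.multiplet_rate < 1:
            raise ValueError("multiplet_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.hashtag_signal_mean <= 0 or self.hashtag_background_mean <= 0:
            raise ValueError("hashtag means must be positive")
        for g, fr in self.phase_fractions.items():
            if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) < 0:
                raise ValueError(f"phase fractions for {g!r} must be a triple summing to 1")
        for tf, eff in self.perturbed_tfs.items():
            if not np.isfinite(eff):
                raise ValueError(f"effect size for {tf!r} is not finite")


@dataclass
class GroundTruth:
    """Planted truth for every simulated cell and perturbation."""

    cells: pd.DataFrame  # index barcode: true_group, true_phase, true_multiplet, library_size
    perturbed_tfs: dict  # tf -> signed log-scale effect
    phase_programs: dict  # phase -> list of program gene IDs
    gene_means: pd.Series  # relative gene abundances (sum to 1)
    prognostic: dict = field(default_factory=dict)  # gene -> true hazard ratio


def gene_ids(n: int) -> pd.Index:
    return pd.Index([f"gene{i:05d}" for i in range(n)])


def generate_network(
    n_tfs: int,
    targets_per_tf: int,
    seed: int,
    genes=None,
    n_genes: int = 18_000,
    activator_fraction: float = 0.7,
) -> list[Regulon]:
    """Random TF-target network over a gene pool.

    TFs are themselves genes of the pool; each regulon samples
    ``targets_per_tf`` distinct targets (excluding the TF), signs them
    activating with probability ``activator_fraction``, and draws edge
    likelihoods uniformly from (0.1, 1].  Regulons may share targets.
    """
    if n_tfs < 1 or targets_per_tf < 2:
        raise ValueError("n_tfs must be >= 1 and targets_per_tf >= 2")
    pool = pd.Index(genes) if genes is not None else gene_ids(n_genes)
    if len(pool) <= targets_per_tf:
        raise ValueError("target pool must be larger than targets_per_tf")
    rng = np.random.default_rng(seed)
    tfs = rng.choice(len(pool), size=n_tfs, replace=False)
    regulons = []
    for ti in tfs:
        tf = pool[ti]
        candidates = np.delete(np.arange(len(pool)), ti)
        tgt = rng.choice(candidates, size=targets_per_tf, replace=False)
        mor = np.where(rng.random(targets_per_tf) < activator_fraction, 1.0, -1.0)
        lik = 0.1 + 0.9 * rng.random(targets_per_tf)
        regulons.append(Regulon(str(tf), pool[tgt].to_numpy(dtype=object), mor, lik))
    return regulons


def resample_network(
    network: list[Regulon], keep_frac: float, seed: int, genes=None, n_genes: int = 18_000
) -> list[Regulon]:
    """A correlated replicate of a network, as from an independent cohort.

    Each regulon keeps a ``keep_frac`` fraction of its edges and
    replaces the rest with fresh random targets; likelihoods are
    redrawn.  Used to emulate two networks inferred from different
    patient cohorts that agree on most of their biology.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must lie in (0, 1]")
    pool = pd.Index(genes) if genes is not None else gene_ids(n_genes)
    rng = np.random.default_rng(seed)
    out = []
    for reg in network:
        n = len(reg)
        n_keep = max(2, int(round(keep_frac * n)))
        keep = rng.choice(n, size=min(n_keep, n), replace=False)
        targets = list(reg.targets[keep])
        mor = list(reg.mor[keep])
        used = set(targets) | {reg.tf}
        candidates = pool[~pool.isin(used)]
        n_new = n - len(targets)
        if n_new > 0:
            fresh = rng.choice(len(candidates), size=n_new, replace=False)
            targets += list(candidates[fresh])
            mor += list(np.where(rng.random(n_new) < 0.7, 1.0, -1.0))
        lik = 0.1 + 0.9 * rng.random(len(targets))
        out.append(Regulon(reg.tf, np.array(targets, dtype=object), np.array(mor), lik))
    return out


def _draw_phases(rng, fractions, n) -> np.ndarray:
    return rng.choice(np.array(_PHASES, dtype=object), size=n, p=np.asarray(fractions))


def generate_dataset(
    config: SimConfig, network: list[Regulon]
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate counts, hashtag counts and ground truth.

    Returns ``(counts, hashtags, truth)`` where ``hashtags`` is a
    barcode-indexed DataFrame with columns h1 (control tag) and h2
    (treated tag).  Multiplet droplets are extra cells whose
    transcriptome comes from one randomly chosen group but whose
    hashtags carry both signals.
    """
    config.validate()
    tf_names = {r.tf for r in network}
    unknown = set(config.perturbed_tfs) - tf_names
    if unknown:
        raise ValueError(f"perturbed TFs not in network: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    genes = gene_ids(config.n_genes)
    n_grp = config.n_cells_per_group
    n_mult = int(round(config.multiplet_rate / (1 - config.multiplet_rate) * 2 * n_grp))
    n_cells = 2 * n_grp + n_mult
    barcodes = pd.Index([f"cell{i:05d}" for i in range(n_cells)])

    # 1. relative gene abundances
    w = rng.lognormal(mean=0.0, sigma=config.gene_abundance_log_sd, size=config.n_genes)
    p_gene = w / w.sum()

    # 2. phase programs: disjoint marker sets from the better-expressed half
    # of the transcriptome (cycle genes are not rare transcripts)
    upper_half = np.argsort(p_gene, kind="stable")[config.n_genes // 2 :]
    n_prog = min(config.n_phase_genes, len(upper_half) // 2)
    prog_idx = rng.choice(upper_half, size=2 * n_prog, replace=False)
    s_idx, g2m_idx = prog_idx[:n_prog], prog_idx[n_prog:]
    programs = {"S": list(genes[s_idx]), "G2M": list(genes[g2m_idx])}

    # 3. cell-level truth
    group = np.array([CONTROL] * n_grp + [TREATED] * n_grp, dtype=object)
    multiplet = np.zeros(n_cells, dtype=bool)
    if n_mult:
        mult_group = rng.choice(np.array([CONTROL, TREATED], dtype=object), size=n_mult)
        group = np.concatenate([group, mult_group])
        multiplet[2 * n_grp :] = True
    phase = np.empty(n_cells, dtype=object)
    for g in (CONTROL, TREATED):
        idx = np.flatnonzero(group == g)
        phase[idx] = _draw_phases(rng, config.phase_fractions[g], idx.size)

    # 4. expected library sizes
    lib = rng.lognormal(config.library_size_log_mean, config.library_size_log_sd, n_cells)

    # 5. per-gene log-scale shifts
    treat_shift = np.zeros(config.n_genes)
    for tf, eff in config.perturbed_tfs.items():
        reg = next(r for r in network if r.tf == tf)
        pos = genes.get_indexer(reg.targets.astype(str))
        ok = pos >= 0
        treat_shift[pos[ok]] += reg.mor[ok] * eff
    phase_shift = {
        ph: np.zeros(config.n_genes) for ph in _PHASES
    }
    phase_shift["S"][s_idx] = config.phase_effect
    phase_shift["G2M"][g2m_idx] = config.phase_effect
    treat_mult = np.exp(treat_shift)
    phase_mult = {ph: np.exp(v) for ph, v in phase_shift.items()}

    # 6. negative-binomial counts, in fixed-size cell blocks
    theta = config.nb_dispersion
    blocks = []
    for start in range(0, n_cells, _CELL_CHUNK):
        stop = min(start + _CELL_CHUNK, n_cells)
        mu = np.empty((config.n_genes, stop - start))
        for j, c in enumerate(range(start, stop)):
            wgt = p_gene * phase_mult[phase[c]]
            if group[c] == TREATED:
                wgt = wgt * treat_mult
            mu[:, j] = lib[c] * wgt / wgt.sum()
        counts = rng.negative_binomial(theta, theta / (theta + mu))
        blocks.append(sp.csr_matrix(counts))
    X = sp.hstack(blocks, format="csr")
    matrix = CountMatrix(X, genes, barcodes)

    # 7. hashtag counts
    mean_h1 = np.where(
        multiplet | (group == CONTROL),
        config.hashtag_signal_mean,
        config.hashtag_background_mean,
    )
    mean_h2 = np.where(
        multiplet | (group == TREATED),
        config.hashtag_signal_mean,
        config.hashtag_background_mean,
    )
    h1 = rng.poisson(mean_h1)
    h2 = rng.poisson(mean_h2)
    hashtags = pd.DataFrame({"h1": h1, "h2": h2}, index=barcodes)

    cells = pd.DataFrame(
        {
            "true_group": group,
            "true_phase": phase,
            "true_multiplet": multiplet,
            "library_size": np.asarray(X.sum(axis=0)).ravel(),
        },
        index=barcodes,
    )
    truth = GroundTruth(
        cells=cells,
        perturbed_tfs=dict(config.perturbed_tfs),
        phase_programs=programs,
        gene_means=pd.Series(p_gene, index=genes),
    )
    return matrix, hashtags, truth


def generate_bulk_reference(
    truth: GroundTruth, library_size: float = 5e6, nb_dispersion: float = 20.0,
    seed: int = 0,
) -> pd.Series:
    """A bulk-style count profile drawn from the same gene abundances.

    Emulates an external bulk RNA-seq reference of the untreated line:
    same relative abundances, much deeper library, tighter dispersion.
    """
    rng = np.random.default_rng(seed)
    mu = truth.gene_means.to_numpy() * library_size
    counts = rng.negative_binomial(nb_dispersion, nb_dispersion / (nb_dispersion + mu))
    return pd.Series(counts, index=truth.gene_means.index, name="bulk")


def generate_survival_cohort(
    n: int, gene_hr: float, censor_rate: float, seed: int, baseline_hazard: float = 0.1
) -> pd.DataFrame:
    """Exponential survival cohort with a log-linear expression effect.

    Hazard for sample i is ``baseline * exp(ln(gene_hr) * expr_i)``
    with standard-normal expression; censoring is independent
    exponential with rate tuned so roughly ``censor_rate`` of samples
    are censored.
    """
    if n < 10:
        raise ValueError("cohort needs at least 10 samples")
    if gene_hr <= 0:
        raise ValueError("gene_hr must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expr = rng.normal(size=n)
    beta = np.log(gene_hr)
    hazard = baseline_hazard * np.exp(beta * expr)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample": [f"s{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "expr": expr,
        }
    )
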