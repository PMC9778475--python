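# Methods

`screg` re-implements, as a tested library, the analysis of a cell-hashing
single-cell RNA-seq experiment contrasting an HDAC-inhibitor-treated
neuroblastoma culture with its vehicle control: demultiplexing, QC and
normalization, differential expression, gene-set and regulon enrichment,
cell-cycle assignment, pseudobulk comparison and survival-evidence
integration. This note records the statistical choices, the defaults and
why, what the synthetic data emulate, and known limitations.

## Hashtag demultiplexing

Each flask is labelled with one hashtag antibody before pooling, so every
droplet carries two hashtag counts (h1 = control, h2 = treated). The rule is
hierarchical: a cell with counts for exactly one hashtag belongs to that
sample; otherwise the larger count must be at least `ratio_threshold` times
the smaller (default 10, inclusive: `a >= 10 b`); anything else — including
(0, 0) — is a multiplet. The comparison uses raw counts. The rule is exposed
per cell (`assign_cell`) and vectorized (`demultiplex`); the threshold is a
parameter because the 10x cutoff is a convention, not a law.

## QC and normalization

Cells with fewer than 1000 detected genes are dropped first, then genes seen
in fewer than 3 cells; both thresholds are parameters and each filter is
idempotent. Normalization is library-size scaling to 10,000 counts followed
by `log1p` (natural log), the default convention of the mainstream
single-cell toolkits; zeros stay exactly zero so sparsity is preserved.
Gene-level dispersion is defined as variance/mean of the log-normalized
values (sample variance, n−1), with 0 for constant genes — the quantity
plotted in mean–dispersion QC panels; since toolkits differ in their
dispersion definitions, this one is documented and parameterizable.
Pseudobulk sums raw counts per group and RPM rescales a profile to reads per
million, so a deep single-cell run can be compared rank-wise (Spearman)
with a bulk library.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum test between treated and control
cells, using the normal approximation with tie correction and continuity
correction. Exact enumeration is infeasible at hundreds of cells and ties
are pervasive because of dropout zeros, which is why the tie correction is
mandatory. Against a full-enumeration oracle over every tie-less rank
configuration with group sizes ≤ 6, the approximation is within 0.03
wherever the exact p ≤ 0.2 and within 0.04 everywhere; the residual
mid-range gap at n = 3–4 is a property of the chunky discrete null (the
continuity correction that causes it is also what keeps the tail accurate —
dropping it widens the worst case to ~0.19). At real group sizes (hundreds
of cells) the approximation error is negligible.

P-values are adjusted with Benjamini–Hochberg. The fold change is computed
on de-logged group means, `log2((expm1 mean_t + 1)/(expm1 mean_c + 1))`,
with pseudocount 1 — the convention of the standard toolkit, since rank
tests define no fold change of their own. The per-gene signature value is
the signed significance `−log10(padj) · sign(log2FC)` with the adjusted p
floored at 1e−300 to keep scores finite. Summary counts use `padj ≤ 0.01`
and strict `|log2FC| > 1`, applied symmetrically to both directions.

## Gene-set enrichment

The enrichment score is the weighted Kolmogorov–Smirnov running sum over
genes ranked by decreasing signature score (ties broken by gene ID for
determinism): hits climb by `|score|^weight` normalized over hits, misses
fall by `1/(N − |set|)`, and the ES is the extremum of largest magnitude
(positive wins a magnitude tie). The null is gene-level: random same-size
sets scored against the same signature. NES divides the observed ES by the
mean |null ES| of matching sign (the GSEA/fgsea convention), and the
permutation p counts null sets with `|ES_null| ≥ |ES|` with a plus-one
correction, so p is never 0 and is uniform under the null (verified by KS
over 200 independent runs).

Per-cell signatures are each cell's normalized expression centered against
the dataset mean — a cell identical to the average scores zero everywhere —
and each cell×set pair gets its own permutation NES; null distributions are
shared between sets of equal size within a cell to keep the cost at one
null per (cell, size). Centering is one of two defensible per-cell scoring
strategies (the other being the raw profile); it is the default because the
quantity of interest is deviation from the pooled population.

## Master-regulator analysis

A regulon is a TF with signed (`mor` ∈ [−1, 1]) and weighted
(`likelihood` ∈ (0, 1]) targets. Gene signed-significance scores are
rank-transformed to normal quantiles, `z = Φ⁻¹((rank − 0.5)/N)`, which is
order-preserving and immune to the p-floor; the regulon activity is the
likelihood-weighted Stouffer sum

    NES = Σ mor·lik·z / sqrt(Σ lik²),

standard normal under the null (empirical sd 1.00 over 2,000 null
replicates), giving an analytic two-sided p per TF, BH-adjusted across TFs.
This is a deliberate re-derivation of "cumulate each gene's contribution
into a TF-specific NES" rather than a numerical clone of the three-tailed
aREA statistic of the viper package; it is validated by planted-truth
recovery (three regulons repressed at log-effect 1 with 200 cells per group
are recovered in the top 5 by |NES| with the correct sign) and by null
calibration, not by identity with external software. TFs with fewer than 2
usable targets are skipped with a logged reason, never zero-filled.

Two networks are combined TF-by-TF with an equal-weight Stouffer consensus
`(NES_a + NES_b)/√2`; the per-cell projection applies the same statistic to
per-cell centered signatures, giving a cells × TFs activity matrix.

## Cell-cycle assignment

Binned-control scoring in the style introduced for tumor single-cell data:
genes are ranked by dataset-average expression into `n_bins = 24`
equal-occupancy bins; each marker gene draws `n_ctrl = 100` control genes
from its own bin; a cell's program score is the mean centered expression of
the markers minus that of the pooled controls. Working on centered
expression makes an exactly-average cell score 0. S and G2M have marker
programs; G1 is the default when neither score is positive, ties go to S
(documented, arbitrary). Default marker lists are the canonical S (43
genes) and G2M (54 genes) sets shipped as package data; on synthetic data
the planted program lists are used instead. The per-group phase table
reports counts and percentages to two decimals.

## Survival and evidence integration

Kaplan–Meier product-limit curves are computed per expression stratum
(quantile bins, quartiles by default — the stratum count in the published
figure is not stated, so it is a parameter). The univariate Cox
proportional-hazards model is fitted by Newton–Raphson on the Breslow
partial likelihood (the simplest consistent tie handling) with
step-halving, tolerance 1e−9 on β, max 50 iterations; the score residual at
convergence is < 1e−8 and the fit matches an established survival library
to 4 significant figures. The Wald z = β̂/se gives the survival p.

Evidence integration uses Fisher's method, `X² = −2 Σ ln p` against χ² with
2k df. Signed evidence is first converted to one-sided p in the "repressed
by treatment and poor prognosis with high expression" direction: `Φ(NES)`
for activity scores, `Φ(−z)` for Wald z. Missing sources are dropped per TF
with df shrinking to 2×(available); TFs with no sources are excluded with a
logged reason. TFs are ranked by integrated p, ties broken by ID.

## Synthetic data

The generator defines the study conditions for every test. Defaults
emulate the real experiment's design: two flasks of 1250 cells each,
18,000 genes, ~7% multiplet droplets, hashtag signal mean 200 vs background
2 (the published hashtag scatter is log-scale and unreadable in magnitude,
so the means are free parameters chosen to give three well-separated
clouds), log-normal expected library sizes (log-mean 9.2 ≈ 10k counts,
log-sd 0.35), log-normal relative gene abundances (log-sd 1.5), and
negative-binomial counts with shared inverse-dispersion 2 (variance
μ + μ²/2). Treatment effects are planted as log-scale shifts `mor × effect`
on the targets of chosen regulons in treated cells; per-cell expected
totals are renormalized so perturbations change composition, not depth.
Cell-cycle structure is two disjoint 50-gene programs (S, G2M) elevated by
log-effect 1 in cells of the matching phase, drawn from the
better-expressed half of the transcriptome (cycle genes are not rare
transcripts); phase fractions default to 25/50/25 in control and 48/36/16
in treated, mirroring the G1 arrest the drug induces. Multiplets are extra
droplets carrying one group's transcriptome but both hashtag signals
(transcriptome mixing is out of scope). A second, correlated network
(`resample_network`, 80% of edges kept) stands in for a regulon network
inferred from an independent patient cohort. Survival cohorts have
exponential event times with hazard `λ₀ exp(ln(HR)·expr)`, standard-normal
expression, and independent exponential censoring tuned to the requested
censoring fraction.

All randomness flows from the single config seed through one generator in a
fixed draw order (counts in fixed 256-cell blocks), so identical seeds give
bit-identical output.

What the simulation does *not* emulate: ambient RNA, batch effects, doublet
transcriptome mixing, gene–gene correlation beyond the planted programs,
UMI saturation, or realistic marker identities. Passing recovery tests
therefore demonstrates that the statistics detect the planted structure at
the stated effect sizes and sample sizes — not that they would behave
identically on real data with those complications.

## Problem sizes in tests and the acceptance script

Tests and the acceptance script run the pipeline at reduced scale — 200–250
cells per group and 1,000–2,000 genes, 20 regulons of 40 targets — which the
null-calibration and recovery suites show is sufficient for every claim
made; the published experiment's absolute numbers (cell counts, 2,708 DE
genes, specific TF identities) depend on the real sequencing run and
external cohorts and are exercised here only as arithmetic worked examples.

## Known limitations

- The MRA statistic approximates, by design, the published tool's aREA;
  absolute NES values are not comparable across the two.
- The Wilcoxon p is an asymptotic approximation; below ~5 cells per group
  with heavy ties it is qualitative only (the pipeline refuses < 3).
- Per-cell permutation enrichment is O(cells × set-sizes × permutations)
  and intended for subsets of cells; the analytic per-cell TF activity is
  the cheap alternative.
- Quantile stratification requires a non-constant covariate and breaks ties
  by first occurrence, so heavily tied expression yields uneven strata.
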