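# Methods

`spatialtme` implements the spatial inference chain used to study
tumor-microenvironment organization in imaging-based single-cell spatial
transcriptomics (CosMx-style data): colocalization quotients, niche
detection from k-nearest-neighbor composition, proximity-conditioned
differential expression, spatially range-gated ligand–receptor scoring,
per-FOV pseudobulk correlation, immune-infiltration stratification, and
survival association of niche abundance. A synthetic cohort generator
provides ground-truth data for every stage.

## Spatial model and units

All coordinates are micrometres. The field of view (FOV, default a
510 µm square) is the atomic spatial unit: neighbor graphs, proximity
predicates and permutations never cross FOV boundaries, because stage
coordinates across FOVs are generally not comparable. Each FOV belongs
to one tissue core, patient and region, with regions labelled T (tumor
core), B (invasive boundary) or N (adjacent normal parenchyma).

## Colocalization quotient (CLQ)

For an ordered type pair A→B within one FOV of N cells,

    CLQ_{A→B} = [ (1/N_A) Σ_{i∈A} n_{i,B}/k ] / [ N_B′ / (N−1) ]

with `n_{i,B}` the number of B cells among i's k nearest neighbors and
`N_B′ = N_B − 1` when A = B (a cell is excluded from its own
neighborhood — the standard self-pair convention). CLQ = 1 under random
labelling; the per-cell local quotients average exactly to the FOV
value, and FOV values are pooled by an A-cell-weighted mean. Default
k = 20 for CLQ (exposed as a flag); niche analysis uses its own k = 50.
Distance ties are broken by cell-table order, so graphs are
reproducible. Inference shuffles type labels within each FOV and uses
the two-sided statistic |CLQ − 1|, p = (1 + #exceedances)/(n_perm + 1).

## Niche detection

Each cell is represented by the type composition of its 50 nearest
neighbors (index cell excluded; rows sum to 1). K-means (Euclidean, 10
restarts, seeded) clusters these vectors; labels are renumbered by
decreasing cluster size for stability. K defaults to 9; `select_k`
reports inertia and mean silhouette over a K range and recommends the
silhouette maximum. Note that unclustered "background" tissue forms its
own composition mode, so on data with substantial background the
silhouette optimum is genuinely one above the number of planted niches;
the planted-K recovery statements in the tests therefore use
background-free constructions. Cells in FOVs smaller than k+1 keep
truncated neighborhoods and are flagged rather than dropped.

Enrichment of a niche for a grouping level (cell type or region) is
log2(observed fraction / marginal fraction), with zero observed
fractions replaced by the pseudo-fraction 1/(n_cells+1).

## Proximity conditioning and differential expression

A reference-type cell is *proximal* to a target type either when ≥1
target cell appears among its first k spatial neighbors (knn mode,
e.g. "within 50 spatial neighbors") or within a radius (radius mode,
default 80 µm for diffusible signaling, 30 µm for contact-dependent
pairs; the radii are conventions, configurable). Differential
expression between proximal and distal cells uses two-sided Wilcoxon
rank-sum tests per gene on the log-normalized view with
Benjamini–Hochberg FDR across tested genes; log2 fold changes are
ratios of group means with pseudocount 1e-9. Groups smaller than 20
cells are flagged.

Because the normalized view is compositional (per-cell totals are
rescaled), a strong planted program in one group shifts *every* gene's
relative share; at large n the rank test can detect that dilution. The
generator therefore applies the coupling boost before rescaling totals
to the target, keeping expected totals equal across groups, and the
default planted program is lowly expressed (~1.5% of cell totals), which
keeps the dilution below the detection floor at the tested group sizes.
This is a genuine caveat for real data too: rank-based DE on
total-count-normalized values conflates a gene's change with changes in
the rest of the cell's transcriptome.

## Ligand–receptor scoring

For a ligand/receptor pair with sender and receiver types, eligible
receivers are receiver cells with ≥1 sender within the interaction
range; eligible senders are senders within range of ≥1 eligible
receiver. With L̄ and R̄ the 10%-trimmed means of normalized ligand
(eligible senders) and receptor (eligible receivers),

    score = L̄·R̄ / (Kh + L̄·R̄),   Kh = 0.5 by default,

a Hill-type mass-action statistic bounded in [0, 1), zero exactly when
either side is silent, 0.5 at half-saturation, and monotone in every
count. This is a deliberate simplification of communication-probability
frameworks: no curated pair database, no pathway aggregation — the
spatial gating is the point. FOVs without eligible pairs are null.
Significance comes from within-FOV label permutation (one-sided).

## Pseudobulk, correlations, signatures

`fov_pseudobulk` averages normalized expression of one cell type per
FOV (≥5 cells of the type, else null). `fov_correlation` is Pearson
(default) or Spearman with pairwise deletion. `signature_score`
averages z-scored member genes per unit. `correlated_genes` returns
genes with Pearson r > 0.4 and p < 0.05 against an anchor gene
(defaults mirror the TCGA-style screen; constant genes fail the filter).

## Outcomes

FOVs are stratified by immune fraction (default immune lineages: T/NK,
B/Plasma, Myeloid) with a median split, ties to low. Survival uses the
Kaplan–Meier product-limit estimator and the two-group log-rank test
(via lifelines), after median dichotomization of a per-patient
covariate. No Cox regression or covariate adjustment is provided, by
design.

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
dataset:

- **Geometry.** 8 patients × (2 T + 1 B + 1 N) FOVs, 510 µm squares,
  ~900 cells per FOV — cell totals near the reported per-cell medians
  (~800 transcripts) with NB dispersion 2.
- **Cell types.** Nine working types (the major liver lineages with the
  CAF compartment split into mCAF/iCAF and endothelium as
  capillary/LSEC). Region-specific background proportions plant the
  observed compositional shifts (mCAF share higher in T/B, iCAF higher
  in N; no malignant cells in N).
- **Niches.** Nine Matérn-style planted niches (uniform centers with
  soft inhibition — centers rejected within 2(r_i + r_j) of one another
  — Gaussian member offsets, radius 30 µm, 80 cells per cluster),
  several restricted to specific regions (e.g. a capillary–CAF niche in
  T/B only, an immune niche in N, a T-cell/myeloid niche at B). Member
  cells carry their planted niche label; background cells are labelled
  "background". Recovery metrics (ARI) are computed on member cells,
  since background has no ground-truth niche.
- **Expression.** Type-specific NB signature means (12 vs baseline 2 on
  a 160-gene panel with realistically named markers); DLL4 silent
  outside capillaries. The DLL4→NOTCH3 coupling doubles a six-gene
  NOTCH-response program in mCAFs within 30 µm of a capillary; means
  are then rescaled so expected totals hit the target.
- **Survival.** Exponential event times with hazard
  `h0·exp(β·abundance)` (h0 = 0.02/month, β = log 2.5), abundance being
  each patient's target-niche cell fraction; the planted target-niche
  load rises linearly across patients so the association is
  identifiable. Censoring: an independent Bernoulli flag per patient
  (default rate 0.2) with the censored observation time uniform before
  the event, plus administrative censoring at 120 months. This gives an
  exact censoring fraction; it is group-symmetric, so null (β = 0)
  log-rank p-values remain uniform. The power study (HR 2.5, n = 60)
  uses administrative censoring only; at these conditions the true
  power of the two-sided log-rank test is ≈0.93.

What the generator does **not** emulate: segmentation error and
transcript spillover between adjacent cells, spatially varying cell
density beyond the planted clusters, batch/platform effects, realistic
gene–gene correlation structure, and protein-panel (GeoMx) data.
Passing tests therefore demonstrate the correctness and calibration of
the inference chain under its stated assumptions, not robustness to
those artifacts.

## Numerical choices

- Normalization: per-cell scaling to 500 counts then log1p (zeros stay
  zero, view kept sparse). A variance-stabilizing replacement for
  residual-based pipelines; all DE/correlation/LR operations consume it.
- QC: cells with fewer than 20 transcripts are removed (a platform
  convention; the threshold is echoed in the QC report).
- kNN ties broken by table order; generator jitters exact coordinate
  collisions by ≤1e-6 µm (reflected at FOV borders).
- Permutation p-values use the add-one estimator, bounded below by
  1/(n_perm+1).
- Per-stage pipeline seeds are sha256(global_seed, stage name) mod 2^31,
  so toggling one stage never shifts another's randomness.
- Degenerate inputs raise named errors rather than returning silently:
  empty matrices, all-cells-removed QC, zero-total cells at
  normalization, constant dichotomization covariates, no-event log-rank.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the chain at desk scale:
200 CSR FOVs of 2,000 cells for CLQ null calibration (k = 20), 50
random instances (N ≤ 300) against the O(N²) brute-force CLQ oracle,
the default ~29,000-cell cohort for niche recovery (9 niches, 50-NN),
~500 cells per proximity group × 3 replicates for DE calibration
(1,000-gene panel), 60 FOVs × 100 replicates for pseudobulk correlation
recovery (planted r = 0.8), and 100 simulated 60-patient cohorts for
log-rank power. These sizes were chosen so each property is measured
with useful precision while the whole suite runs in a couple of minutes.
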