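# spatialtme

Spatial tumor-microenvironment analysis for imaging-based single-cell
spatial transcriptomics (CosMx-style panels), built around the question
of how stromal organization — in particular capillary–fibroblast
crosstalk — shapes immune exclusion in solid tumors such as
hepatocellular carcinoma. The package is aimed at computational
biologists who have per-cell coordinates, cell-type labels and a sparse
count matrix organized in fields of view (FOVs), and who want calibrated
spatial statistics rather than plotting wrappers.

## What it computes

- **Colocalization quotient (CLQ).** For an ordered type pair A→B,
  `CLQ_{A→B} = [(1/N_A) Σ_{i∈A} n_{i,B}/k] / [N_B′/(N−1)]`, the ratio of
  the observed fraction of B among A's k nearest neighbors to the
  random-labelling expectation (CLQ = 1 under no association), per FOV
  and pooled, with within-FOV permutation inference.
- **Spatial niches.** Each cell's 50-nearest-neighbor type composition,
  clustered by k-means into K niches (default 9), with
  log2(observed/expected) enrichment of niches for cell types and tissue
  regions (tumor / boundary / normal) and per-patient niche abundance.
- **Proximity-conditioned differential expression.** Wilcoxon rank-sum
  tests (Benjamini–Hochberg FDR) between reference cells with and
  without a target type nearby — "within k spatial neighbors" or within
  a radius (80 µm default).
- **Range-gated ligand–receptor scoring.** A Hill-type score
  `L̄R̄/(Kh + L̄R̄)` over spatially eligible sender/receiver cells only
  (e.g. DLL4 on capillaries → NOTCH3 on matrix CAFs within 80 µm), with
  permutation p-values.
- **Pseudobulk correlation and gene screens.** Per-FOV mean expression
  within a type, Pearson/Spearman correlation across FOVs, signature
  scoring, and anchored correlation screens (r > 0.4, p < 0.05).
- **Outcomes.** FOV stratification by immune infiltration,
  infiltration-associated DE, and Kaplan–Meier / log-rank survival
  analysis of dichotomized niche or gene abundance.
- **Synthetic cohorts.** A generator that plants all of the above —
  niches, regional composition shifts, a ligand→receptor spatial
  coupling, survival linked to niche abundance — with full ground truth,
  so every stage is testable without external data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
from spatialtme import synthgen, spatial_io, coloc, niche, crosstalk, outcomes

# a 60-patient synthetic cohort (4 FOVs per patient across T/B/N regions)
ds = synthgen.generate_cohort(synthgen.default_config(seed=7, n_patients=60))
cells, matrix, qc = spatial_io.qc_filter_cells(ds.cells, ds.matrix, 20)
matrix = spatial_io.normalize(matrix)

# colocalization of matrix CAFs with capillaries
graph = coloc.build_knn(cells, k=20)
clq = coloc.clq_pair(graph, cells["cell_type"].to_numpy(), "mCAF", "Capillary")

# 50-NN composition niches
g50 = coloc.build_knn(cells, k=50)
comp = niche.neighborhood_composition(g50, cells["cell_type"].to_numpy())
assign = niche.cluster_niches(comp, n_niches=9, seed=0)
enr = niche.niche_enrichment(assign, cells["cell_type"].to_numpy())

# expression of mCAFs near vs far from capillaries, and DLL4->NOTCH3 scoring
flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                  mode="radius", threshold=80.0)
de = crosstalk.proximity_de(matrix, flags)
lr = crosstalk.lr_score(matrix, cells, "DLL4", "NOTCH3",
                        "Capillary", "mCAF", range_um=80.0)

# survival vs abundance of the mCAF/cholangiocyte niche
ab = niche.niche_abundance(assign, cells, level="patient")
target = enr["Cholangiocyte"].idxmax()
merged, logrank = outcomes.km_by_group(ds.survival, ab[target])
```

Output (printed by the snippet above with a few f-strings):

```
cells: 215566, genes: 160, median transcripts/cell: 797
CLQ mCAF->Capillary pooled over 240 FOVs: 1.15
niche -> most enriched type: {1: 'iCAF', 2: 'Malignant', 3: 'Hepatocyte',
  4: 'Myeloid', 5: 'Cholangiocyte', 6: 'Capillary', 7: 'T/NK',
  8: 'Malignant', 9: 'B/Plasma'}
proximal mCAFs: 23341/24217
  gene   log2fc            q
NOTCH3 0.179899 7.867173e-39
  HES1 0.338424 7.419412e-32
  APLN 0.337758 2.095555e-31
DLL4->NOTCH3 LR score (80 um): 0.939 (L=2.61, R=2.97)
mCAF/cholangiocyte niche (5): median OS high=10.3 vs low=27.9 months,
  log-rank chi2=9.80, p=0.0017
```

Reading this: mCAFs sit among capillaries 15% more often than chance
(CLQ 1.15); the nine recovered niches match the planted taxonomy; mCAFs
within 80 µm of a capillary up-regulate the planted NOTCH-response
program (NOTCH3, HES1, APLN top the q-value ranking); the range-gated
DLL4→NOTCH3 score is high; and patients whose tissue is rich in the
mCAF/cholangiocyte niche die sooner — exactly the structure the
generator planted.

## Command line

Every stage is also a subcommand of the `spatialtme` CLI:

```bash
spatialtme simulate --out data/ --seed 7
spatialtme qc --dataset data/ --min-transcripts 20 --out qc/
spatialtme clq --dataset data/ --ref Malignant --k 20 --out clq.tsv
spatialtme niche --dataset data/ --k-neighbors 50 --n-niches 9 --seed 0 --out niches/
spatialtme crosstalk --dataset data/ --ref mCAF --target Capillary \
    --mode radius --threshold 80 --ligand DLL4 --receptor NOTCH3 --out ct/
spatialtme outcomes --dataset data/ --niches niches/niches.tsv --out out/
spatialtme run-all --config run.yaml
```

Datasets on disk are plain text: `cells.tsv` (cell_id, x_um, y_um,
fov_id, core_id, patient_id, region, cell_type), `matrix.mtx`
(MatrixMarket, genes × cells), `genes.tsv`, `barcodes.tsv`, and
optionally `survival.tsv` (patient_id, time_months, event).

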