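"""Spatial niche detection from k-nearest-neighbor composition vectors.

Each cell is summarized by the cell-type composition of its k nearest
neighbors (default k = 50, index cell excluded); k-means over these
composition vectors defines recurrent local tissue states ("niches").
Enrichment of niches for cell types or tissue regions is reported as
log2 observed/expected fractions, and per-patient (or per-region /
per-FOV) niche abundance feeds the survival analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .coloc import NeighborGraph


@dataclass
class CompositionMatrix:
    """Per-cell neighbor composition: rows sum to 1, columns = cell types."""

    values: np.ndarray
    types: np.ndarray
    truncated: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.types)


@dataclass
class NicheAssignment:
    labels: np.ndarray
    n_niches: int
    centroids: np.ndarray
    types: np.ndarray
    inertia: float


def neighborhood_composition(
    graph: NeighborGraph, cell_types: np.ndarray | pd.Series
) -> CompositionMatrix:
    """Fraction of each cell type among every cell's k nearest neighbors.

    Cells in FOVs smaller than k+1 use all available neighbors and are
    flagged as truncated rather than dropped.
    """
    cell_types = np.asarray(cell_types)
    types = np.array(sorted(pd.unique(cell_types)), dtype=object)
    type_code = {t: i for i, t in enumerate(types)}
    codes = np.array([type_code[t] for t in cell_types], dtype=np.int64)
    n = graph.n_cells
    comp = np.zeros((n, len(types)))
    valid = graph.indices >= 0
    safe = np.where(valid, graph.indices, 0)
    nbr_codes = codes[safe]
    for j in range(len(types)):
        comp[:, j] = ((nbr_codes == j) & valid).sum(axis=1)
    denom = graph.n_neighbors.astype(float)
    zero = denom == 0
    if zero.any():
        # single-cell FOVs: no neighborhood; fall back to own type so the
        # row still sums to 1, flagged via truncated
        comp[zero, :] = 0.0
        comp[zero, codes[zero]] = 1.0
        denom[zero] = 1.0
    comp /= denom[:, None]
    truncated = graph.truncated | zero
    return CompositionMatrix(values=comp, types=types, truncated=truncated)


def cluster_niches(
    composition: CompositionMatrix,
    n_niches: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> NicheAssignment:
    """K-means over composition vectors; niches renumbered by size.

    Labels are 1..K with niche 1 the largest, so numbering is stable
    across runs with the same seed regardless of k-means' internal
    ordering.
    """
    if n_niches < 2:
        raise ValueError("n_niches must be >= 2")
    x = composition.values
    if n_niches > x.shape[0]:
        raise ValueError(f"n_niches={n_niches} exceeds {x.shape[0]} cells")
    km = KMeans(n_clusters=n_niches, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    sizes = np.bincount(raw, minlength=n_niches)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(n_niches, dtype=np.int64)
    remap[order] = np.arange(1, n_niches + 1)
    return NicheAssignment(
        labels=remap[raw],
        n_niches=n_niches,
        centroids=km.cluster_centers_[order],
        types=composition.types,
        inertia=float(km.inertia_),
    )


def select_k(
    composition: CompositionMatrix,
    k_range: range | list[int],
    seed: int = 0,
    n_init: int = 10,
    max_silhouette_cells: int = 5000,
) -> pd.DataFrame:
    """Inertia elbow and mean silhouette per candidate niche count.

    Returns one row per K with a ``recommended`` flag on the silhouette
    maximum. Silhouette is computed on a deterministic subsample when the
    cohort exceeds ``max_silhouette_cells`` cells.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if min(ks) < 2:
        raise ValueError("candidate K must be >= 2")
    x = composition.values
    rng = np.random.default_rng(seed)
    if x.shape[0] > max_silhouette_cells:
        sub = rng.choice(x.shape[0], size=max_silhouette_cells, replace=False)
    else:
        sub = np.arange(x.shape[0])
    rows = []
    for k in ks:
        assign = cluster_niches(composition, n_niches=k, seed=seed, n_init=n_init)
        sil = silhouette_score(x[sub], assign.labels[sub]) if len(set(
            assign.labels[sub])) > 1 else np.nan
        rows.append({"K": k, "inertia": assign.inertia, "silhouette": sil})
    out = pd.DataFrame(rows)
    out["recommended"] = out["silhouette"] == out["silhouette"].max()
    return out


def niche_enrichment(
    assignment: NicheAssignment,
    grouping: np.ndarray | pd.Series,
    zscore_rows: bool = False,
) -> pd.DataFrame:
    """log2 observed/expected fraction of each grouping level per niche.

    ``grouping`` is any per-cell categorical (cell type for composition
    heatmaps, region for tissue-context heatmaps). Zero observed
    fractions are replaced by the pseudo-fraction 1/(n_cells+1) so the
    log is finite. Empty niches produce a row of NaN.
    """
    grouping = np.asarray(grouping)
    if grouping.shape[0] != assignment.labels.shape[0]:
        raise ValueError("grouping length differs from assignment")
    levels = np.array(sorted(pd.unique(grouping)), dtype=object)
    n_cells = grouping.shape[0]
    pseudo = 1.0 / (n_cells + 1)
    marginal = np.array([(grouping == g).mean() for g in levels])
    rows = []
    for niche in range(1, assignment.n_niches + 1):
        mask = assignment.labels == niche
        if not mask.any():
            rows.append([np.nan] * len(levels))
            continue
        obs = np.array([(grouping[mask] == g).mean() for g in levels])
        obs = np.maximum(obs, pseudo)
        rows.append(np.log2(obs / marginal))
    out = pd.DataFrame(
        rows, index=pd.Index(range(1, assignment.n_niches + 1), name="niche"),
        columns=levels,
    )
    if zscore_rows:
        vals = out.to_numpy()
        mu = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out = pd.DataFrame((vals - mu) / sd, index=out.index, columns=out.columns)
    return out


def niche_abundance(
    assignment: NicheAssignment,
    cells: pd.DataFrame,
    level: str = "patient",
) -> pd.DataFrame:
    """Fraction of cells in each niche per patient, region, or FOV.

    Rows (grouping units) sum to 1 over niches.
    """
    key = {"patient": "patient_id", "region": "region", "fov": "fov_id"}.get(level)
    if key is None:
        raise ValueError("level must be one of {'patient', 'region', 'fov'}")
    df = pd.DataFrame({key: cells[key].to_numpy(), "niche": assignment.labels})
    counts = df.groupby([key, "niche"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=range(1, assignment.n_niches + 1), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
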