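"""Spatial colocalization of cell-type pairs via the colocalization quotient.

The colocalization quotient (CLQ) of an ordered type pair (A -> B)
compares the observed fraction of B cells among the k nearest neighbors
of A cells with the fraction expected under random labeling:

    CLQ_{A->B} = [ (1/N_A) * sum_{i in A} n_{i,B} / k ] / [ N_B' / (N - 1) ]

where ``n_{i,B}`` counts B cells among cell i's k nearest neighbors,
``N`` is the number of cells in the field of view (FOV), and
``N_B' = N_B - 1`` when A = B (the index cell cannot be its own
neighbor) and ``N_B`` otherwise. CLQ = 1 means no spatial association;
values above 1 mean A cells see B cells among their neighbors more
often than chance.

All neighbor computations are strictly per-FOV: cells never have
neighbors across FOV boundaries. Inference is by random relabeling of
cells within each FOV (coordinates fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class NeighborGraph:
    """Per-FOV exact k-nearest-neighbor lists for every cell.

    ``indices``/``distances`` are (n_cells, k) arrays aligned with the
    cell table row order; rows of FOVs with fewer than k+1 cells are
    padded with -1 / inf and flagged in ``truncated``. FOVs with a
    single cell have no neighbors and are listed in ``excluded_fovs``.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray
    n_neighbors: np.ndarray
    fov_ids: np.ndarray
    truncated: np.ndarray
    excluded_fovs: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


def build_knn(cells: pd.DataFrame, k: int) -> NeighborGraph:
    """Exact Euclidean kNN within each FOV, self excluded.

    Ties in distance are broken deterministically by cell table row
    order, so rebuilding the graph on the same table always yields the
    same neighbor lists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cells)
    coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    fov = cells["fov_id"].to_numpy()
    indices = np.full((n, k), -1, dtype=np.int64)
    distances = np.full((n, k), np.inf)
    n_neighbors = np.zeros(n, dtype=np.int64)
    truncated = np.zeros(n, dtype=bool)
    excluded = []
    for fov_id, idx in pd.Series(np.arange(n)).groupby(fov).groups.items():
        idx = np.asarray(idx)
        m = idx.size
        if m < 2:
            excluded.append(fov_id)
            continue
        k_eff = min(k, m - 1)
        tree = cKDTree(coords[idx])
        dist, nbr = tree.query(coords[idx], k=k_eff + 1)
        # drop self (distance 0 to itself; under exact coordinate ties the
        # self index may not come first, so remove it explicitly)
        for r in range(m):
            row_nbr, row_dist = nbr[r], dist[r]
            keep = row_nbr != r
            row_nbr, row_dist = row_nbr[keep][:k_eff], row_dist[keep][:k_eff]
            order = np.lexsort((idx[row_nbr], row_dist))
            indices[idx[r], :k_eff] = idx[row_nbr[order]]
            distances[idx[r], :k_eff] = row_dist[order]
        n_neighbors[idx] = k_eff
        if k_eff < k:
            truncated[idx] = True
    return NeighborGraph(
        k=k,
        indices=indices,
        distances=distances,
        n_neighbors=n_neighbors,
        fov_ids=fov,
        truncated=truncated,
        excluded_fovs=excluded,
    )


@dataclass
class CLQResult:
    a: str
    b: str
    per_fov: pd.DataFrame
    pooled: float
    local: pd.Series
    n_null_fovs: int
    p_value: float | None = None


def _fov_clq(
    nbr_labels: np.ndarray,
    n_nbr: np.ndarray,
    labels: np.ndarray,
    a: str,
    b: str,
) -> tuple[float, np.ndarray, int, int]:
    """CLQ for one FOV given the (m, k) neighbor-label matrix.

    Returns (clq, local values for A cells, N_A, N_B). NaN when the
    quotient is undefined (no A cells, or no available B neighbors).
    """
    n = labels.shape[0]
    is_a = labels == a
    n_a = int(is_a.sum())
    n_b = int((labels == b).sum())
    n_b_adj = n_b - 1 if a == b else n_b
    if n_a == 0 or n_b_adj <= 0 or n < 2:
        return np.nan, np.empty(0), n_a, n_b
    rows = np.flatnonzero(is_a)
    nb = (nbr_labels[rows] == b).sum(axis=1)
    frac = nb / n_nbr[rows]
    expected = n_b_adj / (n - 1)
    local = frac / expected
    return float(local.mean()), local, n_a, n_b


def _neighbor_label_matrix(
    graph: NeighborGraph, labels: np.ndarray, rows: np.ndarray
) -> np.ndarray:
    idx = graph.indices[rows]
    safe = np.where(idx >= 0, idx, 0)
    out = labels[safe].astype(object)
    out[idx < 0] = None
    return out


def clq_pair(
    graph: NeighborGraph,
    labels: np.ndarray | pd.Series,
    a: str,
    b: str,
) -> CLQResult:
    """CLQ of A -> B per FOV, pooled over FOVs, with per-A-cell local values.

    Pooling is the A-cell-weighted mean of per-FOV CLQ values; FOVs where
    the quotient is undefined are excluded from pooling and counted.
    """
    labels = np.asarray(labels)
    vocab = set(labels)
    for t in (a, b):
        if t not in vocab:
            raise ValueError(f"cell type {t!r} absent from label vector")
    fovs = pd.unique(graph.fov_ids)
    rows_out, locals_idx, locals_val = [], [], []
    for fov_id in fovs:
        rows = np.flatnonzero(graph.fov_ids == fov_id)
        if graph.n_neighbors[rows].max(initial=0) == 0:
            continue
        nbr_labels = _neighbor_label_matrix(graph, labels, rows)
        clq, local, n_a, n_b = _fov_clq(
            nbr_labels, graph.n_neighbors[rows], labels[rows], a, b
        )
        rows_out.append((fov_id, clq, n_a, n_b, rows.size))
        if local.size:
            locals_idx.extend(rows[labels[rows] == a].tolist())
            locals_val.extend(local.tolist())
    per_fov = pd.DataFrame(rows_out, columns=["fov_id", "clq", "n_A", "n_B", "N"])
    ok = per_fov["clq"].notna()
    n_null = int((~ok).sum())
    if ok.any():
        w = per_fov.loc[ok, "n_A"].to_numpy(dtype=float)
        pooled = float(np.average(per_fov.loc[ok, "clq"], weights=w))
    else:
        pooled = np.nan
    local_series = pd.Series(locals_val, index=locals_idx, name="local_clq")
    return CLQResult(a=a, b=b, per_fov=per_fov, pooled=pooled,
                     local=local_series, n_null_fovs=n_null)


def clq_density(
    cells: pd.DataFrame,
    graph: NeighborGraph,
    labels: np.ndarray | pd.Series,
    reference_type: str,
) -> pd.DataFrame:
    """Long table of per-FOV CLQ of the reference type vs every other type.

    One row per (FOV, other type); undefined quotients are dropped and
    counted in the ``n_null`` attribute of the returned frame.
    """
    labels = np.asarray(labels)
    if reference_type not in set(labels):
        raise ValueError(f"reference type {reference_type!r} absent")
    others = [t for t in pd.unique(labels) if t != reference_type]
    frames = []
    n_null = 0
    for other in sorted(others):
        res = clq_pair(graph, labels, reference_type, other)
        tab = res.per_fov[["fov_id", "clq"]].copy()
        tab.insert(1, "other_type", other)
        n_null += res.n_null_fovs
        frames.append(tab.dropna(subset=["clq"]))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_null"] = n_null
    out.attrs["reference_type"] = reference_type
    return out


def clq_permutation(
    graph: NeighborGraph,
    labels: np.ndarray | pd.Series,
    a: str,
    b: str,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation p-value for CLQ(A -> B) departing from 1.

    Cell-type labels are shuffled within each FOV (coordinates, hence the
    neighbor graph, stay fixed); the statistic is |pooled CLQ - 1| and
    p = (1 + #{|CLQ* - 1| >= |CLQ - 1|}) / (n_perm + 1).

    Returns (observed pooled CLQ, p-value).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(labels)
    if len(pd.unique(labels)) < 2:
        raise ValueError("label vector is degenerate (single cell type)")
    rng = np.random.default_rng(seed)
    observed = clq_pair(graph, labels, a, b).pooled
    fov_groups = [
        np.flatnonzero(graph.fov_ids == f) for f in pd.unique(graph.fov_ids)
    ]
    stat_obs = abs(observed - 1.0)
    exceed = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        for rows in fov_groups:
            perm_labels[rows] = labels[rows][rng.permutation(rows.size)]
        clq_star = clq_pair(graph, perm_labels, a, b).pooled
        if abs(clq_star - 1.0) >= stat_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, p


def clq_pair_bruteforce(
    cells: pd.DataFrame, labels: np.ndarray, a: str, b: str, k: int
) -> float:
    """O(N^2) reference CLQ: all-pairs distances, direct formula.

    Independent of the tree-based path; intended as a cross-check on
    small inputs.
    """
    labels = np.asarray(labels)
    vals, weights = [], []
    for fov_id, sub in cells.groupby("fov_id", sort=False):
        rows = sub.index.to_numpy()
        coords = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        lab = labels[rows]
        n = rows.size
        if n < 2:
            continue
        k_eff = min(k, n - 1)
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        n_b = int((lab == b).sum())
        n_b_adj = n_b - 1 if a == b else n_b
        arows = np.flatnonzero(lab == a)
        if arows.size == 0 or n_b_adj <= 0:
            continue
        fracs = []
        for i in arows:
            order = np.lexsort((np.arange(n), d[i]))[:k_eff]
            fracs.append((lab[order] == b).sum() / k_eff)
        vals.append(np.mean(fracs) / (n_b_adj / (n - 1)))
        weights.append(arows.size)
    if not vals:
        return np.nan
    return float(np.average(vals, weights=weights))
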