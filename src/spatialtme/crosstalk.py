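"""Proximity-conditioned expression and range-gated ligand-receptor scoring.

Two proximity predicates are supported for a reference/target type pair,
both evaluated strictly within each FOV:

* ``knn`` — a reference cell is proximal iff at least one target cell
  appears among its ``threshold`` nearest neighbors (e.g. "within 50
  spatial neighbors").
* ``radius`` — proximal iff at least one target cell lies within
  ``threshold`` micrometres (e.g. within 80 um of a capillary).

Differential expression between proximal and distal reference cells uses
two-sided Wilcoxon rank-sum tests on the log-normalized view with
Benjamini-Hochberg FDR control across genes.

Ligand-receptor activity between a sender and a receiver type is scored
with a Hill-type mass-action statistic restricted to spatially eligible
cells: receivers with at least one sender within the interaction range,
and senders within range of at least one such receiver,

    score = (L * R) / (Kh + L * R),   L, R = 10%-trimmed means,

bounded in [0, 1) and zero exactly when either side is silent. Default
ranges: 30 um for contact-dependent pairs, 80 um for diffusible ligands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .coloc import NeighborGraph
from .spatial_io import ExpressionMatrix

CONTACT_RANGE_UM = 30.0
DIFFUSIBLE_RANGE_UM = 80.0


@dataclass
class ProximityFlags:
    ref_type: str
    target_type: str
    mode: str
    threshold: float
    cell_rows: np.ndarray  # row indices of ref_type cells in the cell table
    proximal: np.ndarray   # boolean, aligned with cell_rows


def proximity_flags(
    cells: pd.DataFrame,
    ref_type: str,
    target_type: str,
    mode: str = "radius",
    threshold: float = DIFFUSIBLE_RANGE_UM,
    graph: NeighborGraph | None = None,
) -> ProximityFlags:
    """Flag each reference-type cell as proximal/distal to the target type."""
    types = cells["cell_type"].to_numpy()
    if ref_type not in set(types):
        raise ValueError(f"reference type {ref_type!r} absent from cell table")
    ref_rows = np.flatnonzero(types == ref_type)
    proximal = np.zeros(ref_rows.size, dtype=bool)
    if mode == "knn":
        if graph is None:
            raise ValueError("knn mode requires a neighbor graph")
        k = int(threshold)
        if graph.k < k:
            raise ValueError(f"graph built with k={graph.k} < threshold {k}")
        idx = graph.indices[ref_rows, :k]
        safe = np.where(idx >= 0, idx, 0)
        is_target = (types[safe] == target_type) & (idx >= 0)
        proximal = is_target.any(axis=1)
    elif mode == "radius":
        coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        fov = cells["fov_id"].to_numpy()
        for fov_id in pd.unique(fov[ref_rows]):
            in_fov_ref = ref_rows[fov[ref_rows] == fov_id]
            tgt = np.flatnonzero((fov == fov_id) & (types == target_type))
            if tgt.size == 0:
                continue
            tree = cKDTree(coords[tgt])
            hits = tree.query_ball_point(coords[in_fov_ref], r=threshold)
            if ref_type == target_type:
                flag = np.array(
                    [any(tgt[j] != i for j in h) for i, h in zip(in_fov_ref, hits)]
                )
            else:
                flag = np.array([len(h) > 0 for h in hits])
            proximal[np.searchsorted(ref_rows, in_fov_ref)] = flag
    else:
        raise ValueError("mode must be 'knn' or 'radius'")
    return ProximityFlags(
        ref_type=ref_type, target_type=target_type, mode=mode,
        threshold=float(threshold), cell_rows=ref_rows, proximal=proximal,
    )


def _wilcoxon_de(
    matrix: ExpressionMatrix,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    gene_subset: Sequence[str] | None,
    label_a: str,
    label_b: str,
    min_group: int = 20,
) -> pd.DataFrame:
    """Shared Wilcoxon + BH engine for the proximity and infiltration DE."""
    if rows_a.size < 2 or rows_b.size < 2:
        raise ValueError(
            f"need >= 2 cells per group; got {label_a}={rows_a.size}, "
            f"{label_b}={rows_b.size}"
        )
    genes = list(gene_subset) if gene_subset is not None else list(matrix.genes)
    dense = matrix.normalized_dense(genes)
    xa, xb = dense[:, rows_a], dense[:, rows_b]
    res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided",
                             method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant genes: identical in both groups, no evidence either way
    constant = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0) & (
        xa.mean(axis=1) == xb.mean(axis=1)
    )
    pvals[constant] = 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": genes,
            f"mean_{label_a}": mean_a,
            f"mean_{label_b}": mean_b,
            "log2fc": np.log2((mean_a + 1e-9) / (mean_b + 1e-9)),
            "statistic": np.asarray(res.statistic, dtype=float),
            "p": pvals,
            "q": qvals,
        }
    )
    out.attrs["n_" + label_a] = int(rows_a.size)
    out.attrs["n_" + label_b] = int(rows_b.size)
    out.attrs["small_groups"] = bool(min(rows_a.size, rows_b.size) < min_group)
    return out


def proximity_de(
    matrix: ExpressionMatrix,
    flags: ProximityFlags,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between proximal and distal reference cells.

    Log2 fold change is proximal over distal on the normalized scale
    (pseudo 1e-9); q is the BH-adjusted p across the tested genes.
    """
    rows_prox = flags.cell_rows[flags.proximal]
    rows_dist = flags.cell_rows[~flags.proximal]
    if rows_prox.size == 0 or rows_dist.size == 0:
        raise ValueError(
            f"one group empty: proximal={rows_prox.size}, distal={rows_dist.size}"
        )
    return _wilcoxon_de(matrix, rows_prox, rows_dist, gene_subset,
                        "proximal", "distal")


def proximal_fraction(
    cells: pd.DataFrame, flags: ProximityFlags
) -> pd.DataFrame:
    """Per-region proportion of reference cells proximal to the target.

    Adds pairwise two-proportion z-tests between regions; regions with no
    reference cells get a NaN row.
    """
    region = cells["region"].to_numpy()[flags.cell_rows]
    rows = []
    for reg in ("T", "B", "N"):
        mask = region == reg
        n = int(mask.sum())
        rows.append(
            {
                "region": reg,
                "n_ref": n,
                "n_proximal": int(flags.proximal[mask].sum()),
                "fraction": flags.proximal[mask].mean() if n else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    pairs = {}
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            a, b = out.iloc[i], out.iloc[j]
            if a["n_ref"] == 0 or b["n_ref"] == 0:
                p = np.nan
            else:
                counts = np.array([a["n_proximal"], b["n_proximal"]])
                nobs = np.array([a["n_ref"], b["n_ref"]])
                if counts.sum() in (0, nobs.sum()):
                    p = 1.0  # all-proximal or all-distal everywhere
                else:
                    p = proportions_ztest(counts, nobs)[1]
            pairs[f"{a['region']}_vs_{b['region']}"] = float(p)
    out.attrs["pairwise_p"] = pairs
    return out


class LRScore(NamedTuple):
    ligand: str
    receptor: str
    sender: str
    receiver: str
    per_fov: pd.DataFrame
    pooled_score: float
    pooled_L: float
    pooled_R: float
    n_eligible_receivers: int


def _trimmed_mean(x: np.ndarray) -> float:
    if x.size == 0:
        return np.nan
    return float(stats.trim_mean(x, 0.1))


def _eligible_sets(
    coords: np.ndarray,
    sender_rows: np.ndarray,
    receiver_rows: np.ndarray,
    range_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Receivers with a sender in range; senders in range of such a receiver."""
    if sender_rows.size == 0 or receiver_rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s_tree = cKDTree(coords[sender_rows])
    hits = s_tree.query_ball_point(coords[receiver_rows], r=range_um)
    recv_ok = np.array([len(h) > 0 for h in hits])
    elig_recv = receiver_rows[recv_ok]
    sender_hit = np.zeros(sender_rows.size, dtype=bool)
    for h, ok in zip(hits, recv_ok):
        if ok:
            sender_hit[h] = True
    return sender_rows[sender_hit], elig_recv


def lr_score(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    range_um: float = DIFFUSIBLE_RANGE_UM,
    kh: float = 0.5,
) -> LRScore:
    """Range-gated Hill-type ligand-receptor score per FOV and pooled.

    FOVs with no eligible sender-receiver pair are scored null and
    excluded from pooling; the pooled score uses eligible cells pooled
    across FOVs.
    """
    if range_um <= 0:
        raise ValueError("range_um must be positive")
    if kh <= 0:
        raise ValueError("Kh must be positive")
    gi_l, gi_r = matrix.gene_index(ligand), matrix.gene_index(receptor)
    if matrix.normalized is None:
        raise ValueError("matrix has no normalized view; call normalize() first")
    lig = np.asarray(matrix.normalized[gi_l].todense()).ravel()
    rec = np.asarray(matrix.normalized[gi_r].todense()).ravel()
    coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    types = cells["cell_type"].to_numpy()
    fov = cells["fov_id"].to_numpy()
    per_fov_rows = []
    all_s, all_r = [], []
    for fov_id in pd.unique(fov):
        in_fov = fov == fov_id
        s_rows = np.flatnonzero(in_fov & (types == sender))
        r_rows = np.flatnonzero(in_fov & (types == receiver))
        es, er = _eligible_sets(coords, s_rows, r_rows, range_um)
        if er.size == 0:
            per_fov_rows.append((fov_id, np.nan, np.nan, np.nan, 0))
            continue
        lbar, rbar = _trimmed_mean(lig[es]), _trimmed_mean(rec[er])
        score = (lbar * rbar) / (kh + lbar * rbar)
        per_fov_rows.append((fov_id, score, lbar, rbar, int(er.size)))
        all_s.append(es)
        all_r.append(er)
    per_fov = pd.DataFrame(
        per_fov_rows, columns=["fov_id", "score", "L_bar", "R_bar", "n_eligible"]
    )
    if all_r:
        lbar = _trimmed_mean(lig[np.concatenate(all_s)])
        rbar = _trimmed_mean(rec[np.concatenate(all_r)])
        pooled = (lbar * rbar) / (kh + lbar * rbar)
        n_elig = int(sum(a.size for a in all_r))
    else:
        lbar = rbar = pooled = np.nan
        n_elig = 0
    return LRScore(ligand, receptor, sender, receiver, per_fov,
                   float(pooled), float(lbar), float(rbar), n_elig)


def lr_permutation(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    range_um: float = DIFFUSIBLE_RANGE_UM,
    kh: float = 0.5,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation p for an LR score, shuffling cell-type labels
    within each FOV: p = (1 + #{score* >= score}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    types = cells["cell_type"].to_numpy()
    if len(pd.unique(types)) < 2:
        raise ValueError("degenerate cell-type labels")
    observed = lr_score(matrix, cells, ligand, receptor, sender, receiver,
                        range_um, kh).pooled_score
    rng = np.random.default_rng(seed)
    fov = cells["fov_id"].to_numpy()
    groups = [np.flatnonzero(fov == f) for f in pd.unique(fov)]
    shuffled = cells.copy()
    exceed = 0
    for _ in range(n_perm):
        perm = types.copy()
        for rows in groups:
            perm[rows] = types[rows][rng.permutation(rows.size)]
        shuffled["cell_type"] = perm
        star = lr_score(matrix, shuffled, ligand, receptor, sender, receiver,
                        range_um, kh).pooled_score
        if not np.isnan(star) and star >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (n_perm + 1)


def fov_pseudobulk(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    genes: Sequence[str] | None = None,
    min_cells: int = 5,
) -> pd.DataFrame:
    """FOV x gene matrix of mean normalized expression within one cell type.

    FOVs holding fewer than ``min_cells`` cells of the type get NaN rows;
    the number of contributing cells is reported in the ``n_cells``
    attribute.
    """
    types = cells["cell_type"].to_numpy()
    if cell_type not in set(types):
        raise ValueError(f"cell type {cell_type!r} absent")
    genes = list(genes) if genes is not None else list(matrix.genes)
    dense = matrix.normalized_dense(genes)
    fov = cells["fov_id"].to_numpy()
    fovs = pd.unique(fov)
    out = np.full((len(fovs), len(genes)), np.nan)
    n_cells = {}
    for i, fov_id in enumerate(fovs):
        rows = np.flatnonzero((fov == fov_id) & (types == cell_type))
        n_cells[fov_id] = int(rows.size)
        if rows.size >= min_cells:
            out[i] = dense[:, rows].mean(axis=1)
    table = pd.DataFrame(out, index=pd.Index(fovs, name="fov_id"), columns=genes)
    table.attrs["n_cells"] = n_cells
    table.attrs["min_cells"] = min_cells
    return table


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    note: str = ""


def fov_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    method: str = "pearson",
) -> CorrelationResult:
    """Pearson (default) or Spearman correlation with pairwise NaN deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 paired non-null values, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, "zero variance in one vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(float(r), float(p), n)


def signature_score(
    table: pd.DataFrame, gene_set: Sequence[str]
) -> tuple[pd.Series, list[str]]:
    """Mean of z-scored member genes per unit (cell, FOV or ROI rows).

    ``table`` is units x genes. Returns (score series, missing members).
    Constant member genes contribute zero after z-scoring.
    """
    members = list(dict.fromkeys(gene_set))
    present = [g for g in members if g in table.columns]
    missing = [g for g in members if g not in table.columns]
    if not present:
        raise ValueError("no member gene of the signature is present")
    x = table[present].to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0, keepdims=True)
    sd = np.nanstd(x, axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return pd.Series(np.nanmean(z, axis=1), index=table.index, name="score"), missing


def correlated_genes(
    table: pd.DataFrame,
    anchor_gene: str,
    r_min: float = 0.4,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Genes whose Pearson correlation with the anchor exceeds r_min at p<p_max.

    ``table`` is samples x genes. The anchor is excluded from its own
    list; constant genes (undefined r) are treated as failing the filter.
    """
    if anchor_gene not in table.columns:
        raise ValueError(f"anchor gene {anchor_gene!r} absent")
    if len(table) < 10:
        raise ValueError("need >= 10 samples")
    anchor = table[anchor_gene].to_numpy(dtype=float)
    if np.std(anchor) == 0:
        raise ValueError("anchor gene is constant")
    rows = []
    for g in table.columns:
        if g == anchor_gene:
            continue
        v = table[g].to_numpy(dtype=float)
        if np.std(v) == 0:
            continue
        r, p = stats.pearsonr(anchor, v)
        if r > r_min and p < p_max:
            rows.append({"gene": g, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["gene", "r", "p"]).sort_values(
        "r", ascending=False, ignore_index=True
    )
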