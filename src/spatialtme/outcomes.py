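"""FOV infiltration stratification and survival association of abundances.

FOVs are stratified by the fraction of immune cells they contain
(default immune lineages: T/NK, B/Plasma, Myeloid), with a median split
(ties to low). Differential expression between strata reuses the
Wilcoxon + Benjamini-Hochberg engine from :mod:`spatialtme.crosstalk`.

Survival analysis dichotomizes a per-patient covariate (niche or
subtype abundance, or gene expression) into high/low groups and compares
Kaplan-Meier curves with a two-group log-rank test. No proportional
hazards regression or covariate adjustment is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .crosstalk import _wilcoxon_de
from .spatial_io import ExpressionMatrix

DEFAULT_IMMUNE_TYPES = ("T/NK", "B/Plasma", "Myeloid")


@dataclass
class FOVStrata:
    table: pd.DataFrame  # fov_id, immune_fraction, stratum
    cutpoint: float
    immune_types: tuple[str, ...]


def immune_fraction(
    cells: pd.DataFrame,
    immune_types: Sequence[str] = DEFAULT_IMMUNE_TYPES,
) -> FOVStrata:
    """Per-FOV immune cell fraction with a median high/low split.

    A FOV is "high" iff its fraction strictly exceeds the across-FOV
    median; ties go to "low". If every FOV has the same fraction all
    FOVs land in "low" and a warning is emitted.
    """
    vocab = set(cells["cell_type"])
    unknown = sorted(set(immune_types) - vocab)
    if unknown == sorted(immune_types):
        raise ValueError(f"no immune type present; unknown: {unknown}")
    is_immune = cells["cell_type"].isin(immune_types).to_numpy()
    grp = pd.DataFrame({"fov_id": cells["fov_id"], "immune": is_immune}).groupby(
        "fov_id"
    )["immune"]
    frac = grp.mean()
    cut = float(frac.median())
    stratum = np.where(frac > cut, "high", "low")
    if (stratum == "low").all():
        warnings.warn("all FOVs tied at the median immune fraction; "
                      "every FOV assigned to the low stratum")
    table = pd.DataFrame(
        {"fov_id": frac.index, "immune_fraction": frac.to_numpy(),
         "n_cells": grp.size().to_numpy(), "stratum": stratum}
    ).reset_index(drop=True)
    return FOVStrata(table=table, cutpoint=cut, immune_types=tuple(immune_types))


def infiltration_de(
    matrix: ExpressionMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    strata: FOVStrata,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """DE within one cell type between high- and low-infiltration FOVs.

    Cells inherit their FOV's stratum; log2 fold change is high over low.
    """
    stratum_of = dict(zip(strata.table["fov_id"], strata.table["stratum"]))
    cell_stratum = cells["fov_id"].map(stratum_of).to_numpy()
    is_type = (cells["cell_type"] == cell_type).to_numpy()
    rows_high = np.flatnonzero(is_type & (cell_stratum == "high"))
    rows_low = np.flatnonzero(is_type & (cell_stratum == "low"))
    if rows_high.size == 0 or rows_low.size == 0:
        raise ValueError(
            f"{cell_type!r} missing in a stratum: high={rows_high.size}, "
            f"low={rows_low.size}"
        )
    return _wilcoxon_de(matrix, rows_high, rows_low, gene_subset, "high", "low")


def dichotomize(
    values: pd.Series | np.ndarray, rule: str = "median", q: float = 0.5
) -> tuple[np.ndarray, float]:
    """Split values into high/low groups at the median or a quantile.

    ``high`` iff value > cutpoint; ties are assigned to ``low``. Returns
    (labels, cutpoint). Constant input is an error: no cutpoint exists.
    """
    arr = np.asarray(values, dtype=float)
    if np.all(arr == arr[0]):
        raise ValueError("values are constant; cannot dichotomize")
    if rule == "median":
        cut = float(np.median(arr))
    elif rule == "quantile":
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")
        cut = float(np.quantile(arr, q))
    else:
        raise ValueError("rule must be 'median' or 'quantile'")
    return np.where(arr > cut, "high", "low"), cut


class KMEstimate(NamedTuple):
    table: pd.DataFrame  # time, survival, n_at_risk, n_events, n_censored
    median_time: float


def km_curve(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Product-limit (Kaplan-Meier) survival estimate with a risk table.

    ``table`` has one row per distinct event time; censored observations
    reduce the risk set without stepping the curve. S is right-continuous.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        table = pd.DataFrame(
            columns=["time", "survival", "n_at_risk", "n_events", "n_censored"]
        )
        return KMEstimate(table=table, median_time=float("inf"))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    rows = []
    for t, s in zip(event_times, surv):
        rows.append(
            {
                "time": t,
                "survival": float(s),
                "n_at_risk": int((times >= t).sum()),
                "n_events": int(((times == t) & (events == 1)).sum()),
                "n_censored": int(((times == t) & (events == 0)).sum()),
            }
        )
    median = kmf.median_survival_time_
    return KMEstimate(table=pd.DataFrame(rows), median_time=float(median))


class LogrankResult(NamedTuple):
    statistic: float
    p: float
    df: int
    n_a: int
    n_b: int


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df).

    At each event time the observed events in group A are compared with
    the hypergeometric expectation given the pooled risk set; the
    squared standardized sum is chi-square(1) under equal hazards.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(
        statistic=float(res.test_statistic), p=float(res.p_value), df=1,
        n_a=int(ta.size), n_b=int(tb.size),
    )


def km_by_group(
    survival: pd.DataFrame,
    covariate: pd.Series,
    rule: str = "median",
    q: float = 0.5,
) -> tuple[pd.DataFrame, LogrankResult]:
    """Dichotomize a per-patient covariate and compare KM curves.

    ``survival`` needs columns patient_id, time_months, event; the
    covariate series is indexed by patient_id. Returns the survival
    table augmented with the group label, plus the log-rank result.
    """
    merged = survival.merge(
        covariate.rename("covariate"), left_on="patient_id", right_index=True,
        how="inner",
    )
    if len(merged) < len(survival):
        missing = set(survival["patient_id"]) - set(merged["patient_id"])
        warnings.warn(f"{len(missing)} patients lack the covariate; dropped")
    labels, cut = dichotomize(merged["covariate"], rule=rule, q=q)
    merged = merged.assign(group=labels)
    hi = merged[merged["group"] == "high"]
    lo = merged[merged["group"] == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("dichotomization produced an empty group")
    res = logrank_test(
        hi["time_months"].to_numpy(), hi["event"].to_numpy(),
        lo["time_months"].to_numpy(), lo["event"].to_numpy(),
    )
    merged.attrs["cutpoint"] = cut
    return merged, res
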