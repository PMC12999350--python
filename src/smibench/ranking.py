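"""Rank aggregation across metrics into two performance dimensions.

Method-level performance per metric is the median across datasets (pooling
mechanisms and dropout rates); medians are min-max scaled per metric to
[0, 1] and error-type metrics (NRMSE, RMSE, MAE) are reversed as
1 - scaled so higher is always better; methods are then ranked per metric
(1 = best, ties share the average rank) and the per-dimension rank is the
mean of the per-metric ranks — separately for the imputation-accuracy
dimension (NRMSE, RMSE, MAE, Pearson, cosine) and the cluster-preservation
dimension (silhouette, Calinski-Harabasz, ARI, NMI).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "POLARITY",
    "DIMENSION_METRICS",
    "make_metric_table",
    "median_scores",
    "normalize_scores",
    "aggregate_ranks",
]

#: higher-better (+1) vs lower-better (-1) for every metric the benchmark emits
POLARITY: dict[str, int] = {
    "nrmse": -1,
    "rmse": -1,
    "mae": -1,
    "pearson": +1,
    "cosine": +1,
    "silhouette": +1,
    "calinski_harabasz": +1,
    "nmi": +1,
    "ari": +1,
}

DIMENSION_METRICS: dict[str, tuple[str, ...]] = {
    "accuracy": ("nrmse", "rmse", "mae", "pearson", "cosine"),
    "clustering": ("silhouette", "calinski_harabasz", "ari", "nmi"),
}

_TIDY_COLUMNS = ["method", "dataset", "mechanism", "rate", "metric", "value"]


def make_metric_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a tidy metric table (one row per method/dataset/mechanism/rate/metric)."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in _TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric rows lack columns: {missing}")
    unknown = set(df["metric"]) - set(POLARITY)
    if unknown:
        raise ValueError(f"no polarity defined for metric(s): {sorted(unknown)}")
    return df[_TIDY_COLUMNS].copy()


def median_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Median value per (method, metric), pooling datasets/mechanisms/rates.

    Undefined values (NaN/None) are excluded; a (method, metric) cell with no
    defined value at all is dropped with a warning.  Returns a method x metric
    DataFrame; the median uses the midpoint convention for even counts.
    """
    df = table.dropna(subset=["value"])
    dropped = set(map(tuple, table[["method", "metric"]].drop_duplicates().to_numpy())) - set(
        map(tuple, df[["method", "metric"]].drop_duplicates().to_numpy())
    )
    if dropped:
        warnings.warn(f"no defined values for {sorted(dropped)}; excluded", stacklevel=2)
    piv = df.groupby(["method", "metric"])["value"].median().unstack("metric")
    return piv


def normalize_scores(
    medians: pd.DataFrame, polarity: Mapping[str, int] = POLARITY
) -> pd.DataFrame:
    """Min-max scale each metric's medians to [0, 1]; reverse lower-better metrics.

    After this step higher values consistently indicate better performance.
    A metric where all methods tie (max == min) maps every method to 0.5.
    """
    if len(medians) < 2:
        raise ValueError("need at least 2 methods to min-max scale")
    out = pd.DataFrame(index=medians.index, columns=medians.columns, dtype=float)
    for metric in medians.columns:
        if metric not in polarity:
            raise ValueError(f"no polarity for metric {metric!r}")
        v = medians[metric].astype(float)
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"metric {metric!r}: all methods tie; scored 0.5", stacklevel=2)
            out[metric] = 0.5
            continue
        scaled = (v - lo) / (hi - lo)
        out[metric] = 1.0 - scaled if polarity[metric] < 0 else scaled
    return out


def aggregate_ranks(
    normalized: pd.DataFrame,
    dimension: str,
    use_scores: bool = False,
) -> pd.DataFrame:
    """Average per-metric ranks into one ordering for a dimension.

    Within each metric of the dimension, methods are ranked by normalized
    score (rank 1 = best; ties share the average rank); the dimension rank
    is the mean of those ranks.  ``use_scores=True`` instead averages the
    normalized scores themselves (an alternative aggregation, higher =
    better).  Returns a DataFrame with per-metric ranks, the aggregate, and
    the overall ordering (column ``overall_rank``), sorted best-first.
    """
    if dimension not in DIMENSION_METRICS:
        raise ValueError(f"unknown dimension {dimension!r}")
    metrics = DIMENSION_METRICS[dimension]
    absent = [m for m in metrics if m not in normalized.columns]
    if absent:
        raise ValueError(f"dimension {dimension!r} missing metric(s): {absent}")
    ranks = pd.DataFrame(index=normalized.index)
    for metric in metrics:
        ranks[f"rank_{metric}"] = rankdata(-normalized[metric].to_numpy(), method="average")
    if use_scores:
        agg = normalized[list(metrics)].mean(axis=1)
        order = (-agg).argsort(kind="stable")
        ranks["mean_score"] = agg
    else:
        agg = ranks.mean(axis=1)
        order = agg.argsort(kind="stable")
        ranks["mean_rank"] = agg
    ranks["overall_rank"] = rankdata(
        -agg.to_numpy() if use_scores else agg.to_numpy(), method="average"
    )
    return ranks.iloc[order]
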