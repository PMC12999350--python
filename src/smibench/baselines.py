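"""Baseline imputers: mean, median, half-minimum, kNN, iterative SVD, random forest.

All imputers share the same contract: the returned matrix is complete and
non-negative, and every entry that was observed in the input is preserved
bit-exactly — only missing cells are filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .io import SpatialMatrix
from .missingness import MaskedDataset

__all__ = [
    "ImputationResult",
    "impute_mean",
    "impute_median",
    "impute_hm",
    "impute_knn",
    "impute_svd",
    "impute_rf",
]

Imputable = Union[MaskedDataset, SpatialMatrix]


@dataclass
class ImputationResult:
    """A completed matrix plus provenance (method name, hyperparameters)."""

    imputed: np.ndarray
    method: str
    hyperparams: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imputed = np.asarray(self.imputed, dtype=float)
        if np.isnan(self.imputed).any():
            raise ValueError("imputed matrix contains missing values")
        if self.imputed.min() < 0:
            raise ValueError("imputed matrix contains negative values")

    def to_matrix(self, template: SpatialMatrix) -> SpatialMatrix:
        return SpatialMatrix(
            self.imputed.copy(),
            template.coords.copy(),
            list(template.spot_ids),
            list(template.metabolite_ids),
        )


def _as_matrix(d: Imputable) -> SpatialMatrix:
    return d.observed if isinstance(d, MaskedDataset) else d


def _check_no_empty_columns(m: SpatialMatrix) -> np.ndarray:
    """Return the missing mask, raising if a column has no observed value."""
    miss = np.isnan(m.intensities)
    empty = miss.all(axis=0)
    if empty.any():
        bad = [m.metabolite_ids[j] for j in np.nonzero(empty)[0]]
        raise ValueError(f"column(s) with no observed value: {bad}")
    return miss


def _column_fill(d: Imputable, stat, method: str, **hyper) -> ImputationResult:
    m = _as_matrix(d)
    miss = _check_no_empty_columns(m)
    out = m.intensities.copy()
    for j in range(m.n_metabolites):
        col = out[:, j]
        if miss[:, j].any():
            col[miss[:, j]] = stat(col[~miss[:, j]])
    return ImputationResult(out, method, hyper)


def impute_mean(d: Imputable) -> ImputationResult:
    """Fill each missing cell with its metabolite's observed mean."""
    return _column_fill(d, np.mean, "mean")


def impute_median(d: Imputable) -> ImputationResult:
    """Fill each missing cell with its metabolite's observed median."""
    return _column_fill(d, np.median, "median")


def impute_hm(d: Imputable) -> ImputationResult:
    """Fill each missing cell with half the metabolite's observed minimum.

    A detection-limit heuristic: non-detections are assumed to sit below
    the smallest value actually measured.
    """
    return _column_fill(d, lambda v: v.min() / 2.0, "hm")


def impute_knn(d: Imputable, k: int = 10) -> ImputationResult:
    """k-nearest-neighbour imputation over spots.

    Distances between spots are Euclidean over mutually observed
    metabolites, rescaled by sqrt(p / p_observed) to stay comparable across
    pairs with different overlap; each missing cell is the unweighted mean
    of the k nearest spots that observe that metabolite, falling back to
    the column mean when no eligible neighbour exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = _as_matrix(d)
    _check_no_empty_columns(m)
    if k > m.n_spots - 1:
        warnings.warn(
            f"k={k} exceeds n_spots-1={m.n_spots - 1}; clamping", stacklevel=2
        )
        k = m.n_spots - 1
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = imputer.fit_transform(m.intensities)
    # KNNImputer drops all-missing columns rather than erroring; guarded above
    return ImputationResult(out, "knn", {"k": k})


def impute_svd(
    d: Imputable,
    rank: int = 10,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> ImputationResult:
    """Iterative low-rank SVD imputation with zero-clipping.

    Columns are centred and scaled using observed statistics; missing cells
    start at zero (the column mean on the standardized scale) and are
    repeatedly overwritten by the rank-``rank`` truncated-SVD reconstruction
    until the relative change of the imputed cells falls below ``tol`` or
    ``max_iter`` is reached.  After un-scaling, negative estimates are
    clipped to zero (intensities are physically non-negative); the clipped
    count is reported in the diagnostics.
    """
    m = _as_matrix(d)
    n, p = m.intensities.shape
    if not 1 <= rank <= min(n, p) - 1:
        raise ValueError(f"rank must be in [1, {min(n, p) - 1}]")
    miss = _check_no_empty_columns(m)
    x = m.intensities
    # initialize missing cells at the column mean (zero on the standardized
    # scale); standardization is refreshed from the completed matrix each
    # iteration so an exactly low-rank matrix is a fixed point
    out = x.copy()
    col_means = np.nanmean(x, axis=0)
    for j in range(p):
        out[miss[:, j], j] = col_means[j]

    converged = False
    n_iter = 0
    delta = np.inf
    if miss.any():
        for n_iter in range(1, max_iter + 1):
            mu = out.mean(axis=0)
            sd = out.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            z = (out - mu) / sd
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
            new_vals = (recon * sd + mu)[miss]
            old_vals = out[miss]
            denom = max(np.linalg.norm(old_vals), 1e-12)
            delta = np.linalg.norm(new_vals - old_vals) / denom
            out[miss] = new_vals
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"SVD imputation did not converge in {max_iter} iterations",
                stacklevel=2,
            )
    else:
        converged = True

    clipped = int((out[miss] < 0).sum())
    out[out < 0] = 0.0
    return ImputationResult(
        out,
        "svd",
        {"rank": rank, "tol": tol, "max_iter": max_iter},
        {
            "iterations": n_iter,
            "converged": converged,
            "final_delta": float(delta) if np.isfinite(delta) else None,
            "clipped_count": clipped,
        },
    )


def impute_rf(
    d: Imputable,
    ntree: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """missForest-style iterative random-forest imputation.

    Missing cells start at column means; columns are visited in order of
    increasing missingness, each treated as the regression target of a
    random forest fitted on the rows where it is observed (all other
    columns as predictors, mtry = ceil(p/3)).  Iteration stops when the
    summed squared change of the imputed cells increases — the previous
    iteration's fill is then returned — or at ``max_iter``.
    """
    m = _as_matrix(d)
    n, p = m.intensities.shape
    if p < 2:
        raise ValueError("random-forest imputation needs at least 2 columns")
    miss = _check_no_empty_columns(m)
    x = m.intensities.copy()
    col_means = np.nanmean(x, axis=0)
    for j in range(p):
        x[miss[:, j], j] = col_means[j]

    order = np.argsort(miss.sum(axis=0), kind="stable")
    order = [j for j in order if miss[:, j].any()]
    if not order:
        return ImputationResult(
            x, "rf", {"ntree": ntree, "max_iter": max_iter, "seed": seed},
            {"iterations": 0, "stopped_early": False},
        )
    mtry = int(np.ceil((p - 1) / 3))

    prev = x.copy()
    prev_score = np.inf
    n_iter = 0
    stopped_early = False
    for n_iter in range(1, max_iter + 1):
        for rank_j, j in enumerate(order):
            obs_rows = ~miss[:, j]
            predictors = np.delete(x, j, axis=1)
            forest = RandomForestRegressor(
                n_estimators=ntree,
                max_features=mtry,
                random_state=(seed + 7919 * n_iter + rank_j) % (2**31),
                n_jobs=1,
            )
            forest.fit(predictors[obs_rows], x[obs_rows, j])
            x[miss[:, j], j] = forest.predict(predictors[miss[:, j]])
        score = float(((x - prev)[miss] ** 2).sum())
        if score >= prev_score:
            x = prev  # divergence: keep previous iteration's imputation
            stopped_early = True
            break
        prev = x.copy()
        prev_score = score
    out = x
    out[~miss] = m.intensities[~miss]
    out[out < 0] = 0.0  # forests trained on non-negative data cannot go below 0,
    # but guard anyway
    return ImputationResult(
        out,
        "rf",
        {"ntree": ntree, "max_iter": max_iter, "seed": seed},
        {"iterations": n_iter, "stopped_early": stopped_early},
    )
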