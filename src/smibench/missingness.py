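"""Filtering rules and artificial-dropout generators.

Benchmark instances with known ground truth are created by hiding observed
entries of a (filtered) matrix under one of two mechanisms common in
MS-based metabolomics:

* **MCAR** — missing completely at random: a fixed fraction of observed
  entries, drawn uniformly over the whole matrix.
* **MNAR** — missing not at random, here left-censoring: for a random
  subset of metabolites, all values below a random per-metabolite
  truncation quantile q in [0.30, 0.60] are hidden, so low-intensity
  values are preferentially lost (detection-limit behaviour).

Two filters precede the two benchmark tracks: the accuracy track keeps only
metabolites with a missing rate below 10% (a high-confidence reference for
scoring), while the clustering track merely drops metabolites with more
than 80% missing values to stay close to realistic preprocessing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SpatialMatrix, read_matrix, write_matrix

__all__ = [
    "MaskedDataset",
    "drop_empty_spots",
    "filter_for_accuracy",
    "filter_for_clustering",
    "mask_mcar",
    "mask_mnar",
]

logger = logging.getLogger(__name__)


@dataclass
class MaskedDataset:
    """A dropout benchmark instance: observed data + hidden ground truth.

    ``mask`` is True exactly at the positions that were artificially hidden;
    those positions are missing in ``observed`` and non-missing in
    ``reference``; everywhere else the two matrices agree bit-exactly.
    """

    observed: SpatialMatrix
    reference: SpatialMatrix
    mask: np.ndarray
    mechanism: str
    rate: float
    seed: int
    q_thresholds: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        ref, obs = self.reference.intensities, self.observed.intensities
        if self.mask.shape != ref.shape:
            raise ValueError("mask shape mismatch")
        if np.isnan(ref[self.mask]).any():
            raise ValueError("mask covers a position missing in the reference")
        if not np.isnan(obs[self.mask]).all():
            raise ValueError("masked position still observed")
        unmasked = ~self.mask
        same = (obs[unmasked] == ref[unmasked]) | (
            np.isnan(obs[unmasked]) & np.isnan(ref[unmasked])
        )
        if not same.all():
            raise ValueError("observed differs from reference off the mask")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def truth(self) -> np.ndarray:
        """True values at masked positions, in row-major mask order."""
        return self.reference.intensities[self.mask]

    # -- serialization: observed/reference matrices, mask CSV, JSON metadata
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_matrix(self.observed, d / "observed.csv")
        write_matrix(self.reference, d / "reference.csv")
        rows, cols = np.nonzero(self.mask)
        pd.DataFrame(
            {
                "spot_id": [self.reference.spot_ids[i] for i in rows],
                "metabolite_id": [self.reference.metabolite_ids[j] for j in cols],
            }
        ).to_csv(d / "mask.csv", index=False)
        meta = {
            "mechanism": self.mechanism,
            "rate": self.rate,
            "seed": self.seed,
            "q_thresholds": self.q_thresholds,
            **self.meta,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "MaskedDataset":
        from .io import FormatSpec

        d = Path(directory)
        fs = FormatSpec(zeros_as_missing=False)
        observed = read_matrix(d / "observed.csv", fs)
        reference = read_matrix(d / "reference.csv", fs)
        meta = json.loads((d / "meta.json").read_text())
        mask = np.zeros(reference.intensities.shape, dtype=bool)
        spot_idx = {s: i for i, s in enumerate(reference.spot_ids)}
        met_idx = {m: j for j, m in enumerate(reference.metabolite_ids)}
        pairs = pd.read_csv(d / "mask.csv", dtype=str)
        for s, m in zip(pairs["spot_id"], pairs["metabolite_id"]):
            mask[spot_idx[s], met_idx[m]] = True
        return cls(
            observed,
            reference,
            mask,
            mechanism=meta.pop("mechanism"),
            rate=meta.pop("rate"),
            seed=meta.pop("seed"),
            q_thresholds=meta.pop("q_thresholds", {}),
            meta=meta,
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def drop_empty_spots(m: SpatialMatrix) -> SpatialMatrix:
    """Remove spots whose entries are all missing or zero (no signal at all)."""
    x = m.intensities
    informative = np.nansum(x, axis=1) > 0
    informative &= ~np.all(np.isnan(x), axis=1)
    if not informative.any():
        raise ValueError("every spot is empty")
    if informative.all():
        return m
    return m.subset(rows=np.nonzero(informative)[0])


def _filter_columns(m: SpatialMatrix, keep: np.ndarray, what: str) -> SpatialMatrix:
    if not keep.any():
        raise ValueError(f"no metabolite survives the {what} filter")
    if keep.all():
        return m
    return m.subset(cols=np.nonzero(keep)[0])


def filter_for_accuracy(m: SpatialMatrix, threshold: float = 0.10) -> SpatialMatrix:
    """Keep metabolites with missing fraction strictly below ``threshold``.

    The surviving columns are nearly complete, giving a high-confidence
    reference against which artificial dropout can be scored.
    """
    frac = np.isnan(m.intensities).mean(axis=0)
    return _filter_columns(m, frac < threshold, "accuracy")


def filter_for_clustering(m: SpatialMatrix, threshold: float = 0.80) -> SpatialMatrix:
    """Drop metabolites with *more than* ``threshold`` missing (keeps ==)."""
    frac = np.isnan(m.intensities).mean(axis=0)
    return _filter_columns(m, frac <= threshold, "clustering")


# ---------------------------------------------------------------------------
# dropout generators
# ---------------------------------------------------------------------------

def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def mask_mcar(m: SpatialMatrix, rate: float, seed: int = 0) -> MaskedDataset:
    """Hide ``round(rate * n_observed)`` entries uniformly at random.

    The draw is global over all observed entries of the matrix (not
    stratified per metabolite); the count uses round-half-to-even.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    obs_pos = np.flatnonzero(~np.isnan(m.intensities))
    n_mask = _round_half_even(rate * obs_pos.size)
    chosen = rng.choice(obs_pos, size=n_mask, replace=False)
    mask = np.zeros(m.intensities.size, dtype=bool)
    mask[chosen] = True
    mask = mask.reshape(m.intensities.shape)
    observed = m.copy()
    observed.intensities[mask] = np.nan
    return MaskedDataset(
        observed,
        m.copy(),
        mask,
        mechanism="MCAR",
        rate=rate,
        seed=seed,
        meta={"draw": "global"},
    )


def mask_mnar(
    m: SpatialMatrix,
    proportion: float,
    q_low: float = 0.30,
    q_high: float = 0.60,
    seed: int = 0,
) -> MaskedDataset:
    """Left-censor a random subset of metabolites below a random quantile.

    ``round(proportion * n_metabolites)`` metabolites are selected uniformly;
    each gets an independent truncation quantile q ~ Uniform[q_low, q_high]
    and all its observed values strictly below the empirical q-quantile
    (linear-interpolation convention) are hidden.  A degenerate column whose
    observed values are all equal yields zero masked entries and a log line.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    if not 0 <= q_low <= q_high:
        raise ValueError("invalid quantile bounds")
    rng = np.random.default_rng(seed)
    p = m.n_metabolites
    n_sel = _round_half_even(proportion * p)
    cols = np.sort(rng.choice(p, size=n_sel, replace=False))
    mask = np.zeros(m.intensities.shape, dtype=bool)
    q_thresholds: dict[str, float] = {}
    for j in cols:
        q = float(rng.uniform(q_low, q_high))
        col = m.intensities[:, j]
        obs = ~np.isnan(col)
        vals = col[obs]
        q_thresholds[m.metabolite_ids[j]] = q
        if vals.size == 0:
            continue
        thr = np.quantile(vals, q)
        below = obs & (col < thr)
        if not below.any():
            logger.info(
                "MNAR: column %s degenerate at q=%.3f, nothing censored",
                m.metabolite_ids[j],
                q,
            )
        mask[:, j] = below
    observed = m.copy()
    observed.intensities[mask] = np.nan
    return MaskedDataset(
        observed,
        m.copy(),
        mask,
        mechanism="MNAR",
        rate=proportion,
        seed=seed,
        q_thresholds=q_thresholds,
    )
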