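"""End-to-end benchmark orchestration.

One config drives the whole pipeline: generate or load a dataset, apply the
two filtering tracks, simulate MCAR/MNAR dropout over a rate grid, run every
imputation method (with optional hyperparameter grids), score accuracy at
the masked entries, cluster the imputed matrices for the preservation
dimension, and aggregate everything into the two-dimension ranking.  All
randomness derives from the config seed, so re-running a config reproduces
every report bit-exactly; failures of a single grid cell are recorded in
the manifest without aborting the rest of the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, evaluation, gcn, io, missingness, ranking, synthetic

__all__ = ["BenchmarkConfig", "run_benchmark", "impute_with", "METHODS"]

logger = logging.getLogger(__name__)

RATES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

METHODS = ("mean", "median", "hm", "knn", "svd", "rf", "gcn", "external")


@dataclass
class BenchmarkConfig:
    """Declarative description of one benchmark run.

    ``methods`` maps a method name to a list of hyperparameter dicts (its
    sweep grid); an empty list means a single run at defaults.  ``synthetic``
    holds SyntheticSpec fields; alternatively ``input_path`` (and optional
    ``labels_path``) point at an existing matrix.
    """

    synthetic: dict = field(default_factory=dict)
    input_path: str | None = None
    labels_path: str | None = None
    zeros_as_missing: bool = True
    mechanisms: tuple[str, ...] = ("MCAR", "MNAR")
    rates: tuple[float, ...] = RATES
    methods: dict = field(default_factory=lambda: {"mean": [], "knn": [], "gcn": []})
    cluster_algorithms: tuple[str, ...] = ("leiden",)
    resolutions: tuple[float, ...] = evaluation.RESOLUTION_GRID
    seed: int = 0
    store_matrices: bool = False

    def __post_init__(self) -> None:
        self.mechanisms = tuple(self.mechanisms)
        self.rates = tuple(float(r) for r in self.rates)
        self.resolutions = tuple(float(r) for r in self.resolutions)
        self.cluster_algorithms = tuple(self.cluster_algorithms)
        if not self.methods:
            raise ValueError("methods must be non-empty")
        for name in self.methods:
            if name not in METHODS:
                raise ValueError(f"unknown method {name!r}")
        for r in self.rates:
            if not 0 < r < 1:
                raise ValueError("rates must lie in (0, 1)")
        for mech in self.mechanisms:
            if mech not in ("MCAR", "MNAR"):
                raise ValueError(f"unknown mechanism {mech!r}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def impute_with(
    method: str,
    d,
    params: dict | None = None,
    seed: int = 0,
) -> baselines.ImputationResult:
    """Dispatch a single imputation by method name.

    ``external`` reads a pre-imputed matrix from ``params['path']`` (the
    file-based adapter for methods run outside this package) and validates
    the observed-preservation contract.
    """
    params = dict(params or {})
    if method == "mean":
        return baselines.impute_mean(d)
    if method == "median":
        return baselines.impute_median(d)
    if method == "hm":
        return baselines.impute_hm(d)
    if method == "knn":
        return baselines.impute_knn(d, **params)
    if method == "svd":
        return baselines.impute_svd(d, **params)
    if method == "rf":
        params.setdefault("seed", seed)
        return baselines.impute_rf(d, **params)
    if method == "gcn":
        params.setdefault("seed", seed)
        if "hidden_dims" in params:
            params["hidden_dims"] = tuple(params["hidden_dims"])
        if "decoder_dims" in params:
            params["decoder_dims"] = tuple(params["decoder_dims"])
        return gcn.impute_gcn(d, gcn.GCNConfig(**params))
    if method == "external":
        return _external_result(d, params)
    raise ValueError(f"unknown method {method!r}")


def _external_result(d, params: dict) -> baselines.ImputationResult:
    m = baselines._as_matrix(d)
    ext = io.read_matrix(params["path"], io.FormatSpec(zeros_as_missing=False))
    if ext.intensities.shape != m.intensities.shape:
        raise ValueError("external matrix shape mismatch")
    obs = ~np.isnan(m.intensities)
    if not np.array_equal(ext.intensities[obs], m.intensities[obs]):
        raise ValueError("external matrix does not preserve observed entries")
    return baselines.ImputationResult(
        ext.intensities, params.get("name", "external"), {"path": str(params["path"])}
    )


def _load_dataset(cfg: BenchmarkConfig):
    if cfg.input_path:
        m = io.read_matrix(
            cfg.input_path, io.FormatSpec(zeros_as_missing=cfg.zeros_as_missing)
        )
        labels = (
            synthetic.read_labels(cfg.labels_path) if cfg.labels_path else None
        )
        return m, labels, "input"
    spec = synthetic.SyntheticSpec(**{"seed": cfg.seed, **cfg.synthetic})
    m, labels = synthetic.generate_dataset(spec)
    if cfg.zeros_as_missing:
        m = io.zeros_to_missing(m)
    return m, labels, "synthetic"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_benchmark(cfg: BenchmarkConfig, outdir: str | Path) -> dict:
    """Run the full benchmark grid and persist all reports under ``outdir``.

    Returns the manifest (also written as ``manifest.json``): config echo,
    derived seeds, accuracy and clustering report locations, rank tables,
    and any per-cell failures.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    m, labels, dataset_id = _load_dataset(cfg)
    base = missingness.drop_empty_spots(m)
    failures: list[dict] = []

    # ---- accuracy track ---------------------------------------------------
    acc = missingness.filter_for_accuracy(base)
    io.write_matrix(acc, out / "accuracy_input.csv")
    acc_reports: list[evaluation.AccuracyReport] = []
    rows: list[dict] = []
    for im, mech in enumerate(cfg.mechanisms):
        for ir, rate in enumerate(cfg.rates):
            mask_seed = (cfg.seed + 1000 * (im + 1) + 10 * ir) % (2**31)
            if mech == "MCAR":
                masked = missingness.mask_mcar(acc, rate, seed=mask_seed)
            else:
                masked = missingness.mask_mnar(acc, rate, seed=mask_seed)
            for method, grid in cfg.methods.items():
                for ig_, params in enumerate(grid or [{}]):
                    cell = f"{mech}/rate={rate}/{method}/{ig_}"
                    try:
                        res = impute_with(method, masked, params, seed=mask_seed)
                        rep = evaluation.accuracy_metrics(res, masked, dataset_id)
                        acc_reports.append(rep)
                        for metric, value in rep.metrics().items():
                            rows.append(
                                {
                                    "method": method,
                                    "dataset": dataset_id,
                                    "mechanism": mech,
                                    "rate": rate,
                                    "metric": metric,
                                    "value": value,
                                    "grid_index": ig_,
                                }
                            )
                        if cfg.store_matrices:
                            d = out / "imputed" / cell
                            d.mkdir(parents=True, exist_ok=True)
                            io.write_matrix(res.to_matrix(acc), d / "imputed.csv")
                    except Exception as exc:  # per-cell isolation
                        logger.exception("cell %s failed", cell)
                        failures.append({"cell": cell, "error": str(exc)})
    acc_df = pd.DataFrame(rows)
    acc_df.to_csv(out / "accuracy_reports.csv", index=False)

    # best hyperparameter configs per (dataset, mechanism, rate) for methods
    # with grids; ranking below uses the per-method best-NRMSE rows
    best_rows = _best_rows(acc_df)

    # ---- clustering track -------------------------------------------------
    clu = missingness.filter_for_clustering(base)
    clu_rows: list[dict] = []
    to_cluster: dict[str, io.SpatialMatrix] = {"raw": io.fill_missing(clu, 0.0)}
    for method, grid in cfg.methods.items():
        params = (grid or [{}])[0]
        try:
            res = impute_with(method, clu, params, seed=cfg.seed)
            to_cluster[method] = res.to_matrix(clu)
        except Exception as exc:
            logger.exception("clustering-track imputation %s failed", method)
            failures.append({"cell": f"clustering/{method}", "error": str(exc)})
    for name, mat in to_cluster.items():
        emb = evaluation.pca_embedding(mat)
        for algo in cfg.cluster_algorithms:
            for res_param in cfg.resolutions:
                try:
                    lab = evaluation.cluster_spots(
                        mat, algo, res_param, seed=cfg.seed, embedding=emb
                    )
                    rep = evaluation.clustering_metrics(
                        mat, lab, labels, algo, res_param, embedding=emb
                    )
                    for metric, value in rep.metrics().items():
                        clu_rows.append(
                            {
                                "method": name,
                                "dataset": dataset_id,
                                "mechanism": "native",
                                "rate": np.nan,
                                "metric": metric,
                                "value": value,
                                "algorithm": algo,
                                "resolution": res_param,
                                "n_clusters": rep.n_clusters,
                            }
                        )
                except Exception as exc:
                    logger.exception("clustering %s/%s/%s failed", name, algo, res_param)
                    failures.append(
                        {"cell": f"clustering/{name}/{algo}/{res_param}", "error": str(exc)}
                    )
    clu_df = pd.DataFrame(clu_rows)
    clu_df.to_csv(out / "clustering_reports.csv", index=False)

    # ---- ranking ----------------------------------------------------------
    rank_tables: dict[str, str] = {}
    for dim, df in (("accuracy", best_rows), ("clustering", clu_df)):
        try:
            metrics = ranking.DIMENSION_METRICS[dim]
            sub = df[df["metric"].isin(metrics)] if len(df) else df
            if not len(sub) or sub["method"].nunique() < 2:
                raise ValueError("need >= 2 methods with reports")
            table = ranking.make_metric_table(sub.to_dict("records"))
            med = ranking.median_scores(table)
            norm = ranking.normalize_scores(med)
            ranks = ranking.aggregate_ranks(norm, dim)
            ranks.to_csv(out / f"ranks_{dim}.csv")
            io.save_report(ranks.reset_index().to_dict("records"), out / f"ranks_{dim}.json")
            rank_tables[dim] = f"ranks_{dim}.csv"
        except Exception as exc:
            logger.warning("ranking dimension %s skipped: %s", dim, exc)
            failures.append({"cell": f"ranking/{dim}", "error": str(exc)})

    manifest = {
        "config": _plain(asdict(cfg)),
        "dataset": dataset_id,
        "n_spots": base.n_spots,
        "n_metabolites_accuracy": acc.n_metabolites,
        "n_metabolites_clustering": clu.n_metabolites,
        "rank_tables": rank_tables,
        "failures": failures,
        "files": {},
    }
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _best_rows(acc_df: pd.DataFrame) -> pd.DataFrame:
    """Per (method, mechanism, rate): keep the grid cell minimizing NRMSE."""
    if not len(acc_df):
        return acc_df
    wide = acc_df.pivot_table(
        index=["method", "dataset", "mechanism", "rate", "grid_index"],
        columns="metric",
        values="value",
        aggfunc="first",
    ).reset_index()
    best = wide.loc[
        wide.groupby(["method", "dataset", "mechanism", "rate"])["nrmse"].idxmin()
    ]
    return best.melt(
        id_vars=["method", "dataset", "mechanism", "rate", "grid_index"],
        var_name="metric",
        value_name="value",
    )
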