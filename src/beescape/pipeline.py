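"""Seeded end-to-end runs: simulate -> QC -> sibship -> metrics -> stats.

One RunConfig drives the whole chain. Every output table carries the run's
config hash and seed (CSV: a leading ``#`` comment line; JSON: fields), and
re-running an identical config reproduces identical numbers. Stage logging
echoes the record counts at every filter: workers in, clusters at the
support cut, triangulable clusters, colonies per cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colony_metrics, landscape_stats, popgen_qc, sibship, synthetic_data
from .grid import Grid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_real_dataset", "DEFAULT_CATEGORIES"]

# Predictor categories for variation partitioning: human demography,
# human-made infrastructure, natural habitat.
DEFAULT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "demography": ("popDensity", "indTI", "popTotalCom", "pop_40-59", "pop_60plus"),
    "infrastructure": ("buildPerc", "houseDensity", "roadPerc", "otherPavedPerc"),
    "natural": (
        "meadPerc",
        "green1Perc",
        "grassShrubPerc",
        "forestPerc",
        "bareEarthPerc",
        "treeCount",
        "elevat",
        "treeCanopyPerc",
    ),
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    # inputs; None means simulate them
    genotypes_csv: str | None = None
    captures_csv: str | None = None
    covariates_csv: str | None = None
    grid_spec: dict = field(
        default_factory=lambda: {"n_rows": 10, "n_cols": 27, "cell_size_m": 2000.0}
    )
    # simulation scale (used only when inputs are simulated); the default
    # emulates the study design: 86 of the grid's cells visited
    sim: dict = field(default_factory=lambda: {"n_cells_sampled": 86})
    # analysis parameters
    m: float = 1.0
    n: float = 1.0
    restarts: int = 3
    min_support: float = 0.80
    coord_tol_m: float = 0.5
    n_perm: int = 999
    max_subset_size: int = 6
    mistype_rate: float = 0.01
    dropout_rate: float = 0.0
    stages: tuple[str, ...] = ("simulate", "qc", "sibship", "metrics", "stats")
    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CATEGORIES.items()}
    )

    def validate(self) -> None:
        for path in (self.genotypes_csv, self.captures_csv, self.covariates_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")
        assigned = [v for vs in self.categories.values() for v in vs]
        if len(assigned) != len(set(assigned)):
            raise ValueError("a predictor is assigned to more than one category")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        cfg.categories = {k: tuple(v) for k, v in cfg.categories.items()}
        return cfg


def _write_csv(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a machine-readable summary dict (also written to
    ``summary.json`` in the run directory). A stage failure raises with the
    stage name; outputs written so far are flagged as partial in the
    summary on disk when possible.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash()} seed={config.seed}"
    summary: dict = {"config_hash": config.config_hash(), "seed": int(config.seed), "stages": {}}

    error = synthetic_data.ErrorModel(dropout_rate=config.dropout_rate, mistype_rate=config.mistype_rate)
    grid = Grid(**config.grid_spec)

    try:
        genotypes, captures, covariates = _stage_inputs(config, grid, out, tag, summary)
        partition = None
        if "sibship" in config.stages:
            partition = _stage_sibship(config, genotypes, error, out, tag, summary)
        if "qc" in config.stages and partition is not None:
            _stage_qc(config, genotypes, partition, out, tag, summary)
        cells = None
        if "metrics" in config.stages and partition is not None:
            cells = _stage_metrics(config, partition, captures, grid, out, tag, summary)
        if "stats" in config.stages and cells is not None and covariates is not None:
            _stage_stats(config, cells, covariates, out, tag, summary)
    except Exception as exc:
        summary["failed_stage"] = getattr(exc, "_stage", "unknown")
        summary["error"] = str(exc)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        raise

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _tag_stage(exc: Exception, stage: str) -> Exception:
    exc._stage = stage
    return exc


def _stage_inputs(config, grid, out, tag, summary):
    stage = "simulate"
    try:
        if config.genotypes_csv is not None:
            genotypes = pd.read_csv(config.genotypes_csv, comment="#")
            captures = pd.read_csv(config.captures_csv, comment="#")
            covariates = pd.read_csv(config.covariates_csv, comment="#") if config.covariates_csv else None
            summary["stages"][stage] = {"source": "files", "n_workers": int(genotypes["worker_id"].nunique())}
            return genotypes, captures, covariates

        sim = dict(config.sim)
        landscape = synthetic_data.LandscapeConfig(
            n_rows=grid.n_rows, n_cols=grid.n_cols, cell_size_m=grid.cell_size_m, origin_lonlat=grid.origin_lonlat
        )
        density = synthetic_data.DensityModel(
            intercept=sim.get("density_intercept", 3.0),
            coefs=sim.get("density_coefs", {"otherPavedPerc": -0.5, "treeCanopyPerc": 0.4}),
        )
        kernel = synthetic_data.KernelModel(
            base_m=sim.get("kernel_base_m", 1000.0),
            coefs=sim.get("kernel_coefs", {"roadPerc": 250.0, "buildPerc": 150.0}),
        )
        # sample a seeded random subset of cells, as the field protocol did
        n_sampled = sim.get("n_cells_sampled")
        cells_sampled = None
        if n_sampled is not None and n_sampled < grid.n_cells:
            cell_rng = np.random.default_rng(config.seed + 101)
            cells_sampled = tuple(
                int(c) for c in cell_rng.choice(grid.n_cells, size=n_sampled, replace=False)
            )
        protocol = synthetic_data.SamplingProtocol(
            max_per_cell=sim.get("max_per_cell", 60), cells_sampled=cells_sampled
        )
        err = synthetic_data.ErrorModel(dropout_rate=config.dropout_rate, mistype_rate=config.mistype_rate)
        data = synthetic_data.simulate_study(
            config=landscape,
            density_model=density,
            kernel_model=kernel,
            error=err,
            protocol=protocol,
            workers_mean=sim.get("workers_mean", 3.0),
            seed=config.seed,
        )
        _write_csv(data.genotypes, out / "genotypes.csv", tag)
        _write_csv(data.captures, out / "captures.csv", tag)
        _write_csv(data.covariates, out / "covariates.csv", tag)
        _write_csv(data.truth_workers, out / "truth_workers.csv", tag)
        grid.write_geojson(out / "grid.geojson")
        summary["stages"][stage] = {
            "source": "simulated",
            "n_colonies_true": len(data.colonies),
            "n_workers": int(data.genotypes["worker_id"].nunique()),
        }
        logger.info("simulate: %d colonies, %d captured workers", len(data.colonies), len(data.captures))
        return data.genotypes, data.captures, data.covariates
    except Exception as exc:
        raise _tag_stage(exc, stage)


def _stage_sibship(config, genotypes, error, out, tag, summary):
    stage = "sibship"
    try:
        part = sibship.reconstruct_sibships(
            genotypes, error=error, restarts=config.restarts, seed=config.seed
        )
        filtered = sibship.filter_clusters(part, min_support=config.min_support, min_size=2)
        _write_csv(filtered.to_frame(), out / "partition.csv", tag)
        with open(out / "sibship_summary.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config.config_hash(),
                    "seed": int(config.seed),
                    "restart_logliks": part.restart_logliks,
                    "total_loglik": part.total_loglik,
                    "n_clusters_raw": len(part.multi_clusters()),
                    "n_clusters_retained": len(filtered.multi_clusters()),
                    "n_singletons": len(filtered.singletons()),
                },
                fh,
                indent=2,
            )
        summary["stages"][stage] = {
            "workers_in": int(genotypes["worker_id"].nunique()),
            "clusters_at_support_cut": len(filtered.multi_clusters()),
            "singletons": len(filtered.singletons()),
        }
        logger.info(
            "sibship: %d workers -> %d clusters >= %.0f%% + %d singletons",
            genotypes["worker_id"].nunique(),
            len(filtered.multi_clusters()),
            100 * config.min_support,
            len(filtered.singletons()),
        )
        return filtered
    except Exception as exc:
        raise _tag_stage(exc, stage)


def _stage_qc(config, genotypes, partition, out, tag, summary):
    stage = "qc"
    try:
        pruned = popgen_qc.prune_one_per_colony(genotypes, partition, seed=config.seed)
        summaries = popgen_qc.locus_summaries(pruned)
        hwe = popgen_qc.hwe_test(pruned, seed=config.seed)
        table = popgen_qc.locus_summary_frame(summaries).merge(
            hwe[["locus", "hwe_p", "flag"]], on="locus", how="left", suffixes=("_init", "")
        )
        table = table.drop(columns=[c for c in ("hwe_p_init", "hwe_flag") if c in table])
        _write_csv(table, out / "locus_summary.csv", tag)
        summary["stages"][stage] = {
            "workers_after_prune": int(pruned["worker_id"].nunique()),
            "n_loci": len(summaries),
            "hwe_flagged": int(hwe["flag"].sum()),
        }
        logger.info("qc: %d workers after one-per-colony prune", pruned["worker_id"].nunique())
    except Exception as exc:
        raise _tag_stage(exc, stage)


def _stage_metrics(config, partition, captures, grid, out, tag, summary):
    stage = "metrics"
    try:
        triangulable = colony_metrics.triangulable_clusters(partition, captures, config.coord_tol_m)
        colonies = colony_metrics.locate_colonies(triangulable, captures, grid)
        cells = colony_metrics.summarize_cells(colonies, grid, m=config.m, n=config.n)
        colony_df = pd.DataFrame(
            [
                (c.colony_id, c.center_lonlat[0], c.center_lonlat[1], c.cell_id, len(c.members), c.mean_fd_m)
                for c in colonies
            ],
            columns=["colony_id", "lon", "lat", "cell_id", "n_members", "mean_fd_m"],
        )
        cell_df = colony_metrics.cell_summary_frame(cells)
        _write_csv(colony_df, out / "colonies.csv", tag)
        _write_csv(cell_df, out / "cell_summary.csv", tag)
        summary["stages"][stage] = {
            "triangulable_clusters": len(triangulable.multi_clusters()),
            "cells_with_estimates": len(cells),
            "mean_aveMeanFD_m": float(cell_df["aveMeanFD_m"].mean()) if len(cell_df) else None,
            "mean_colNe": float(cell_df["colNe"].mean()) if len(cell_df) else None,
        }
        logger.info(
            "metrics: %d triangulable clusters -> %d cells with estimates",
            len(triangulable.multi_clusters()),
            len(cells),
        )
        return cell_df
    except Exception as exc:
        raise _tag_stage(exc, stage)


def _stage_stats(config, cell_df, covariates, out, tag, summary):
    stage = "stats"
    try:
        merged = cell_df.merge(covariates, on="cell_id", how="inner")
        predictors_all = [v for vs in config.categories.values() for v in vs if v in merged.columns]
        usable = [v for v in predictors_all if merged[v].std() > 0]

        corr_table = merged[["colNe", "ln_aveMeanFD"] + usable]
        rho, padj = landscape_stats.spearman_fdr(corr_table)
        _write_csv(rho.reset_index(names="variable"), out / "spearman_rho.csv", tag)
        _write_csv(padj.reset_index(names="variable"), out / "spearman_padj.csv", tag)

        vif = landscape_stats.vif_screen(merged[usable])
        _write_csv(vif, out / "vif.csv", tag)

        results: dict = {"config_hash": config.config_hash(), "seed": int(config.seed)}
        n_cells = len(merged)
        max_size = min(config.max_subset_size, max(1, n_cells - 3))
        for response in ("colNe", "ln_aveMeanFD"):
            models = landscape_stats.best_subset_regression(
                merged[response], merged[usable], max_size=max_size
            )
            rank_df = pd.DataFrame(
                [
                    {
                        "rank": i + 1,
                        "predictors": "+".join(m.predictors),
                        "adj_r2_percent": 100 * m.adj_r2,
                        "aic": m.aic,
                    }
                    for i, m in enumerate(models)
                ]
            )
            _write_csv(rank_df, out / f"model_ranking_{response}.csv", tag)
            best = landscape_stats.select_parsimonious(models)
            results[f"best_model_{response}"] = {
                "predictors": list(best.predictors),
                "adj_r2": best.adj_r2,
                "aic": best.aic,
                "variance_explained": best.variance_explained,
            }

        if n_cells > len(usable) + 1:
            rda_res = landscape_stats.rda(
                merged[["ln_aveMeanFD", "colNe"]], merged[usable], n_perm=config.n_perm, seed=config.seed
            )
            results["rda"] = {
                "r2": rda_res.r2,
                "adj_r2": rda_res.adj_r2,
                "perm_p": rda_res.perm_p,
                "proportion_of_model": rda_res.proportion_of_model.tolist(),
                "proportion_of_total": rda_res.proportion_of_total.tolist(),
                "predictor_scores": rda_res.predictor_scores.to_dict(),
                "response_scores": rda_res.response_scores.to_dict(),
            }
            sets = {
                name: merged[[v for v in vs if v in usable]]
                for name, vs in config.categories.items()
            }
            if all(len(s.columns) > 0 for s in sets.values()):
                names = tuple(sets)
                vp = landscape_stats.varpart3(
                    merged[["ln_aveMeanFD", "colNe"]], *sets.values(), names=names
                )
                results["varpart"] = {
                    "unique": vp.unique,
                    "pair_shared": {"+".join(k): v for k, v in vp.pair_shared.items()},
                    "triple_shared": vp.triple_shared,
                    "full_adj_r2": vp.full_adj_r2,
                    "residual": vp.residual,
                }
        with open(out / "landscape_stats.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
        summary["stages"][stage] = {
            "n_cells": n_cells,
            "n_predictors": len(usable),
            "rda_r2": results.get("rda", {}).get("r2"),
        }
        logger.info("stats: %d cells x %d predictors", n_cells, len(usable))
    except Exception as exc:
        raise _tag_stage(exc, stage)


def summarize_real_dataset(cell_table: pd.DataFrame) -> dict:
    """Headline per-cell summaries for a study-shaped cell table.

    Expects columns ``aveMeanFD_m`` and ``colNe``; returns their means with
    standard errors and the Spearman correlation between colony density and
    foraging distance on both the raw and natural-log distance scale.
    """
    from scipy import stats as _stats

    fd = cell_table["aveMeanFD_m"].to_numpy(dtype=float)
    ne = cell_table["colNe"].to_numpy(dtype=float)
    n = len(fd)
    r_raw, p_raw = _stats.spearmanr(ne, fd)
    r_ln, p_ln = _stats.spearmanr(ne, np.log(fd))
    return {
        "n_cells": n,
        "mean_aveMeanFD_m": float(fd.mean()),
        "se_aveMeanFD_m": float(fd.std(ddof=1) / np.sqrt(n)),
        "mean_colNe": float(ne.mean()),
        "se_colNe": float(ne.std(ddof=1) / np.sqrt(n)),
        "spearman_colNe_vs_aveMeanFD": float(r_raw),
        "spearman_p_raw": float(p_raw),
        "spearman_colNe_vs_ln_aveMeanFD": float(r_ln),
        "spearman_p_ln": float(p_ln),
    }
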