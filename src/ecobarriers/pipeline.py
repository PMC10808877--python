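"""Reproducible end-to-end runs binding the analysis stages together.

Stages run in dependency order — simulate, climate, barriers, pairs,
fit-sharing, origins, report — inside one run directory. Each stage
records a content hash of its configuration and inputs in the manifest;
a rerun with unchanged inputs reuses the cached outputs, and deleting a
stage's outputs regenerates only that stage and those downstream. All
randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    climate_components,
    cost_paths,
    origin_corridors,
    pair_assembly,
    sharing_models,
    synthetic_world,
)
from .grids import read_grid, write_grid

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "climate", "barriers", "pairs", "fit_sharing", "origins", "report"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Defaults reproduce the study constants: 100 nearest neighbours for
    pair building, 2500 km long-range threshold, 5-with-data
    neighbourhood statistic, alpha = 0.05.
    """

    out_dir: str = "run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    world: dict = field(default_factory=dict)
    n_traits: int = 10
    n_areas: int = 5
    k_neighbors: int = 100
    long_range_min_km: float = 2500.0
    neighbor_mode: str = "five_with_data"
    alpha: float = 0.05
    connectivity: int = 8
    spatial_filter: bool = True
    recodings: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def world_config(self) -> synthetic_world.WorldConfig:
        return synthetic_world.WorldConfig(**{"seed": self.seed, **self.world})

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, out: Path):
        self.path = out / "manifest.json"
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists() else {"stages": {}}
        )

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec.get("key") == key
            and all(Path(p).exists() for p in rec.get("outputs", []))
            and all(o.exists() for o in outputs)
        )

    def record(self, stage: str, key: str, outputs: list[Path], **extra) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "outputs": [str(o) for o in outputs],
            **extra,
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def validate_inputs(
    societies: pd.DataFrame,
    trait_table: pd.DataFrame | None = None,
    tree=None,
) -> dict:
    """Schema and consistency checks; returns errors/warnings lists."""
    errors, warnings_ = [], []
    if societies["id"].duplicated().any():
        errors.append("duplicate society ids")
    bad_lat = ~societies["lat"].between(-90, 90)
    bad_lon = ~societies["lon"].between(-180, 180)
    if bad_lat.any():
        errors.append(f"{int(bad_lat.sum())} societies with latitude outside [-90, 90]")
    if bad_lon.any():
        errors.append(f"{int(bad_lon.sum())} societies with longitude outside [-180, 180]")
    if tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        orphans = set(societies["id"]) - tips
        if orphans:
            warnings_.append(f"{len(orphans)} societies missing from the tree")
    if trait_table is not None:
        unknown = set(trait_table["society_id"]) - set(societies["id"])
        if unknown:
            errors.append(f"{len(unknown)} trait rows with unknown society ids")
        _, drop = pair_assembly.usable_traits(trait_table)
        if drop:
            warnings_.append(
                f"{len(drop)} traits flagged with <=2 discrete categories: {drop}"
            )
    return {"errors": errors, "warnings": warnings_, "ok": not errors}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    chash = config.config_hash()
    (out / "config_echo.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )

    wc = config.world_config()

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    # ------------------------------------------------------------ simulate
    sim_out = [
        out / f
        for f in (
            "societies.csv",
            "tree.nwk",
            "temperature.txt",
            "precipitation.txt",
            "elevation.txt",
            "traits.csv",
        )
    ]
    sim_key = hashlib.sha256(
        json.dumps(
            {"world": dataclasses.asdict(wc), "n_traits": config.n_traits,
             "n_areas": config.n_areas},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    if stage_enabled("simulate"):
        if manifest.fresh("simulate", sim_key, sim_out):
            logger.info("simulate: cached")
        else:
            world = synthetic_world.generate_world(wc)
            world.societies = synthetic_world.assign_origin_areas(
                world.societies, config.n_areas, seed=wc.seed
            )
            traits = synthetic_world.evolve_trait_table(
                world.tree, world.societies, world.th_by_society, wc, config.n_traits
            )
            synthetic_world.write_world(world, out, traits)
            manifest.record("simulate", sim_key, sim_out)

    # ------------------------------------------------------------- climate
    climate_out = [out / "th.txt", out / "ai.txt", out / "env_loadings.csv"]
    climate_in = [out / "temperature.txt", out / "precipitation.txt"]
    if stage_enabled("climate"):
        key = _hash_files([p for p in climate_in if p.exists()])
        if manifest.fresh("climate", key, climate_out):
            logger.info("climate: cached")
        else:
            temp = read_grid(out / "temperature.txt")
            precip = read_grid(out / "precipitation.txt")
            axes = climate_components.env_pca(
                climate_components.summarize_series(temp, precip)
            )
            write_grid(out / "th.txt", axes.th)
            write_grid(out / "ai.txt", axes.ai)
            axes.loadings.to_csv(out / "env_loadings.csv")
            manifest.record(
                "climate",
                key,
                climate_out,
                explained_variance=axes.explained_variance.tolist(),
            )

    # ------------------------------------------------------------ barriers
    barrier_out = [out / "pair_barriers.csv"]
    if stage_enabled("barriers"):
        ins = [out / "societies.csv", out / "th.txt", out / "ai.txt", out / "elevation.txt"]
        key = _hash_files([p for p in ins if p.exists()]) + f":{config.k_neighbors}:{config.connectivity}"
        if manifest.fresh("barriers", key, barrier_out):
            logger.info("barriers: cached")
        else:
            societies = pd.read_csv(out / "societies.csv")
            th_r, ai_r = read_grid(out / "th.txt"), read_grid(out / "ai.txt")
            elev_r = read_grid(out / "elevation.txt")
            graph = cost_paths.build_graph(th_r, connectivity=config.connectivity)
            pairs = pair_assembly.nearest_pairs(societies, k=config.k_neighbors)
            barriers = cost_paths.compute_pair_barriers(
                societies,
                pairs,
                graph,
                cost_paths.node_env_values(graph, th_r),
                cost_paths.node_env_values(graph, ai_r),
                cost_paths.node_env_values(graph, elev_r),
            )
            barriers.to_csv(out / "pair_barriers.csv", index=False)
            manifest.record(
                "barriers", key, barrier_out, n_pairs=len(barriers),
                n_dropped=len(pairs) - len(barriers),
            )

    # --------------------------------------------------------------- pairs
    pairs_out = [out / "pair_covariates.csv", out / "trait_pair_data.csv"]
    if stage_enabled("pairs"):
        ins = [out / "pair_barriers.csv", out / "tree.nwk", out / "traits.csv"]
        key = _hash_files([p for p in ins if p.exists()]) + f":{config.neighbor_mode}"
        if manifest.fresh("pairs", key, pairs_out):
            logger.info("pairs: cached")
        else:
            import dendropy

            societies = pd.read_csv(out / "societies.csv")
            barriers = pd.read_csv(out / "pair_barriers.csv")
            traits = pd.read_csv(out / "traits.csv")
            tree = dendropy.Tree.get(path=str(out / "tree.nwk"), schema="newick")
            rel = pair_assembly.relatedness(tree, barriers)
            cov = barriers.assign(relatedness=rel.to_numpy())
            cov.to_csv(out / "pair_covariates.csv", index=False)

            usable, dropped = pair_assembly.usable_traits(traits, config.recodings)
            long_rows = []
            for trait in usable:
                rec = config.recodings.get(trait)
                share = pair_assembly.score_sharing(traits, trait, cov, rec)
                trans = pair_assembly.neighbor_transmission(
                    cov, societies, traits, trait,
                    mode=config.neighbor_mode, recoding=rec,
                )
                long_rows.append(
                    cov.assign(
                        trait=trait,
                        share=share.to_numpy(),
                        neighbor_transmission=trans.to_numpy(),
                    )
                )
            long_df = pd.concat(long_rows, ignore_index=True)
            long_df.to_csv(out / "trait_pair_data.csv", index=False)
            manifest.record(
                "pairs", key, pairs_out, n_usable_traits=len(usable),
                n_dropped_traits=len(dropped),
            )

    # --------------------------------------------------------- fit_sharing
    fit_out = [out / "sharing_results.csv", out / "sharing_forest.csv"]
    if stage_enabled("fit_sharing"):
        ins = [out / "trait_pair_data.csv"]
        key = _hash_files([p for p in ins if p.exists()]) + f":{config.alpha}"
        if manifest.fresh("fit_sharing", key, fit_out):
            logger.info("fit_sharing: cached")
        else:
            long_df = pd.read_csv(out / "trait_pair_data.csv")
            results, excluded = [], []
            for trait, sub in long_df.groupby("trait"):
                fit, comps = sharing_models.fit_trait(sub, str(trait))
                row = {
                    "trait": trait,
                    "n_pairs": fit.n_pairs,
                    "share_fraction": fit.share_fraction,
                    "sigma2": fit.sigma2,
                    "converged": fit.converged,
                    "auc": fit.auc,
                    "included": fit.included,
                    "exclusion_reason": fit.exclusion_reason,
                }
                for comp in sharing_models.COMPONENT_NAMES:
                    if comp in fit.params.index:
                        row[f"beta_{comp}"] = fit.params[comp]
                        row[f"se_{comp}"] = fit.se[comp]
                        row[f"p_{comp}"] = fit.pvalues[comp]
                results.append(row)
                if not fit.included:
                    excluded.append((trait, fit.exclusion_reason))
            res_df = pd.DataFrame(results)
            # FDR adjustment across included models, per component
            for comp in sharing_models.COMPONENT_NAMES:
                col = f"p_{comp}"
                if col not in res_df.columns:
                    continue
                mask = res_df["included"] & res_df[col].notna()
                res_df[f"padj_{comp}"] = np.nan
                if mask.any():
                    res_df.loc[mask, f"padj_{comp}"] = sharing_models.adjust_fdr(
                        res_df.loc[mask, col].to_numpy()
                    )
            res_df.to_csv(out / "sharing_results.csv", index=False)

            forest = []
            for _, row in res_df[res_df["included"]].iterrows():
                for comp in sharing_models.COMPONENT_NAMES:
                    if f"beta_{comp}" in row:
                        forest.append(
                            {
                                "trait": row["trait"],
                                "component": comp,
                                "estimate": row[f"beta_{comp}"],
                                "se": row[f"se_{comp}"],
                                "p_adjusted": row[f"padj_{comp}"],
                                "significant": row[f"padj_{comp}"] < config.alpha,
                            }
                        )
            pd.DataFrame(forest).to_csv(out / "sharing_forest.csv", index=False)
            manifest.record(
                "fit_sharing", key, fit_out,
                n_models=len(res_df),
                n_included=int(res_df["included"].sum()),
                excluded=[{"trait": t, "reason": r} for t, r in excluded],
            )

    # -------------------------------------------------------------- origins
    origins_out = [
        out / "origin_close_groups.csv",
        out / "origin_long_groups.csv",
        out / "origin_close_tukey_p.csv",
        out / "origin_long_tukey_p.csv",
        out / "origin_loadings.csv",
    ]
    if stage_enabled("origins"):
        ins = [out / "societies.csv", out / "th.txt", out / "ai.txt", out / "elevation.txt"]
        key = (
            _hash_files([p for p in ins if p.exists()])
            + f":{config.k_neighbors}:{config.long_range_min_km}:{config.spatial_filter}"
        )
        if manifest.fresh("origins", key, origins_out):
            logger.info("origins: cached")
        else:
            societies = pd.read_csv(out / "societies.csv")
            th_r, ai_r = read_grid(out / "th.txt"), read_grid(out / "ai.txt")
            elev_r = read_grid(out / "elevation.txt")
            graph = cost_paths.build_graph(th_r, connectivity=config.connectivity)
            th = cost_paths.node_env_values(graph, th_r)
            ai = cost_paths.node_env_values(graph, ai_r)
            elev = cost_paths.node_env_values(graph, elev_r)
            loadings_parts = []
            extra = {}
            for range_label, min_km in (
                ("close", 0.0),
                ("long", config.long_range_min_km),
            ):
                focal = origin_corridors.focal_barrier_table(
                    societies, graph, th, ai, elev,
                    k=config.k_neighbors, min_km=min_km,
                )
                origin = origin_corridors.origin_pca(focal, range_label)
                coords = (
                    societies.set_index("id")
                    .loc[origin.scores["id"], ["lat", "lon"]]
                    .reset_index(drop=True)
                )
                comps = origin_corridors.compare_components(
                    origin, coords,
                    spatial_filter=config.spatial_filter,
                    alpha=config.alpha, seed=config.seed,
                )
                stats_rows, tukey_p = [], []
                for pc, cmp_res in comps.items():
                    gs = cmp_res.group_stats.assign(component=pc)
                    stats_rows.append(gs)
                    tp = cmp_res.tukey_p.copy()
                    tp.insert(0, "component", pc)
                    tukey_p.append(tp)
                    extra[f"{range_label}:{pc}:n_eigenvectors"] = cmp_res.n_eigenvectors
                pd.concat(stats_rows).to_csv(
                    out / f"origin_{range_label}_groups.csv", index=False
                )
                pd.concat(tukey_p).to_csv(out / f"origin_{range_label}_tukey_p.csv")
                ld = origin.loadings.copy()
                ld.insert(0, "range", range_label)
                loadings_parts.append(ld)
            pd.concat(loadings_parts).to_csv(out / "origin_loadings.csv")
            manifest.record("origins", key, origins_out, **extra)

    # --------------------------------------------------------------- report
    if stage_enabled("report"):
        report = {
            "config_hash": chash,
            "seed": config.seed,
            "stages": manifest.data["stages"],
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))

    return out
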