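"""Full factorial sensitivity experiment: scale × shape × sampling × replicate.

One master seed drives every stage (landscape, zonation, splits, forest
fits) through fixed offsets, so a rerun with the same configuration
reproduces the result table byte for byte.  Per species the design runs
ten model families: the village scale exists only in irregular (IRR,
Voronoi) shape, while the sub-district and district scales are run both
as merged IRR units and as regular grids (REG) whose cell side equals
the average spatial resolution of the matching IRR system — five
level/shape combinations, each under both predictor-sampling methods.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import census, evaluation, features, landscape, zonation
from .grid import GridSpec, PredictorStack, write_raster
from .model import ModelConfig, run_replicates

logger = logging.getLogger(__name__)

# seed offsets for the pipeline stages, all derived from the master seed
_PREDICTOR_SEED, _MASK_SEED, _VILLAGE_SEED, _POP_SEED, _MERGE_SEED = 0, 1, 2, 3, 4
_FAMILY_STRIDE = 1000


@dataclass
class ExperimentConfig:
    """Everything needed to run the sensitivity experiment once."""

    nrows: int = 200
    ncols: int = 200
    cell: float = 0.5
    n_layers: int = 8
    range_km: float = 10.0
    unsuitable_fraction: float = 0.25
    n_villages: int = 2000
    village_clustering: str = "uniform"
    n_subdistricts: int = 200
    n_districts: int = 50
    species: list[landscape.SpeciesProfile] = field(
        default_factory=landscape.default_species_profiles
    )
    model: ModelConfig = field(default_factory=ModelConfig)
    density_offset: float = census.DENSITY_OFFSET
    master_seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [
            landscape.SpeciesProfile(**s) for s in raw.pop("species", [])
        ] or landscape.default_species_profiles()
        model = ModelConfig(**raw.pop("model", {}))
        return cls(species=species, model=model, **raw)


@dataclass
class ExperimentResult:
    """Assembled outputs of one sensitivity run."""

    table: pd.DataFrame
    stack: PredictorStack
    villages: list[landscape.VillageSite]
    systems: dict[tuple[str, str], zonation.ZonationSystem]
    summary_maps: dict[tuple[str, str, str, str], "object"]
    cell_status: pd.DataFrame
    provenance: dict


def build_landscape(cfg: ExperimentConfig
                    ) -> tuple[PredictorStack, list[landscape.VillageSite]]:
    """Stages 1-2: predictors + mask + villages + populations."""
    spec = GridSpec(0.0, 0.0, cfg.cell, cfg.nrows, cfg.ncols)
    stack = landscape.generate_predictors(
        spec, cfg.n_layers, cfg.range_km, seed=cfg.master_seed + _PREDICTOR_SEED
    )
    stack = landscape.generate_suitability_mask(
        stack, cfg.unsuitable_fraction, seed=cfg.master_seed + _MASK_SEED
    )
    villages = landscape.generate_villages(
        stack, cfg.n_villages, cfg.village_clustering,
        seed=cfg.master_seed + _VILLAGE_SEED,
    )
    for k, profile in enumerate(cfg.species):
        villages = landscape.generate_population(
            villages, stack, profile, seed=cfg.master_seed + _POP_SEED + 101 * k
        )
    return stack, villages


def build_zonations(cfg: ExperimentConfig, stack: PredictorStack,
                    villages: list[landscape.VillageSite]
                    ) -> dict[tuple[str, str], zonation.ZonationSystem]:
    """Stage 3: village Voronoi, nested IRR merges, ASR-matched REG grids.

    REG systems are built only at the sub-district and district scales;
    their cell side is the ASR of the matching IRR system computed from
    suitable land area.
    """
    region = box(*stack.spec.bounds)
    land = float(stack.mask.sum()) * stack.spec.cell_area()
    vill = zonation.voronoi_zonation(villages, region, land_area=land)
    sub = zonation.merge_to_coarser(
        vill, cfg.n_subdistricts, "subdistrict",
        seed=cfg.master_seed + _MERGE_SEED, land_area=land,
    )
    dist = zonation.merge_to_coarser(
        sub, cfg.n_districts, "district",
        seed=cfg.master_seed + _MERGE_SEED + 1, land_area=land,
    )
    systems = {
        ("village", "IRR"): vill,
        ("subdistrict", "IRR"): sub,
        ("district", "IRR"): dist,
        # min_area_frac=0 keeps boundary slivers so every village lies in
        # exactly one cell and counts are conserved exactly; sliver units
        # without suitable pixels drop out of the response downstream.
        ("subdistrict", "REG"): zonation.regular_grid_zonation(
            region, sub.asr, "subdistrict", min_area_frac=0.0
        ),
        ("district", "REG"): zonation.regular_grid_zonation(
            region, dist.asr, "district", min_area_frac=0.0
        ),
    }
    return systems


FAMILIES = [
    ("village", "IRR"),
    ("subdistrict", "IRR"),
    ("subdistrict", "REG"),
    ("district", "IRR"),
    ("district", "REG"),
]


def run_sensitivity(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the whole factorial and assemble the long-format result table.

    Any failure inside one factorial cell is logged and recorded in the
    cell-status manifest; remaining cells still run.
    """
    t0 = time.time()
    stack, villages = build_landscape(cfg)
    systems = build_zonations(cfg, stack, villages)
    region_labels = {key: census.label_raster(sys_, stack)
                     for key, sys_ in systems.items()}
    village_system = systems[("village", "IRR")]
    village_labels = region_labels[("village", "IRR")]
    areas = {key: census.suitable_areas_all(sys_, stack, region_labels[key])
             for key, sys_ in systems.items()}
    assignments = {key: census.assign_villages(villages, sys_)
                   for key, sys_ in systems.items()}

    rows: list[dict] = []
    status: list[dict] = []
    maps: dict[tuple[str, str, str, str], object] = {}
    provenance = {"generated_totals": {p.name: p.total for p in cfg.species},
                  "observed_totals": {}}

    for sp_idx, profile in enumerate(cfg.species):
        sp = profile.name
        v_counts = census.aggregate_counts(
            villages, village_system, sp, assignments[("village", "IRR")]
        )
        provenance["observed_totals"][sp] = int(sum(v_counts.values()))
        v_records, _ = census.make_response(
            v_counts, areas[("village", "IRR")], cfg.density_offset
        )

        for fam_idx, (level, shape) in enumerate(FAMILIES):
            system = systems[(level, shape)]
            labels = region_labels[(level, shape)]
            counts = census.aggregate_counts(
                villages, system, sp, assignments[(level, shape)]
            )
            records, _ = census.make_response(
                counts, areas[(level, shape)], cfg.density_offset
            )
            scheme = evaluation.DEFAULT_SCHEMES[level]
            for s_idx, sampling in enumerate(features.SAMPLING_METHODS):
                cell_id = f"{sp}/{level}/{shape}/{sampling}"
                fam_seed = (
                    cfg.master_seed
                    + _FAMILY_STRIDE * (1 + sp_idx * 10 + fam_idx * 2 + s_idx)
                )
                t_cell = time.time()
                try:
                    feats = features.build_feature_table(
                        system, stack, sampling, seed=fam_seed, labels=labels
                    )
                    keep = feats.index.intersection([r.psu_id for r in records])
                    recs = [r for r in records if r.psu_id in set(keep)]
                    mcfg = ModelConfig(
                        n_trees=cfg.model.n_trees,
                        mtry_rule=cfg.model.mtry_rule,
                        train_fraction=cfg.model.train_fraction,
                        n_replicates=cfg.model.n_replicates,
                        seed=fam_seed,
                    )
                    reps, summary = run_replicates(
                        feats.loc[keep], recs, stack, mcfg
                    )
                    maps[(sp, level, shape, sampling)] = summary
                    for rep in reps:
                        pairs = evaluation.paired_obs_pred(
                            rep.prediction, system, recs, stack,
                            cfg.density_offset, psu_ids=rep.eval_ids,
                            labels=labels,
                        )
                        strat = evaluation.area_stratified_metrics(pairs, scheme)
                        for _, mrow in strat.iterrows():
                            rows.append(dict(
                                species=sp, level=level, shape=shape,
                                sampling=sampling, replicate=rep.replicate_id,
                                metric=mrow["metric"],
                                area_class=mrow["area_class"],
                                value=mrow["value"],
                            ))
                        cor_down = evaluation.downscaling_precision(
                            rep.prediction, village_system, v_records, stack,
                            cfg.density_offset, labels=village_labels,
                        )
                        rows.append(dict(
                            species=sp, level=level, shape=shape,
                            sampling=sampling, replicate=rep.replicate_id,
                            metric="COR_down", area_class="all",
                            value=cor_down,
                        ))
                    status.append(dict(cell=cell_id, status="ok",
                                       seconds=round(time.time() - t_cell, 2)))
                except Exception as exc:  # keep remaining cells running
                    logger.exception("cell %s failed", cell_id)
                    status.append(dict(cell=cell_id, status=f"error: {exc}",
                                       seconds=round(time.time() - t_cell, 2)))

    table = pd.DataFrame(rows)
    cell_status = pd.DataFrame(status)
    logger.info("sensitivity run finished in %.1f s", time.time() - t0)

    result = ExperimentResult(
        table=table, stack=stack, villages=villages, systems=systems,
        summary_maps=maps, cell_status=cell_status, provenance=provenance,
    )
    if cfg.outdir:
        write_artifacts(result, cfg)
    return result


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean ± sd per (species, level, shape, sampling, metric,
    area_class), mirroring the usual bar-plot-with-error-bars summary."""
    g = table.groupby(
        ["species", "level", "shape", "sampling", "metric", "area_class"],
        sort=True,
    )["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"std": "sd", "count": "n_replicates"})


def write_artifacts(result: ExperimentResult, cfg: ExperimentConfig) -> None:
    """Write the table, summaries, zonations, maps and manifest to outdir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "sensitivity_table.csv", index=False)
    summarize(result.table).to_csv(out / "sensitivity_summary.csv", index=False)
    result.cell_status.to_csv(out / "cell_status.csv", index=False)
    landscape.villages_to_csv(result.villages, out / "villages.csv")
    landscape.villages_to_geojson(result.villages, out / "villages.geojson")
    for (level, shape), system in result.systems.items():
        zonation.system_to_geojson(system, out / f"zonation_{level}_{shape}.geojson")
    for name, layer in result.stack.layers.items():
        write_raster(out / f"{name}.tif", layer, result.stack.spec)
    write_raster(out / "mask.tif", result.stack.mask.astype(float),
                 result.stack.spec)
    for (sp, level, shape, sampling), summary in result.summary_maps.items():
        stem = f"{sp}_{level}_{shape}_{sampling}"
        write_raster(out / f"mean_{stem}.tif", summary.mean_map, summary.spec)
        write_raster(out / f"sd_{stem}.tif", summary.sd_map, summary.spec)
    pd.Series(result.provenance).to_json(out / "provenance.json")


def export_maps(result: ExperimentResult, bboxes: list[tuple[float, float, float, float]],
                outdir: str | Path, offset: float | None = None) -> list[Path]:
    """Observed-vs-predicted map panels and value histograms per bbox.

    For each bounding box ``(xmin, ymin, xmax, ymax)`` and each summary
    map, writes a PNG with the observed village-density raster beside
    the replicate-mean prediction, plus histograms of the two value
    distributions with their means marked.  An empty bbox list writes
    nothing; a bbox outside the region is an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if offset is None:
        offset = census.DENSITY_OFFSET
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = result.stack
    spec = stack.spec
    rxmin, rymin, rxmax, rymax = spec.bounds
    written: list[Path] = []

    village_system = result.systems[("village", "IRR")]
    labels = census.label_raster(village_system, stack)
    species = sorted({s for v in result.villages for s in v.counts})
    obs_maps: dict[str, np.ndarray] = {}
    areas = census.suitable_areas_all(village_system, stack, labels)
    for sp in species:
        counts = census.aggregate_counts(result.villages, village_system, sp)
        recs, _ = census.make_response(counts, areas, offset)
        dens = {r.psu_id: r.log_density for r in recs}
        obs = np.full(spec.shape, np.nan)
        for k, p in enumerate(village_system.psus):
            if p.id in dens:
                obs[labels == k] = dens[p.id]
        obs_maps[sp] = obs

    for b_idx, (xmin, ymin, xmax, ymax) in enumerate(bboxes):
        if xmin < rxmin or ymin < rymin or xmax > rxmax or ymax > rymax:
            raise ValueError(f"bbox {b_idx} extends outside the region")
        i0, j0 = spec.index_of(xmin, ymin)
        i1 = min(spec.nrows, int(np.ceil((ymax - spec.y0) / spec.cell)))
        j1 = min(spec.ncols, int(np.ceil((xmax - spec.x0) / spec.cell)))
        for (sp, level, shape, sampling), summary in result.summary_maps.items():
            obs_win = obs_maps[sp][i0:i1, j0:j1]
            pred_win = summary.mean_map[i0:i1, j0:j1]
            fig, axes = plt.subplots(2, 2, figsize=(9, 8))
            for ax, win, title in (
                (axes[0, 0], obs_win, "observed (village log10 density)"),
                (axes[0, 1], pred_win, "predicted mean (log10 density)"),
            ):
                im = ax.imshow(win, origin="lower",
                               extent=(xmin, xmax, ymin, ymax))
                ax.set_title(title, fontsize=9)
                fig.colorbar(im, ax=ax, shrink=0.8)
            for ax, win, title in (
                (axes[1, 0], obs_win, "observed values"),
                (axes[1, 1], pred_win, "predicted values"),
            ):
                vals = win[np.isfinite(win)]
                if vals.size:
                    ax.hist(vals, bins=30, color="0.6")
                    ax.axvline(vals.mean(), color="tab:blue", lw=1.5)
                ax.set_title(title, fontsize=9)
            fig.suptitle(f"{sp} {level}/{shape}/{sampling} bbox{b_idx}",
                         fontsize=10)
            fig.tight_layout()
            path = outdir / f"bbox{b_idx}_{sp}_{level}_{shape}_{sampling}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
    return written
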