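"""End-to-end orchestration: synthetic world -> traits -> grid -> models.

Stages run in dependency order, each writing its CSV interface with a
provenance header (run hash + seed); re-running with the same configuration
and seed reproduces identical tables.  Stage functions are importable on
their own so the command-line interface can run them independently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import environment as env_mod
from . import io as io_mod
from . import stats as stats_mod
from .grid import (EqualAreaGrid, PresenceGrid, assemblage_mean, make_grid,
                   merge_ranges_by_complex, quantile_bins, rasterize_ranges)
from .lightness import ExclusionRecord, SpeciesTrait, complex_average, \
    species_lightness, traits_to_frame
from .synth import SynthConfig, SynthWorld, gen_world, render_species_images

log = logging.getLogger("melanomap")

DEFAULT_CONTINENTS = {"west": {}, "east": {"tmp_south": 22.0, "tmp_north": -8.0}}


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``continents`` (synthetic worlds)
    or ``data_paths`` (on-disk images/ranges/rasters) must be set."""

    seed: int = 0
    out_dir: Path = Path("melanomap_out")
    continents: dict[str, dict] | None = field(
        default_factory=lambda: dict(DEFAULT_CONTINENTS))
    data_paths: dict[str, dict] | None = None
    cell_size: float = 50_000.0
    min_richness: int = 5
    alpha: float = 0.001
    delta_threshold: float = 0.1
    k_bins: int = 10
    run_gls: bool = True
    gls_max_n: int = 400
    gls_variables: tuple[str, ...] = ("TMP",)
    image_shape: tuple[int, int] = (320, 440)
    complex_map: dict[str, str] = field(default_factory=dict)
    save_images: bool = False
    save_maps: bool = True

    def __post_init__(self) -> None:
        if (self.continents is None) == (self.data_paths is None):
            raise ValueError("exactly one of continents / data_paths required")
        for name, val in [("cell_size", self.cell_size),
                          ("min_richness", self.min_richness),
                          ("alpha", self.alpha),
                          ("delta_threshold", self.delta_threshold),
                          ("k_bins", self.k_bins)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        self.out_dir = Path(self.out_dir)
        self.image_shape = tuple(self.image_shape)      # YAML gives lists
        self.gls_variables = tuple(self.gls_variables)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def run_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")        # where outputs land is not part of the run
        return io_mod.config_hash(d)


def continent_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed (< 2^31) for the index-th continent."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2 ** 31))


def synth_config_for(config: PipelineConfig, name: str) -> SynthConfig:
    names = sorted(config.continents)
    overrides = dict(config.continents[name])
    overrides.setdefault("seed", continent_seed(config.seed, names.index(name)))
    return SynthConfig(**overrides)


# ---------------------------------------------------------------------------
# stages

def stage_traits(world: SynthWorld, image_shape: tuple[int, int],
                 complex_map: dict[str, str] | None = None
                 ) -> tuple[list[SpeciesTrait], list[ExclusionRecord],
                            list]:
    """Render every species' images and extract species-level traits."""
    traits: list[SpeciesTrait] = []
    exclusions: list[ExclusionRecord] = []
    renders = []
    for sp in world.pool:
        sp_renders = render_species_images(sp, world.config,
                                           image_shape=image_shape)
        renders.extend(sp_renders)
        result = species_lightness([r.image for r in sp_renders])
        if isinstance(result, ExclusionRecord):
            exclusions.append(result)
        else:
            traits.append(result)
    if complex_map:
        traits = complex_average(traits, complex_map)
    log.info("traits: %d species scored, %d excluded",
             len(traits), len(exclusions))
    return traits, exclusions, renders


def stage_grid(world: SynthWorld, traits: list[SpeciesTrait],
               config: PipelineConfig
               ) -> tuple[EqualAreaGrid, PresenceGrid, pd.DataFrame]:
    """Grid the extent, rasterize ranges, compute assemblage means."""
    x0, y0, x1, y1 = world.config.extent
    grid = make_grid(shapely.box(x0, y0, x1, y1),
                     cell_size=config.cell_size, crs=world.config.crs)
    geoms = {sid: r.polygon for sid, r in world.ranges.items()}
    if config.complex_map:
        geoms = merge_ranges_by_complex(geoms, config.complex_map)
    trait_ids = {t.species_id for t in traits}
    geoms = {sid: g for sid, g in geoms.items() if sid in trait_ids}
    presence = rasterize_ranges(geoms, grid)

    trait_map = {t.species_id: t for t in traits}
    families = sorted({t.family for t in traits})
    tables = []
    for side in ("dorsal", "ventral"):
        for scope in ["all"] + families:
            res = assemblage_mean(presence, trait_map, side=side,
                                  family_scope=scope,
                                  min_richness=config.min_richness)
            log.info("assemblage %s/%s: %d cells kept, %d excluded",
                     side, scope, len(res.table), res.n_cells_excluded)
            tables.append(res.table)
    return grid, presence, pd.concat(tables, ignore_index=True)


def stage_environment(world: SynthWorld, grid: EqualAreaGrid) -> pd.DataFrame:
    return env_mod.build_cell_environment(world.climate.monthly, grid)


def stage_stats(assemblages: dict[str, pd.DataFrame],
                environments: dict[str, pd.DataFrame],
                families: list[str], config: PipelineConfig,
                grids: dict[str, EqualAreaGrid] | None = None
                ) -> tuple[list, pd.DataFrame]:
    """Model battery plus (optionally) spatial GLS per continent."""
    records = stats_mod.table1_battery(
        assemblages, environments, sorted(assemblages), families,
        alpha=config.alpha, delta_threshold=config.delta_threshold)

    gls_rows = []
    if config.run_gls and grids is not None:
        for cont in sorted(assemblages):
            grid = grids[cont]
            centers = pd.DataFrame(grid.cell_centers() / 1000.0,
                                   columns=["x_km", "y_km"])
            centers["cell_id"] = grid.cell_ids
            for side in ("dorsal", "ventral"):
                sub = assemblages[cont]
                sub = sub[(sub["family_scope"] == "all")
                          & (sub["side"] == side)]
                merged = sub.merge(environments[cont], on="cell_id") \
                    .merge(centers, on="cell_id")
                for var in config.gls_variables:
                    data = merged[["mean_lightness", var, "x_km",
                                   "y_km", "cell_id"]].dropna()
                    if len(data) < 10:
                        continue
                    rec = stats_mod.fit_gls_spatial(
                        data["mean_lightness"].to_numpy(),
                        data[var].to_numpy(),
                        data[["x_km", "y_km"]].to_numpy(),
                        max_n=config.gls_max_n, seed=config.seed,
                        cell_ids=data["cell_id"].tolist())
                    gls_rows.append({
                        "continent": cont, "side": side, "variable": var,
                        "slope": rec.params[1], "slope_se": rec.bse[1],
                        "rho_km": rec.rho_km, "loglik": rec.loglik,
                        "n_cells_used": rec.n_cells_used,
                        "subsampled": rec.subsampled})
                    log.info("GLS %s/%s/%s: slope=%.3f rho=%.1f km n=%d",
                             cont, side, var, rec.params[1], rec.rho_km,
                             rec.n_cells_used)
    return records, pd.DataFrame(gls_rows)


def render_maps(assemblages: pd.DataFrame, grid: EqualAreaGrid,
                k_bins: int, out_dir: Path, continent: str = "") -> list[Path]:
    """Quantile choropleths, red = lightest bin, blue = darkest bin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    cell_pos = {cid: (r, c) for cid, r, c in
                zip(grid.cell_ids, grid.rows, grid.cols)}
    paths = []
    for (side, scope), sub in assemblages.groupby(["side", "family_scope"]):
        if sub.empty:
            log.warning("map %s/%s skipped: empty scope", side, scope)
            continue
        values = sub["mean_lightness"].to_numpy()
        if np.all(values == values[0]):
            log.warning("map %s/%s: constant lightness field", side, scope)
        k = min(k_bins, max(2, len(np.unique(values))))
        bins = (quantile_bins(values, k) if len(np.unique(values)) > 1
                else np.zeros(len(values), dtype=int))
        nrows = int(grid.rows.max()) + 1
        ncols = int(grid.cols.max()) + 1
        img = np.full((nrows, ncols), np.nan)
        for cid, b in zip(sub["cell_id"], bins):
            r, c = cell_pos[cid]
            img[r, c] = b
        fig, ax = plt.subplots(figsize=(6, 4.5))
        cmap = plt.get_cmap("RdBu_r", k)   # high bin (lightest) -> red
        im = ax.imshow(img, origin="lower", cmap=cmap, vmin=-0.5, vmax=k - 0.5)
        edges = np.quantile(values, np.arange(1, k) / k)
        ax.set_title(f"{continent} {scope} {side} mean lightness "
                     f"({k} quantile bins)")
        cbar = fig.colorbar(im, ax=ax, ticks=range(k))
        cbar.set_label("quantile bin (blue=dark, red=light); edges: "
                       + ", ".join(f"{e:.1f}" for e in edges), fontsize=6)
        path = out_dir / f"map_{continent}_{scope}_{side}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# full run

@dataclass
class PipelineResult:
    config: PipelineConfig
    worlds: dict[str, SynthWorld]
    traits: dict[str, list[SpeciesTrait]]
    exclusions: dict[str, list[ExclusionRecord]]
    grids: dict[str, EqualAreaGrid]
    presence: dict[str, PresenceGrid]
    assemblages: dict[str, pd.DataFrame]
    environments: dict[str, pd.DataFrame]
    model_records: list
    gls_table: pd.DataFrame
    contrasts: list
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in dependency order and write the output bundle."""
    if config.data_paths is not None:
        raise NotImplementedError(
            "real-data runs: use the stage functions with pre-loaded inputs; "
            "the bundled driver covers synthetic worlds")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    rh = config.run_hash()

    try:
        worlds, traits, exclusions = {}, {}, {}
        grids, presence, assemblages, environments = {}, {}, {}, {}
        for name in sorted(config.continents):
            scfg = synth_config_for(config, name)
            log.info("continent %s: synth seed %d", name, scfg.seed)
            world = gen_world(scfg)
            worlds[name] = world
            cdir = out / name
            cdir.mkdir(exist_ok=True)

            tr, ex, renders = stage_traits(world, config.image_shape,
                                           config.complex_map or None)
            traits[name], exclusions[name] = tr, ex
            if config.save_images:
                img_dir = cdir / "specimens"
                img_dir.mkdir(exist_ok=True)
                for rend in renders:
                    im = rend.image
                    stem = f"{im.species_id}_{im.side}_{im.morph_id}"
                    io_mod.write_specimen_png(im, img_dir / f"{stem}.png")
                    io_mod.write_mask_png(im.roi_mask,
                                          img_dir / f"{stem}_mask.png")
            io_mod.write_table(traits_to_frame(tr), cdir / "traits.csv",
                               run_hash=rh, seed=config.seed)
            io_mod.write_table(
                pd.DataFrame([{"species_id": e.species_id, "reason": e.reason}
                              for e in ex]),
                cdir / "exclusions.csv", run_hash=rh, seed=config.seed)

            grid, pres, asm = stage_grid(world, tr, config)
            grids[name], presence[name], assemblages[name] = grid, pres, asm
            io_mod.write_table(grid.to_frame(), cdir / "grid.csv",
                               run_hash=rh, seed=config.seed)
            io_mod.write_table(pres.to_triplets(),
                               cdir / "presence_triplets.csv",
                               run_hash=rh, seed=config.seed)
            io_mod.write_table(asm, cdir / "assemblages.csv",
                               run_hash=rh, seed=config.seed)
            io_mod.write_ranges_geojson(
                {sid: r.polygon for sid, r in world.ranges.items()},
                cdir / "ranges.geojson", crs=world.config.crs)

            env = stage_environment(world, grid)
            environments[name] = env
            io_mod.write_table(env, cdir / "environment.csv",
                               run_hash=rh, seed=config.seed)

            if config.save_maps:
                render_maps(asm, grid, config.k_bins, cdir / "maps",
                            continent=name)

        families = sorted({t.family for tr in traits.values() for t in tr})
        records, gls_table = stage_stats(assemblages, environments, families,
                                         config, grids)
        io_mod.write_table(stats_mod.records_to_frame(records),
                           out / "model_table.csv", run_hash=rh,
                           seed=config.seed)
        io_mod.write_table(gls_table, out / "gls.csv", run_hash=rh,
                           seed=config.seed)

        contrasts = []
        for name in sorted(config.continents):
            contrasts.extend(
                stats_mod.tukey_side_family(traits[name], continent=name))
        io_mod.write_table(stats_mod.contrasts_to_frame(contrasts),
                           out / "side_contrasts.csv", run_hash=rh,
                           seed=config.seed)
        log.info("pipeline complete: %d model records, %d contrasts",
                 len(records), len(contrasts))
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    return PipelineResult(config=config, worlds=worlds, traits=traits,
                          exclusions=exclusions, grids=grids,
                          presence=presence, assemblages=assemblages,
                          environments=environments, model_records=records,
                          gls_table=gls_table, contrasts=contrasts,
                          out_dir=out)
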