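"""End-to-end orchestration: simulate or ingest, tile, derive, fit, report.

``run_pipeline`` chains the full analysis — stem census, phylogeny and
DEM in (simulated or from files); quadrat grids at each grain; terrain
covariates; per-quadrat SR/PD/NRI/NTI under the randomization null;
Hegyi competition; and the mixed-effects coefficient grid — writing every
table as CSV into a run directory together with a manifest (config,
seeds, version) from which the run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from phylograin.competition import hegyi_ci, hegyi_ci_same_quadrat, quadrat_ci
from phylograin.forest_io import (
    DemGrid,
    LifeStage,
    QuadratGrid,
    build_community_matrix,
    prune_to_species,
    read_ascii_grid,
    read_newick,
    read_stem_table,
    write_ascii_grid,
    write_newick,
    write_stem_table,
)
from phylograin.models import ModelFit, build_design, coefficient_grid, fit_lmm
from phylograin.phylo import NullModelConfig, ses_metrics, stage_summary
from phylograin.synthetic import (
    AssemblyScenario,
    DbhModel,
    simulate_dem,
    simulate_phylogeny,
    simulate_stem_map,
)
from phylograin.terrain import compute_terrain_layers, quadrat_terrain

#: Stage groupings fitted per scale: whole community plus the three bins.
STAGE_GROUPS: tuple[str | None, ...] = (None, "sapling", "juvenile", "adult")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either the three input paths are given (census CSV, Newick tree,
    ESRI ASCII DEM) or a synthetic forest is generated from the scenario
    fields.  All randomness derives from ``seed``.
    """

    # inputs (None => simulate)
    stem_table: str | None = None
    tree: str | None = None
    dem: str | None = None
    # synthetic-forest settings
    n_species: int = 104
    n_stems: int = 20000
    scenario_mode: str = "neutral"
    scenario_intensity: float = 0.0
    env_covariate: str = "elevation"
    relief_amplitude: float = 30.0
    # analysis settings
    plot_side: float = 340.0
    scales: tuple[float, ...] = (2.5, 5.0, 10.0)
    block_scale: float = 20.0
    dem_cell: float = 5.0
    n_rand: int = 999
    ci_mode: str = "radius"  # or "quadrat"
    grouping: str = "dominant_species"  # or "block"
    fit_models: bool = True
    out_dir: str = "phylograin_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "scales" in data:
            data["scales"] = tuple(data["scales"])
        return cls(**data)


def _subseed(seed: int, k: int) -> int:
    return (seed * 10007 + k) % (2**31 - 1)


def dominant_species(table: pd.DataFrame, grid: QuadratGrid) -> pd.Series:
    """Species with the largest basal area (sum of DBH^2) per quadrat.

    Ties break to the lexicographically first species code; quadrats
    without stems are NaN.
    """
    ids = grid.assign(table["x"].to_numpy(), table["y"].to_numpy())
    frame = pd.DataFrame(
        {"quadrat": ids, "species": table["species"].to_numpy(),
         "ba": table["dbh_cm"].to_numpy() ** 2}
    )
    sums = frame.groupby(["quadrat", "species"], sort=True)["ba"].sum().reset_index()
    sums = sums.sort_values(["quadrat", "ba", "species"],
                            ascending=[True, False, True], kind="mergesort")
    dom = sums.drop_duplicates("quadrat").set_index("quadrat")["species"]
    return dom.reindex(range(grid.n_quadrats))


def validate_inputs(stem_path, tree_path, dem_path, plot_side: float) -> dict:
    """Cross-check the three inputs; returns a machine-readable report.

    Checks species agreement between census and tree, DEM coverage of
    the plot, the 1 cm DBH census floor, and coincident stem positions.
    Failures are listed, not raised.
    """
    failures: list[dict] = []
    table = tree = dem = None
    try:
        table = read_stem_table(stem_path, plot_side=plot_side)
    except Exception as exc:  # report, don't raise
        failures.append({"check": "stem_table", "detail": str(exc)})
    try:
        tree = read_newick(tree_path)
    except Exception as exc:
        failures.append({"check": "tree", "detail": str(exc)})
    try:
        dem = read_ascii_grid(dem_path)
    except Exception as exc:
        failures.append({"check": "dem", "detail": str(exc)})
    if table is not None and tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = sorted(set(table["species"]) - tips)
        if missing:
            failures.append({"check": "species_in_tree", "detail": f"missing: {missing}"})
    if dem is not None and not dem.covers(plot_side):
        failures.append({"check": "dem_coverage",
                         "detail": f"DEM does not cover [0, {plot_side}]^2"})
    if table is not None:
        xy = table[["x", "y"]].round(9)
        dup = xy.duplicated()
        if dup.any():
            failures.append({"check": "coincident_stems",
                             "detail": f"{int(dup.sum())} duplicated positions"})
    return {"ok": not failures, "failures": failures}


def build_metric_table(
    table: pd.DataFrame,
    tree,
    dem: DemGrid,
    config: PipelineConfig,
    log=lambda msg: None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quadrat metric table over all scales and stage groups.

    Returns ``(metrics, summary)`` where ``metrics`` joins SR/PD/NRI/NTI,
    terrain covariates, quadrat CI and the grouping column, and
    ``summary`` is the per scale x stage mean-NRI/NTI t-test table.
    """
    layers = compute_terrain_layers(dem)
    block_grid = QuadratGrid(config.plot_side, config.block_scale)
    all_rows = []
    ses_rows = []
    for si, scale in enumerate(config.scales):
        grid = QuadratGrid(config.plot_side, scale)
        terr = quadrat_terrain(layers, grid)
        if config.ci_mode == "radius":
            ci_records = hegyi_ci(table, radius=scale)
        elif config.ci_mode == "quadrat":
            ci_records = hegyi_ci_same_quadrat(table, grid)
        else:
            raise ValueError(f"unknown ci_mode {config.ci_mode!r}")
        if config.grouping == "dominant_species":
            group = dominant_species(table, grid)
        elif config.grouping == "block":
            group = pd.Series(
                grid.parent_ids(block_grid).astype(str), index=range(grid.n_quadrats)
            )
        else:
            raise ValueError(f"unknown grouping {config.grouping!r}")
        for gi, stage in enumerate(STAGE_GROUPS):
            cm = build_community_matrix(table, grid, stage=stage)
            cfg = NullModelConfig(
                n_rand=config.n_rand, seed=_subseed(config.seed, 100 + 10 * si + gi)
            )
            ses = ses_metrics(cm, tree, cfg)
            ses_rows.append(ses)
            ci_q = quadrat_ci(ci_records, table, grid, stage=stage)
            metr = ses.set_index("quadrat")
            metr = metr.join(terr).join(ci_q)
            metr["group"] = group
            metr = metr.rename(
                columns={"SR": "sr", "PD": "pd", "NRI": "nri", "NTI": "nti"}
            )
            metr = metr.reset_index()
            all_rows.append(metr)
            log(
                f"scale {scale} stage {stage or 'community'}: "
                f"{int((metr['sr'] > 0).sum())}/{len(metr)} occupied quadrats, "
                f"{int(metr['valid'].sum())} with defined NRI/NTI"
            )
    metrics = pd.concat(all_rows, ignore_index=True)
    summary = stage_summary(pd.concat(ses_rows, ignore_index=True))
    return metrics, summary


def fit_all_models(metrics: pd.DataFrame, config: PipelineConfig,
                   log=lambda msg: None) -> tuple[list[ModelFit], pd.DataFrame]:
    """Fit every response x scale x stage design that has enough rows."""
    fits: list[ModelFit] = []
    skipped = []
    for scale in config.scales:
        for stage in STAGE_GROUPS:
            stage_name = stage or "community"
            for response in ("sr", "pd", "nri", "nti"):
                try:
                    design = build_design(
                        metrics, response, scale=scale, stage=stage_name
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fits.append(fit_lmm(design))
                except ValueError as exc:
                    skipped.append(
                        {"response": response, "scale": scale,
                         "stage": stage_name, "reason": str(exc)}
                    )
                    log(f"skipped {response}@{scale}/{stage_name}: {exc}")
    if not fits:
        raise PipelineError("models: no design had enough rows to fit")
    return fits, pd.DataFrame(skipped)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full chain and write all artifacts to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{name}: {exc}") from exc

    def inputs():
        if config.stem_table and config.tree and config.dem:
            table = read_stem_table(config.stem_table, plot_side=config.plot_side)
            tree = read_newick(config.tree)
            dem = read_ascii_grid(config.dem)
        else:
            tree = simulate_phylogeny(config.n_species, _subseed(config.seed, 1))
            dem = simulate_dem(
                config.plot_side, config.dem_cell, config.relief_amplitude,
                _subseed(config.seed, 2),
            )
            scenario = AssemblyScenario(
                mode=config.scenario_mode,
                intensity=config.scenario_intensity,
                env_covariate=config.env_covariate,
                seed=_subseed(config.seed, 3),
            )
            table = simulate_stem_map(tree, dem, config.n_stems, DbhModel(), scenario)
            write_stem_table(table, out / "stems.csv")
            write_newick(tree, out / "tree.nwk")
            write_ascii_grid(dem, out / "dem.asc")
        if not dem.covers(config.plot_side):
            raise ValueError("DEM does not cover the plot")
        tree = prune_to_species(tree, set(table["species"]))
        log(f"inputs: {len(table)} stems, "
            f"{sum(1 for _ in tree.leaf_node_iter())} species on tree")
        return table, tree, dem

    table, tree, dem = stage("inputs", inputs)
    metrics, summary = stage(
        "metrics", lambda: build_metric_table(table, tree, dem, config, log)
    )
    metrics.to_csv(out / "metric_table.csv", index=False)
    summary.to_csv(out / "stage_summary.csv", index=False)

    if config.fit_models:
        fits, skipped = stage("models", lambda: fit_all_models(metrics, config, log))
        grid = coefficient_grid(fits)
        grid.to_csv(out / "coefficients.csv", index=False)
        if len(skipped):
            skipped.to_csv(out / "models_skipped.csv", index=False)

    from phylograin import __version__ as _version

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": _version,
        "log": log_lines,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
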