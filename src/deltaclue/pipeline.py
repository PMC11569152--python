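"""End-to-end orchestration on a synthetic study region.

``run_pipeline`` chains every stage — synthetic world, historic
transition analysis, scenario demand, suitability fitting, allocation,
validation — writing the legacy input bundle, per-year maps, a
convergence log and a machine-readable run manifest under a work
directory, all reproducible from the manifest's seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import AllocationParams, run_simulation
from .demand import DemandTable, build_trajectory
from .grid import ContinuousRaster, write_esri_ascii
from .history import apply_scenario_overrides, build_allow_matrix, count_transitions, derive_elasticity
from .legacy import LegacyBundle, write_legacy_inputs
from .scenarios import ScenarioConfig
from .suitability import fit_all_classes
from .synth import SyntheticWorld, gen_restriction_mask, make_world
from .validation import class_accuracies, confusion_matrix, multiresolution_accuracy, overall_accuracy

__all__ = ["PipelineResult", "run_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    world: SyntheticWorld
    bundle: LegacyBundle
    maps: dict
    convergence_log: pd.DataFrame
    validation: dict
    manifest: dict


def _demand_tables_from_shares(config: ScenarioConfig, areas_ha: pd.Series):
    """Scenario demand on the synthetic region: shares of the active area."""
    total = float(areas_ha.sum())
    codes = list(areas_ha.index)
    start = DemandTable(areas_ha.astype(float), total)
    # shift demand toward the scenario's urban share, keep ratios elsewhere
    urban = codes[0]
    urb = round(total * config.urban_share / 100.0) * 100.0
    rest = areas_ha.drop(urban)
    scale = (total - urb) / float(rest.sum())
    end_areas = {urban: urb}
    for c in rest.index:
        end_areas[c] = round(float(rest[c]) * scale / 100.0) * 100.0
    end_series = pd.Series(end_areas)[codes]
    end_series.iloc[-1] += total - float(end_series.sum())
    end = DemandTable(end_series, total)
    return start, end


def run_pipeline(
    config: ScenarioConfig,
    workdir,
    seed: int = 0,
    n_years: int | None = None,
    params: AllocationParams | None = None,
) -> PipelineResult:
    """Run the full pipeline for one scenario on a synthetic region."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    n_years = n_years if n_years is not None else min(config.n_years, 8)

    world = make_world(seed=seed)
    codes = world.landuse0.class_codes()
    cell_area = (world.spec.cellsize / 100.0) ** 2  # m -> ha

    # historic analysis
    table = count_transitions(world.history)
    elas = derive_elasticity(table, method="minmax")
    # elasticity 1.0 is reserved for frozen classes (the study's water);
    # an active class under changing demand cannot be fully immovable
    elas = elas.clip(upper=0.99)
    elas = apply_scenario_overrides(
        elas, {_code_of(codes, k): v for k, v in config.elasticity_overrides.items()}
    )
    allow = build_allow_matrix(table, min_count=0)

    # demand
    areas = pd.Series(world.landuse0.class_counts(codes), dtype=float) * cell_area
    start, end = _demand_tables_from_shares(config, areas)
    traj = build_trajectory(start, end, n_years)

    # suitability
    models = fit_all_classes(world.landuse0, world.drivers)

    # restrictions / preferences
    restricted = gen_restriction_mask(world.landuse0, config.restriction_fraction, seed=seed + 1)

    bundle = LegacyBundle(
        landuse0=world.landuse0,
        demand=traj.table,
        models=models,
        allow=allow,
        restriction=ContinuousRaster(
            world.spec, restricted.astype(float), name="restriction"
        ),
        locspec={},
        drivers=world.drivers,
        dynamic_drivers={},
        params={"scenario": config.name, "tolerance": "0.0035"},
    )
    write_legacy_inputs(bundle, workdir / "inputs")

    years = list(range(1, n_years + 1))
    traj_run = traj.table.iloc[1:].copy()
    traj_run.index = years
    maps, log = run_simulation(
        world.landuse0,
        years,
        traj_run,
        driver_provider=lambda year: world.drivers,
        models=models,
        elas={int(c): float(elas[c]) for c in elas.index},
        allow=allow,
        restrictions=restricted,
        params=params or AllocationParams(),
        cell_area_ha=cell_area,
    )
    outdir = workdir / "maps"
    outdir.mkdir(exist_ok=True)
    for year, m in maps.items():
        write_esri_ascii(m, outdir / f"cov_all.{year}")
    log.to_csv(workdir / "convergence_log.csv", index=False)

    final = maps[years[-1]]
    cm = confusion_matrix(final, world.landuse0)
    validation = {
        "overall_accuracy_pct": overall_accuracy(cm),
        "class_accuracies": class_accuracies(cm),
        "multiresolution": multiresolution_accuracy(final, world.landuse0, [1, 2, 5]),
    }
    validation["class_accuracies"].to_csv(workdir / "validation_accuracies.csv")

    manifest = {
        "scenario": config.name,
        "seed": int(seed),
        "n_years": int(n_years),
        "grid": [world.spec.nrows, world.spec.ncols],
        "class_codes": [int(c) for c in codes],
        "package_version": __version__,
        "final_areas_ha": {int(c): float(np.count_nonzero(final.values == c) * cell_area)
                           for c in codes},
        "demand_final_ha": {int(c): float(traj.table.iloc[-1][c]) for c in codes},
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(world, bundle, maps, log, validation, manifest)


def _code_of(codes, key):
    """Scenario overrides may use class names; synthetic worlds use codes."""
    from .datasets import CLASS_NAMES

    if isinstance(key, int) or str(key).isdigit():
        return int(key)
    for code, name in CLASS_NAMES.items():
        if name == key:
            return code if code in codes else codes[0]
    raise KeyError(key)
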