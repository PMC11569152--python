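"""CLUE-style competitive land-use allocation.

Each simulated year, every changeable cell is assigned the allowed class
with the highest total probability

    P(cell, k) = suitability(cell, k)
               + locspec_weight(k) * locspec(cell, k)
               + competition(k)
               + elasticity(k) * [k is the current class]

where the per-class competition scalar is adjusted iteratively — raised
for classes below their demanded area, lowered for classes above it —
until every class's allocated area lies within a relative tolerance of
its demand.  Elasticity rewards staying put; a class with elasticity 1.0
never yields its cells (the study's "changes are impossible" endpoint).
Restricted cells and frozen classes are copied through unchanged, and the
allow matrix rules out conversions never observed historically.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import CategoricalRaster
from .stack import DriverStack
from .suitability import SuitabilityModel, predict_suitability

__all__ = [
    "AllocationParams",
    "AllocationState",
    "NonConvergenceError",
    "InfeasibleAllocationError",
    "cell_probability",
    "allocate_year",
    "run_simulation",
]

_NEG = -1e18  # effective -inf for disallowed assignments


class NonConvergenceError(RuntimeError):
    """The competition loop hit max_iterations before meeting demand."""

    def __init__(self, msg: str, deviations: pd.Series | None = None):
        super().__init__(msg)
        self.deviations = deviations


class InfeasibleAllocationError(ValueError):
    """Demand exceeds the area reachable under the allow matrix/restrictions."""


@dataclasses.dataclass
class AllocationParams:
    """Engine tuning parameters (the study set these by trial and error).

    tolerance
        Max relative deviation of allocated from demanded area, per class.
    step_gain
        Competition-adjustment gain: each iteration adds
        ``step_gain * (demand - allocated) / demand`` to a class's
        competition scalar.
    locspec_weights
        Per-class weight on the location-specific preference raster.
    """

    tolerance: float = 0.0035
    max_iterations: int = 2000
    step_gain: float = 0.05
    locspec_weights: dict[int, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.step_gain <= 0:
            raise ValueError("step_gain must be > 0")
        if any(w < 0 for w in self.locspec_weights.values()):
            raise ValueError("locspec weights must be >= 0")


@dataclasses.dataclass
class AllocationState:
    """Mutable per-year simulation state."""

    landuse: CategoricalRaster
    age: np.ndarray  # years each cell has held its current class
    competition: dict[int, float]
    restricted: np.ndarray  # boolean mask; True = no change permitted
    year: int

    @classmethod
    def initial(
        cls,
        landuse: CategoricalRaster,
        restricted: np.ndarray | None = None,
        year: int = 0,
        age: np.ndarray | None = None,
    ) -> "AllocationState":
        if restricted is None:
            restricted = np.zeros(landuse.spec.shape, dtype=bool)
        if age is None:
            age = np.zeros(landuse.spec.shape, dtype=np.int64)
        comp = {int(c): 0.0 for c in landuse.class_codes()}
        return cls(landuse, age, comp, restricted.astype(bool), year)


def cell_probability(
    suitability: float,
    elas: float,
    locspec: float,
    competition: float,
    locspec_weight: float = 1.0,
    is_current: bool = False,
) -> float:
    """Total assignment probability of one (cell, class) pair."""
    return suitability + locspec_weight * locspec + competition + (elas if is_current else 0.0)


def _demand_in_cells(demand_row: pd.Series, n_active: int, cell_area_ha: float) -> pd.Series:
    """Convert ha demands to whole cells with exact conservation.

    Largest-remainder rounding, ties broken by class order, so the cell
    demands sum exactly to the active cell count.
    """
    raw = demand_row.astype(float) / cell_area_ha
    if abs(float(raw.sum()) - n_active) > 0.5:
        raise InfeasibleAllocationError(
            f"demand row sums to {raw.sum():.1f} cells but the active area is {n_active}"
        )
    base = np.floor(raw.to_numpy())
    short = int(round(n_active - base.sum()))
    rema = raw.to_numpy() - base
    order = np.argsort(-rema, kind="stable")
    cells = base.astype(np.int64)
    for i in order[:short]:
        cells[i] += 1
    return pd.Series(cells, index=demand_row.index)


def allocate_year(
    state: AllocationState,
    demand_row: pd.Series,  # ha per class code
    suitability: Mapping[int, np.ndarray],
    elas: Mapping[int, float],
    allow: pd.DataFrame,
    locspec: Mapping[int, np.ndarray] | None = None,
    params: AllocationParams | None = None,
    cell_area_ha: float = 100.0,
) -> tuple[AllocationState, dict]:
    """Allocate one year's demand; returns the new state and an iteration log.

    Raises :class:`InfeasibleAllocationError` when a class's demand
    exceeds the area that could possibly hold it under the allow matrix
    and restriction mask, and :class:`NonConvergenceError` when the
    competition loop exhausts ``max_iterations``.
    """
    params = params or AllocationParams()
    demand_row = demand_row.sort_index()  # internal order: ascending class code
    codes = [int(c) for c in demand_row.index]
    k = len(codes)
    lu = state.landuse
    spec = lu.spec
    active = lu.data_mask
    n_active = int(active.sum())
    demand_cells = _demand_in_cells(demand_row, n_active, cell_area_ha)

    restricted = state.restricted & active
    # cells whose class can never be left also hold fast
    immovable = restricted.copy()
    for c in codes:
        if float(elas[c]) >= 1.0:
            immovable |= active & (lu.values == c)
    movable = active & ~immovable

    flat_mov = np.flatnonzero(movable.ravel())
    cur = lu.values.ravel()[flat_mov]
    code_pos = {c: i for i, c in enumerate(codes)}
    cur_idx = np.array([code_pos[int(c)] for c in cur]) if flat_mov.size else np.empty(0, int)

    # fixed per-class counts from immovable cells
    fixed_counts = np.array(
        [int(np.count_nonzero(lu.values[immovable] == c)) for c in codes]
    )

    # feasibility: demand must not exceed the area reachable under the
    # allow matrix and restriction mask (elasticity-frozen cells still
    # count as reachable; an elasticity-1.0 class that must shrink
    # surfaces as non-convergence instead)
    allow_np = allow.loc[codes, codes].to_numpy()
    flat_unres = np.flatnonzero((active & ~restricted).ravel())
    unres_idx = np.array(
        [code_pos[int(c)] for c in lu.values.ravel()[flat_unres]], dtype=int
    ) if flat_unres.size else np.empty(0, int)
    for j, c in enumerate(codes):
        held = int(np.count_nonzero(lu.values[restricted] == c))
        convertible = int(np.count_nonzero(allow_np[unres_idx, j])) if flat_unres.size else 0
        reachable = held + convertible
        if demand_cells.iloc[j] > reachable:
            raise InfeasibleAllocationError(
                f"class {c}: demand {demand_cells.iloc[j]} cells exceeds the "
                f"reachable area {reachable}"
            )

    # static part of the probability matrix: suitability + weighted locspec
    base = np.empty((k, flat_mov.size))
    for j, c in enumerate(codes):
        row = suitability[c].ravel()[flat_mov].astype(float)
        if locspec is not None and c in locspec:
            row = row + params.locspec_weights.get(c, 1.0) * locspec[c].ravel()[flat_mov]
        base[j] = row
    # staying bonus and allow mask depend only on the current class
    stay_bonus = np.zeros((k, flat_mov.size))
    if flat_mov.size:
        stay_bonus[cur_idx, np.arange(flat_mov.size)] = np.array(
            [float(elas[c]) for c in codes]
        )[cur_idx]
        allowed = allow_np[cur_idx].T.astype(bool)  # (k, n_movable)
    else:
        allowed = np.ones((k, 0), dtype=bool)

    comp = np.array([state.competition.get(c, 0.0) for c in codes], dtype=float)
    target = demand_cells.to_numpy()
    assign = cur_idx
    log_iters = 0
    for it in range(1, params.max_iterations + 1):
        log_iters = it
        p = base + stay_bonus + comp[:, None]
        p[~allowed] = _NEG
        assign = np.argmax(p, axis=0)  # first max = lowest class code
        if flat_mov.size:
            keep = p[cur_idx, np.arange(flat_mov.size)] >= p[assign, np.arange(flat_mov.size)]
            assign = np.where(keep, cur_idx, assign)
        counts = fixed_counts + np.bincount(assign, minlength=k)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.where(
                target > 0,
                np.abs(counts - target) / np.maximum(target, 1),
                np.where(counts > 0, np.inf, 0.0),
            )
        if np.all(dev <= params.tolerance):
            break
        comp = comp + params.step_gain * (target - counts) / np.maximum(target, 1)
    else:
        worst = int(np.argmax(dev))
        raise NonConvergenceError(
            f"no convergence after {params.max_iterations} iterations; worst class "
            f"{codes[worst]} deviates {dev[worst]:.4f} (tolerance {params.tolerance})",
            deviations=pd.Series(dev, index=codes),
        )

    new_vals = lu.values.copy()
    code_arr = np.asarray(codes)
    new_vals.ravel()[flat_mov] = code_arr[assign]
    new_lu = CategoricalRaster(spec, new_vals)
    changed = new_vals != lu.values
    new_age = np.where(changed, 0, state.age + 1)
    new_age[~active] = 0
    new_state = AllocationState(
        landuse=new_lu,
        age=new_age,
        competition={c: float(comp[j]) for j, c in enumerate(codes)},
        restricted=state.restricted,
        year=state.year + 1,
    )
    log = {
        "year": new_state.year,
        "iterations": log_iters,
        "max_deviation": float(dev.max()),
        "allocated_cells": {c: int(counts[j]) for j, c in enumerate(codes)},
    }
    return new_state, log


def run_simulation(
    initial: CategoricalRaster,
    years: Sequence[int],
    trajectory: pd.DataFrame,  # index = year, columns = class codes, values = ha
    driver_provider: Callable[[int], DriverStack],
    models: SuitabilityModel,
    elas: Mapping[int, float],
    allow: pd.DataFrame,
    restrictions: np.ndarray | None = None,
    locspec: Mapping[int, np.ndarray] | None = None,
    params: AllocationParams | None = None,
    cell_area_ha: float = 100.0,
) -> tuple[dict[int, CategoricalRaster], pd.DataFrame]:
    """Fold the yearly allocation over a simulation period.

    Suitability is refreshed each year from that year's driver stack.
    Returns the map per year and a convergence log (year, iterations, max
    relative deviation).
    """
    state = AllocationState.initial(initial, restricted=restrictions, year=int(years[0]) - 1)
    maps: dict[int, CategoricalRaster] = {}
    logs = []
    for year in years:
        if year not in trajectory.index:
            raise KeyError(f"trajectory has no demand row for {year}")
        drivers = driver_provider(int(year))
        suit = {
            int(c): predict_suitability(models[int(c)], drivers).values
            for c in trajectory.columns
        }
        demand_row = trajectory.loc[year]
        try:
            state, log = allocate_year(
                state, demand_row, suit, elas, allow, locspec, params, cell_area_ha
            )
        except (NonConvergenceError, InfeasibleAllocationError) as err:
            raise type(err)(f"year {year}: {err}") from err
        state.year = int(year)
        log["year"] = int(year)
        maps[int(year)] = state.landuse
        logs.append(log)
    log_frame = pd.DataFrame(
        [{k: v for k, v in log.items() if k != "allocated_cells"} for log in logs]
    )
    return maps, log_frame
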