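"""Scenario demand construction and annual demand trajectories.

The allocation engine consumes a prescribed area (ha) per land-use class
per simulated year.  For each scenario the 2050 demand table is built from
a handful of published rules — an urban share of total land, a split of
the rural (pasture + crops) reduction, an intentional forest-planting
figure plus natural-succession gain, and non-forest nature as the
conservation remainder — then interpolated linearly from the 2018 stocks
to yearly demand rows.  All areas are kept on a 100 ha unit (the unit the
allocation engine uses), rounded half away from zero.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .grid import CategoricalRaster

__all__ = [
    "DemandTable",
    "DemandTrajectory",
    "SuccessionParams",
    "InfeasibleDemandError",
    "round_to_unit",
    "total_area",
    "share_demand",
    "split_rural",
    "succession_gain",
    "forest_demand",
    "nature_remainder",
    "build_trajectory",
]

#: Demand accounting unit (ha).
UNIT = 100.0


class InfeasibleDemandError(ValueError):
    """A demand rule produced a negative or non-conserving area."""


def round_to_unit(x: float, unit: float = UNIT) -> float:
    """Round to the nearest ``unit``, half away from zero."""
    return math.copysign(math.floor(abs(x) / unit + 0.5) * unit, x) if x else 0.0


@dataclasses.dataclass
class DemandTable:
    """Per-class area (ha) at one year; classes sum exactly to the total."""

    areas: pd.Series  # index = class name, values = ha
    total: float

    def __post_init__(self) -> None:
        self.areas = self.areas.astype(float)
        if (self.areas < 0).any():
            raise InfeasibleDemandError(f"negative demand: {dict(self.areas[self.areas < 0])}")
        if abs(float(self.areas.sum()) - self.total) > 1e-6:
            raise InfeasibleDemandError(
                f"class areas sum to {self.areas.sum():.1f}, not the total {self.total:.1f}"
            )

    def __getitem__(self, cls: str) -> float:
        return float(self.areas[cls])


@dataclasses.dataclass
class SuccessionParams:
    """Parameters of the abandoned-land-to-forest succession accounting.

    horizon_years
        Length of the simulated period (2018 to 2050 = 32 years).
    succession_lag
        Years from abandonment to closed forest (study default 30 — a low
        estimate chosen so some succession completes within the horizon).
    eligible_fraction
        Share of the abandoned/nature pool with succession potential.
    advanced_fraction
        Share of *existing* non-forest nature already far enough along to
        close within the horizon (unpublished degree of freedom; exposed
        as a parameter, default 0).
    planting_ha
        Intentional forest creation (ha) on top of natural succession.
    """

    horizon_years: float = 32.0
    succession_lag: float = 30.0
    eligible_fraction: float = 1.0
    advanced_fraction: float = 0.0
    planting_ha: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eligible_fraction <= 1.0:
            raise ValueError("eligible_fraction must lie in [0, 1]")
        if not 0.0 <= self.advanced_fraction <= 1.0:
            raise ValueError("advanced_fraction must lie in [0, 1]")
        if self.succession_lag < 0:
            raise ValueError("succession_lag must be >= 0")


def total_area(landuse: CategoricalRaster, cell_area_ha: float = 100.0) -> float:
    """Total active area (ha): non-nodata cells times the cell area."""
    return float(np.count_nonzero(landuse.data_mask)) * cell_area_ha


def share_demand(total_ha: float, share: float) -> float:
    """Demand from a share of total land, rounded to the nearest 100 ha."""
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must lie in [0, 1]")
    return round_to_unit(total_ha * share)


def split_rural(
    pasture_2018: float,
    crops_2018: float,
    rural_2050_total: float,
    pasture_fraction: float,
) -> tuple[float, float]:
    """Split a rural-area reduction between pasture and crops.

    ``pasture_fraction`` of the total reduction comes out of pasture, the
    remainder out of crops; both results round to the nearest 100 ha.
    """
    if not 0.0 <= pasture_fraction <= 1.0:
        raise ValueError("pasture_fraction must lie in [0, 1]")
    rural_2018 = pasture_2018 + crops_2018
    if rural_2050_total > rural_2018:
        raise InfeasibleDemandError("rural area cannot grow under a reduction split")
    reduction = rural_2018 - rural_2050_total
    pasture = round_to_unit(pasture_2018 - pasture_fraction * reduction)
    crops = round_to_unit(crops_2018 - (1.0 - pasture_fraction) * reduction)
    if pasture < 0 or crops < 0:
        raise InfeasibleDemandError("rural split produced a negative area")
    return pasture, crops


def succession_gain(
    abandoned_pool_ha: float,
    existing_nature_ha: float,
    params: SuccessionParams,
) -> float:
    """Forest gained (ha) over the horizon via succession plus planting.

    Land abandoned at a linear rate over the horizon becomes forest iff it
    was abandoned at least ``succession_lag`` years before the horizon
    end, so a fraction max(0, horizon - lag)/horizon of the eligible
    abandoned pool closes.  Existing nature contributes its eligible
    already-advanced share.
    """
    if abandoned_pool_ha < 0 or existing_nature_ha < 0:
        raise ValueError("pools must be >= 0")
    h, lag = params.horizon_years, params.succession_lag
    frac_in_time = max(0.0, h - lag) / h if h > 0 else 0.0
    gain_abandoned = params.eligible_fraction * abandoned_pool_ha * frac_in_time
    gain_existing = params.eligible_fraction * existing_nature_ha * params.advanced_fraction
    return gain_abandoned + gain_existing + params.planting_ha


def forest_demand(forest_2018: float, gain_ha: float) -> float:
    """2050 forest area: 2018 stock plus gain, nearest 100 ha."""
    if gain_ha < -forest_2018:
        raise InfeasibleDemandError("forest loss exceeds the 2018 stock")
    return round_to_unit(forest_2018 + gain_ha)


def nature_remainder(total_ha: float, other_classes: Mapping[str, float]) -> float:
    """Non-forest nature as the exact conservation remainder."""
    rem = total_ha - float(sum(other_classes.values()))
    if rem < 0:
        raise InfeasibleDemandError(
            f"other classes exceed the total by {-rem:.1f} ha; no land left for nature"
        )
    return rem


@dataclasses.dataclass
class DemandTrajectory:
    """Per-year demand rows (ha per class); every row sums to the total."""

    table: pd.DataFrame  # index = year, columns = class names
    total: float

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.table.index]

    def row(self, year: int) -> pd.Series:
        return self.table.loc[year]


def build_trajectory(
    start: DemandTable, end: DemandTable, n_years: int
) -> DemandTrajectory:
    """Linear interpolation from the start stocks to the end demands.

    Produces ``n_years + 1`` yearly rows.  Each interpolated row is
    rounded to the 100 ha unit and re-balanced so it sums exactly to the
    (shared) total, with the remainder assigned to the largest class.
    """
    if list(start.areas.index) != list(end.areas.index):
        raise ValueError("start and end tables must share the class set")
    if abs(start.total - end.total) > 1e-6:
        raise InfeasibleDemandError(
            f"start total {start.total:.1f} != end total {end.total:.1f}"
        )
    rows = []
    for t in range(n_years + 1):
        w = t / n_years if n_years else 1.0
        row = (1.0 - w) * start.areas + w * end.areas
        row = row.map(round_to_unit)
        resid = start.total - float(row.sum())
        if resid:
            row[row.idxmax()] += resid
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.RangeIndex(n_years + 1, name="year_index"))
    return DemandTrajectory(frame, start.total)
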