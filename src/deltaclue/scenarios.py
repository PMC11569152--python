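"""Scenario configurations and the per-scenario demand-table builder.

A :class:`ScenarioConfig` encodes one scenario's quantitative rules: the
urban share of total land, how the rural (pasture + crops) total is set
(either a rural share split by a pasture fraction, or direct per-class
areas where the study adjusted the published reduction by hand), the
forest gain, elasticity overrides, and the simulation years.  The four
Dutch One Health SSP rule sets ship as built-ins.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import pandas as pd

from .demand import (
    DemandTable,
    DemandTrajectory,
    build_trajectory,
    forest_demand,
    nature_remainder,
    share_demand,
    split_rural,
)

__all__ = ["ScenarioConfig", "build_demand_table", "builtin_scenarios", "NL_SCENARIOS"]

_CLASS_ORDER = ["urban", "pasture", "crops", "forest", "non_forest_nature"]


@dataclasses.dataclass
class ScenarioConfig:
    """Quantitative rule set of one scenario.

    Exactly one of (``rural_share`` + ``rural_pasture_fraction``) or
    (``pasture_2050_ha`` + ``crops_2050_ha``) must be given; forest is
    2018 stock plus ``forest_gain_ha``; non-forest nature is always the
    conservation remainder.
    """

    name: str
    urban_share: float
    rural_share: float | None = None
    rural_pasture_fraction: float | None = None
    pasture_2050_ha: float | None = None
    crops_2050_ha: float | None = None
    forest_gain_ha: float = 0.0
    nature_share: float | None = None  # informational; remainder rule governs
    elasticity_overrides: dict[str, float] = dataclasses.field(default_factory=dict)
    restriction_fraction: float = 0.0
    locspec_weights: dict[str, float] = dataclasses.field(default_factory=dict)
    year_start: int = 2018
    year_end: int = 2050

    def __post_init__(self) -> None:
        shares = [self.urban_share, self.rural_share or 0.0, self.nature_share or 0.0]
        if any(s < 0 for s in shares) or sum(shares) > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: shares must be >= 0 and sum to <= 1")
        by_split = self.rural_share is not None
        by_direct = self.pasture_2050_ha is not None
        if by_split == by_direct:
            raise ValueError(
                f"{self.name}: give either a rural share split or direct rural areas"
            )
        if by_split and self.rural_pasture_fraction is None:
            raise ValueError(f"{self.name}: rural share needs a pasture fraction")
        if by_direct and self.crops_2050_ha is None:
            raise ValueError(f"{self.name}: direct rural areas need both classes")
        if self.year_start >= self.year_end:
            raise ValueError(f"{self.name}: year_start must precede year_end")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start


def build_demand_table(config: ScenarioConfig, areas_2018: Mapping[str, float]) -> DemandTable:
    """Apply one scenario's rules to the 2018 stocks.

    Order of operations: urban from its share of the total; pasture and
    crops from the rural rule; forest from the 2018 stock plus the
    scenario gain; non-forest nature as the exact remainder, so the table
    conserves total area by construction.
    """
    total = float(sum(areas_2018[c] for c in _CLASS_ORDER))
    urban = share_demand(total, config.urban_share)
    if config.rural_share is not None:
        rural_2050 = total * config.rural_share
        pasture, crops = split_rural(
            areas_2018["pasture"], areas_2018["crops"], rural_2050,
            config.rural_pasture_fraction,
        )
    else:
        pasture = float(config.pasture_2050_ha)
        crops = float(config.crops_2050_ha)
    forest = forest_demand(areas_2018["forest"], config.forest_gain_ha)
    others = {"urban": urban, "pasture": pasture, "crops": crops, "forest": forest}
    nature = nature_remainder(total, others)
    areas = pd.Series({**others, "non_forest_nature": nature})[_CLASS_ORDER]
    return DemandTable(areas, total)


def demand_trajectory(config: ScenarioConfig, areas_2018: Mapping[str, float]) -> DemandTrajectory:
    """Yearly demand rows from the 2018 stocks to the scenario's 2050 table."""
    total = float(sum(areas_2018[c] for c in _CLASS_ORDER))
    start = DemandTable(pd.Series(dict(areas_2018))[_CLASS_ORDER], total)
    end = build_demand_table(config, areas_2018)
    traj = build_trajectory(start, end, config.n_years)
    traj.table.index = pd.RangeIndex(config.year_start, config.year_end + 1, name="year")
    return traj


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """The four Dutch One Health SSP rule sets.

    SSP1 "Together Green": urban 17%; pasture/crops set directly (the
    study adjusted a published 31% grassland reduction for category
    differences); +100,000 ha planted forest.
    SSP3 "Our Town First": urban 15%, rural 65% with 80% of the reduction
    from pasture; ~25,000 ha succession forest; pasture and crops made
    stickier (elasticity 0.4) in this low-investment world.
    SSP4 "The Green Gulf": urban 17%; direct rural areas; 11,500 ha EU
    planting target plus ~23,000 ha succession.
    SSP5 "After us comes the Deluge": urban 21%, rural 64% with 60% of the
    reduction from pasture; ~9,500 ha succession forest.
    """
    return {
        "SSP1": ScenarioConfig(
            name="SSP1", urban_share=0.17, nature_share=0.21,
            pasture_2050_ha=750_000.0, crops_2050_ha=1_432_600.0,
            forest_gain_ha=100_000.0,
        ),
        "SSP3": ScenarioConfig(
            name="SSP3", urban_share=0.15, rural_share=0.65,
            rural_pasture_fraction=0.8, nature_share=0.20,
            forest_gain_ha=25_000.0,
            elasticity_overrides={"pasture": 0.4, "crops": 0.4},
        ),
        "SSP4": ScenarioConfig(
            name="SSP4", urban_share=0.17, nature_share=0.20,
            pasture_2050_ha=770_000.0, crops_2050_ha=1_448_100.0,
            forest_gain_ha=11_500.0 + 23_000.0,
        ),
        "SSP5": ScenarioConfig(
            name="SSP5", urban_share=0.21, rural_share=0.64,
            rural_pasture_fraction=0.6, nature_share=0.15,
            forest_gain_ha=9_500.0,
        ),
    }


#: Built-in scenario table, keyed by name.
NL_SCENARIOS = builtin_scenarios()
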