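"""Scenario demand tables from the published 2018 stocks and rules.

Builds the four SSP 2050 demand tables and their yearly trajectories,
writing the tables as CSV and each trajectory in the legacy demand.in1
dialect.
"""

from pathlib import Path

import pandas as pd

from deltaclue.datasets import AREAS_2018
from deltaclue.scenarios import NL_SCENARIOS, build_demand_table, demand_trajectory

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = {"2018": pd.Series(AREAS_2018)}
    for name in sorted(NL_SCENARIOS):
        config = NL_SCENARIOS[name]
        rows[name] = build_demand_table(config, AREAS_2018).areas
        traj = demand_trajectory(config, AREAS_2018)
        path = OUT / f"demand_{name}.in1"
        with open(path, "w") as fh:
            fh.write(f"{len(traj.table)}\n")
            for _, row in traj.table.iterrows():
                fh.write(" ".join(f"{v:.1f}" for v in row) + "\n")
    table = pd.DataFrame(rows).T
    table["total"] = table.sum(axis=1)
    table.to_csv(OUT / "demand_tables.csv", index_label="scenario")
    print("2050 demand tables (ha):")
    print(table.to_string(float_format=lambda v: f"{v:,.0f}"))
    print("\nevery scenario row conserves the 2018 total of 3,549,000 ha;")
    print("yearly demand.in1 trajectories written per scenario.")


if __name__ == "__main__":
    main()
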