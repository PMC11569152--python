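"""Build the synthetic study region and write its legacy input bundle.

The study's real inputs (a national land-cover series and gridded
drivers) are out of scope, so the analyses run on a 50x50 synthetic
region with known generating coefficients and transition rates.  This
script materialises that region and the model-file bundle under
results/world/, plus a ground-truth manifest for the recovery analyses.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from deltaclue.grid import ContinuousRaster
from deltaclue.history import build_allow_matrix, count_transitions
from deltaclue.legacy import LegacyBundle, write_legacy_inputs
from deltaclue.suitability import fit_all_classes
from deltaclue.synth import make_world

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "world"


def main() -> None:
    world = make_world(seed=SEED)
    codes = world.landuse0.class_codes()
    print(f"synthetic region: {world.spec.nrows}x{world.spec.ncols} cells, "
          f"classes {codes}, {len(world.history)} historic snapshots")
    print("class cell counts:", world.landuse0.class_counts())

    models = fit_all_classes(world.landuse0, world.drivers)
    table = count_transitions(world.history)
    allow = build_allow_matrix(table)
    areas = pd.Series(world.landuse0.class_counts(codes), dtype=float) * 100.0
    bundle = LegacyBundle(
        landuse0=world.landuse0,
        demand=pd.DataFrame([areas]),
        models=models,
        allow=allow,
        restriction=ContinuousRaster(world.spec, np.zeros(world.spec.shape),
                                     name="restriction"),
        locspec={},
        drivers=world.drivers,
        dynamic_drivers={},
        params={"seed": str(SEED)},
    )
    write_legacy_inputs(bundle, OUT)
    with open(OUT / "ground_truth.txt", "w") as fh:
        for code, (intercept, coefs) in world.true_coefficients.items():
            terms = " ".join(f"{n}:{v}" for n, v in coefs.items())
            fh.write(f"class {code} intercept {intercept} {terms}\n")
        for c in codes:
            fh.write(f"away_rate {c} {1 - world.true_transition_rates.loc[c, c]:.3f}\n")
    print(f"legacy bundle + ground truth written to {OUT}")


if __name__ == "__main__":
    main()
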