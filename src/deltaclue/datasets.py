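"""Published Dutch study inputs used by the pipeline.

These are the small printed tables of the 2018 Netherlands study region:
class coding, 2018 class areas, 1990-2018 historic change counts with the
conversion elasticities derived from them, and the 2018 validation
confusion matrix.  They are inputs to the demand builder, the elasticity
derivation and the validation metrics; everything gridded is out of scope
and emulated by :mod:`deltaclue.synth`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Land-use class codes; 4 is unused in the coding scheme.
CLASS_CODES: tuple[int, ...] = (0, 1, 2, 3, 5)
CLASS_NAMES: dict[int, str] = {
    0: "urban",
    1: "pasture",
    2: "crops",
    3: "forest",
    5: "non_forest_nature",
}
#: Water is frozen out of the analysis (it barely changed historically).
WATER_CODE: int = 6

#: 2018 land-use areas (ha) on the 1 km grid, water excluded.
AREAS_2018: dict[str, float] = {
    "urban": 538_000.0,
    "pasture": 1_055_800.0,
    "crops": 1_456_000.0,
    "forest": 302_400.0,
    "non_forest_nature": 196_800.0,
}

#: Number of 1 km cells that left each class, 1990-2018 (five map snapshots).
CHANGE_COUNTS_1990_2018: dict[str, int] = {
    "urban": 234,
    "pasture": 1630,
    "crops": 1678,
    "forest": 270,
    "non_forest_nature": 215,
    "water": 91,
}

#: Conversion elasticities as used by the study (0 = converts freely,
#: 1 = never converts), derived from the historic change counts.
ELASTICITY_NL: dict[str, float] = {
    "urban": 0.90,
    "pasture": 0.04,
    "crops": 0.01,
    "forest": 0.88,
    "non_forest_nature": 0.91,
    "water": 0.99,
}

_CM_ORDER = ["urban", "pasture", "crops", "forest", "non_forest_nature"]
#: 2018 validation confusion matrix (rows = model prediction,
#: columns = reference land cover), counts of 1 km cells.
CONFUSION_2018: pd.DataFrame = pd.DataFrame(
    np.array(
        [
            [4021, 738, 529, 46, 46],
            [430, 9457, 508, 28, 136],
            [802, 128, 13329, 137, 164],
            [89, 70, 50, 2735, 79],
            [37, 164, 142, 80, 1545],
        ],
        dtype=np.int64,
    ),
    index=pd.Index(_CM_ORDER, name="predicted"),
    columns=pd.Index(_CM_ORDER, name="reference"),
)


def class_code(name: str) -> int:
    for code, n in CLASS_NAMES.items():
        if n == name:
            return code
    raise KeyError(name)
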