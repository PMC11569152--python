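"""The legacy model-file bundle and its text dialects.

The allocation engine's inputs travel as a directory of small text files
(the layout the original CLUE-family executable consumes): the starting
land-use raster ``cov_all.0``, yearly demands ``demand.in1``, per-class
regression coefficients ``alloc1.reg``, the permitted-conversion matrix
``allow.txt``, parameters ``main.1``, a restriction raster
``region_all.fil``, per-class preference rasters ``locspec<code>.fil``,
predictor rasters ``sc1gr<index>.fil`` (static) or ``sc1gr<index>.<year>``
(dynamic) with ``predictor_names.txt`` mapping indices to names, and an
optional residence-time raster ``age.0``.

Dialects (fixed by this package, with round-trip tests):

``demand.in1``
    First line: number of years.  Then one line per year of
    whitespace-separated demands (ha) in ascending class-code order.
``alloc1.reg``
    Per class: a line ``classcode intercept n_predictors`` followed by
    ``n_predictors`` lines ``coefficient predictor_index``.
``allow.txt``
    K x K matrix of 0/1; row = from-class, column = to-class, ascending
    class-code order.
``main.1``
    ``key value`` pairs, one per line; ``class_codes`` and ``cell_area_ha``
    are always present.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, ContinuousRaster, FormatError, check_aligned, read_esri_ascii, write_esri_ascii
from .stack import DriverStack
from .suitability import ClassLogit, SuitabilityModel

__all__ = ["LegacyBundle", "MissingFileError", "ConsistencyError", "read_legacy_inputs", "write_legacy_inputs"]


class MissingFileError(FileNotFoundError):
    """A required bundle file is absent."""


class ConsistencyError(ValueError):
    """Class codes or dimensions disagree between bundle files."""


@dataclasses.dataclass
class LegacyBundle:
    """Typed content of a legacy input directory."""

    landuse0: CategoricalRaster
    demand: pd.DataFrame  # index = year index, columns = class codes, ha
    models: SuitabilityModel
    allow: pd.DataFrame  # 0/1, index/columns = class codes
    restriction: ContinuousRaster  # 1 = no change permitted
    locspec: dict[int, ContinuousRaster]
    drivers: DriverStack
    dynamic_drivers: dict[str, dict[int, ContinuousRaster]]
    params: dict[str, str]
    age: CategoricalRaster | None = None

    @property
    def class_codes(self) -> list[int]:
        return [int(c) for c in self.demand.columns]

    def validate(self) -> None:
        codes = self.class_codes
        if sorted(self.models.class_codes) != sorted(codes):
            raise ConsistencyError(
                f"regression classes {self.models.class_codes} != demand classes {codes}"
            )
        if [int(c) for c in self.allow.index] != codes:
            raise ConsistencyError("allow matrix classes disagree with demand classes")
        rasters = [self.landuse0, self.restriction, *self.locspec.values()]
        if self.age is not None:
            rasters.append(self.age)
        check_aligned(*rasters, self.drivers.spec)
        for name in {n for m in self.models.classes.values() for n in m.coefficients}:
            if name not in self.drivers and name not in self.dynamic_drivers:
                raise ConsistencyError(f"model driver {name!r} has no predictor raster")


def _require(directory: Path, name: str) -> Path:
    p = directory / name
    if not p.exists():
        raise MissingFileError(f"required bundle file missing: {p}")
    return p


def write_legacy_inputs(bundle: LegacyBundle, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.validate()
    codes = bundle.class_codes

    write_esri_ascii(bundle.landuse0, directory / "cov_all.0")

    with open(directory / "demand.in1", "w") as fh:
        fh.write(f"{len(bundle.demand)}\n")
        for _, row in bundle.demand.iterrows():
            fh.write(" ".join(f"{row[c]:.1f}" for c in codes) + "\n")

    names = bundle.drivers.names + [n for n in bundle.dynamic_drivers if n not in bundle.drivers.names]
    with open(directory / "predictor_names.txt", "w") as fh:
        for i, n in enumerate(names):
            fh.write(f"{i} {n}\n")

    with open(directory / "alloc1.reg", "w") as fh:
        for c in codes:
            m = bundle.models[c]
            fh.write(f"{c} {m.intercept!r} {len(m.coefficients)}\n")
            for name, coef in m.coefficients.items():
                fh.write(f"{coef!r} {names.index(name)}\n")

    with open(directory / "allow.txt", "w") as fh:
        for c in codes:
            fh.write(" ".join(str(int(bundle.allow.loc[c, d])) for d in codes) + "\n")

    params = dict(bundle.params)
    params["class_codes"] = ",".join(str(c) for c in codes)
    params.setdefault("cell_area_ha", "100")
    with open(directory / "main.1", "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} {v}\n")

    write_esri_ascii(bundle.restriction, directory / "region_all.fil", decimals=0)
    for c, r in bundle.locspec.items():
        write_esri_ascii(r, directory / f"locspec{c}.fil")
    for name, r in bundle.drivers.layers.items():
        write_esri_ascii(r, directory / f"sc1gr{names.index(name)}.fil")
    for name, series in bundle.dynamic_drivers.items():
        for year, r in series.items():
            write_esri_ascii(r, directory / f"sc1gr{names.index(name)}.{year}")
    if bundle.age is not None:
        write_esri_ascii(bundle.age, directory / "age.0")
    return directory


def read_legacy_inputs(directory) -> LegacyBundle:
    directory = Path(directory)
    landuse0 = read_esri_ascii(_require(directory, "cov_all.0"), categorical=True)

    lines = _require(directory, "demand.in1").read_text().splitlines()
    try:
        n_years = int(lines[0].split()[0])
    except (IndexError, ValueError) as err:
        raise FormatError("demand.in1: first line must be the number of years") from err
    rows = [[float(t) for t in line.split()] for line in lines[1 : n_years + 1]]
    if len(rows) != n_years:
        raise FormatError(f"demand.in1: expected {n_years} year lines, found {len(rows)}")

    name_lines = _require(directory, "predictor_names.txt").read_text().split()
    pred_names = {int(name_lines[i]): name_lines[i + 1] for i in range(0, len(name_lines), 2)}

    tokens = _require(directory, "alloc1.reg").read_text().split()
    models: dict[int, ClassLogit] = {}
    pos = 0
    while pos < len(tokens):
        code = int(tokens[pos])
        intercept = float(tokens[pos + 1])
        n_pred = int(tokens[pos + 2])
        pos += 3
        coefs = {}
        for _ in range(n_pred):
            coef = float(tokens[pos])
            idx = int(tokens[pos + 1])
            coefs[pred_names[idx]] = coef
            pos += 2
        models[code] = ClassLogit(code, intercept, coefs,
                                  candidate_set=tuple(coefs))
    codes = sorted(models)
    if any(len(r) != len(codes) for r in rows):
        raise ConsistencyError("demand.in1 column count disagrees with alloc1.reg classes")
    demand = pd.DataFrame(rows, columns=codes)
    demand.index.name = "year_index"

    allow_rows = [
        [int(t) for t in line.split()]
        for line in _require(directory, "allow.txt").read_text().splitlines()
        if line.strip()
    ]
    if len(allow_rows) != len(codes) or any(len(r) != len(codes) for r in allow_rows):
        raise ConsistencyError("allow.txt is not a K x K matrix over the model classes")
    allow = pd.DataFrame(allow_rows, index=codes, columns=codes)

    params = {}
    for line in _require(directory, "main.1").read_text().splitlines():
        if line.strip():
            k, _, v = line.partition(" ")
            params[k] = v.strip()

    region_files = sorted(directory.glob("region_*.fil"))
    if not region_files:
        raise MissingFileError(f"required bundle file missing: {directory / 'region_*.fil'}")
    restriction = read_esri_ascii(region_files[0], name="restriction")

    locspec = {}
    for p in sorted(directory.glob("locspec*.fil")):
        code = int(re.match(r"locspec(\d+)\.fil", p.name).group(1))
        locspec[code] = read_esri_ascii(p, name=f"locspec{code}")

    drivers = DriverStack(landuse0.spec)
    dynamic: dict[str, dict[int, ContinuousRaster]] = {}
    for p in sorted(directory.glob("sc1gr*.*")):
        m = re.match(r"sc1gr(\d+)\.(.+)", p.name)
        idx, suffix = int(m.group(1)), m.group(2)
        name = pred_names[idx]
        if suffix == "fil":
            drivers.add(read_esri_ascii(p, name=name))
        else:
            dynamic.setdefault(name, {})[int(suffix)] = read_esri_ascii(p, name=name)

    age_path = directory / "age.0"
    age = read_esri_ascii(age_path, categorical=True) if age_path.exists() else None

    bundle = LegacyBundle(
        landuse0=landuse0,
        demand=demand,
        models=SuitabilityModel(models),
        allow=allow,
        restriction=restriction,
        locspec=locspec,
        drivers=drivers,
        dynamic_drivers=dynamic,
        params=params,
        age=age,
    )
    bundle.validate()
    return bundle
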