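"""Rasters on the analysis grid and the Esri ASCII dialect.

Everything in the pipeline lives on one rectangular grid (the study uses a
1 km grid in a projected metric CRS, EPSG:28992).  A raster is a
:class:`GridSpec` plus a 2-D array in row-major order from the northwest
corner; a cell value refers to the whole cell.  Two rasters are *aligned*
iff every spec field except the nodata sentinel is equal, and every
pipeline stage rejects unaligned inputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "Raster",
    "CategoricalRaster",
    "ContinuousRaster",
    "AlignmentError",
    "FormatError",
    "DimensionError",
    "read_esri_ascii",
    "write_esri_ascii",
    "check_aligned",
]

DEFAULT_NODATA = -9999.0

#: Esri ASCII header keys, in canonical write order.
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class AlignmentError(ValueError):
    """Two rasters do not share the same grid."""


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class DimensionError(ValueError):
    """Value count or shape disagrees with the declared dimensions."""


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    ncols, nrows
        Grid dimensions (>= 1).
    xll, yll
        Coordinates (m) of the lower-left corner of the lower-left cell.
    cellsize
        Cell edge length in metres (> 0); the study grid uses 1000 m.
    nodata
        Sentinel value marking cells outside the study region.
    crs_code
        Label only; no reprojection is ever performed.
    """

    ncols: int
    nrows: int
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1000.0
    nodata: float = DEFAULT_NODATA
    crs_code: str = "EPSG:28992"

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def aligned_with(self, other: "GridSpec") -> bool:
        """Equality of all fields except the nodata sentinel."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
            and self.crs_code == other.crs_code
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (nrows, ncols), row 0 = north."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        y = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)


@dataclasses.dataclass
class Raster:
    """Base raster: a spec plus a matching 2-D value array."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise DimensionError(
                f"value array shape {self.values.shape} does not match grid "
                f"shape {self.spec.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata

    @property
    def data_mask(self) -> np.ndarray:
        return ~self.nodata_mask


@dataclasses.dataclass
class CategoricalRaster(Raster):
    """Integer class map; the land-use state at one time.

    Class codes follow the study coding 0=Urban, 1=Pasture, 2=Crops,
    3=Forest, 5=Non-forest nature (4 unused), 4/6=extensions permitted.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64, copy=False)

    def class_codes(self) -> list[int]:
        """Sorted class codes present (excluding nodata)."""
        vals = self.values[self.data_mask]
        return sorted(int(v) for v in np.unique(vals))

    def class_counts(self, codes=None) -> dict[int, int]:
        vals = self.values[self.data_mask]
        if codes is None:
            codes = np.unique(vals)
        return {int(c): int(np.count_nonzero(vals == c)) for c in codes}


@dataclasses.dataclass
class ContinuousRaster(Raster):
    """Real-valued driver raster; finite everywhere off nodata."""

    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.float64, copy=False)
        off = self.values[self.data_mask]
        if off.size and not np.all(np.isfinite(off)):
            raise ValueError(f"driver {self.name!r} has non-finite values off nodata")


def check_aligned(*rasters: Raster | GridSpec) -> GridSpec:
    """Return the shared spec, raising :class:`AlignmentError` on any mismatch."""
    specs = [r if isinstance(r, GridSpec) else r.spec for r in rasters]
    if not specs:
        raise ValueError("no rasters given")
    first = specs[0]
    for s in specs[1:]:
        if not first.aligned_with(s):
            raise AlignmentError(f"grids are not aligned: {first} vs {s}")
    return first


def read_esri_ascii(
    path,
    categorical: bool = False,
    name: str = "",
    units: str = "",
    crs_code: str = "EPSG:28992",
) -> CategoricalRaster | ContinuousRaster:
    """Read an Esri ASCII grid (.asc).

    The file must begin with the six header keys ``ncols nrows xllcorner
    yllcorner cellsize nodata_value`` (case-insensitive, one per line),
    followed by ``nrows x ncols`` whitespace-separated numbers in row-major
    order from the northwest corner.
    """
    path = Path(path)
    text = path.read_text()
    tokens = text.split()
    header: dict[str, float] = {}
    pos = 0
    # header: key/value pairs until a bare number appears in key position
    while pos + 1 < len(tokens) and len(header) < len(_HEADER_KEYS):
        key = tokens[pos].lower()
        if key not in _HEADER_KEYS:
            break
        header[key] = float(tokens[pos + 1])
        pos += 2
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: malformed Esri ASCII header, missing {missing}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    spec = GridSpec(
        ncols=ncols,
        nrows=nrows,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header["nodata_value"],
        crs_code=crs_code,
    )
    body = tokens[pos:]
    if len(body) != ncols * nrows:
        raise DimensionError(
            f"{path}: expected {ncols * nrows} values, found {len(body)}"
        )
    values = np.array([float(t) for t in body]).reshape(nrows, ncols)
    if categorical:
        ivals = values.astype(np.int64)
        if not np.array_equal(ivals, values):
            raise FormatError(f"{path}: non-integer values in categorical raster")
        return CategoricalRaster(
            dataclasses.replace(spec, nodata=float(int(spec.nodata))), ivals
        )
    return ContinuousRaster(spec, values, name=name or path.stem, units=units)


def write_esri_ascii(raster: Raster, path, decimals: int | None = None) -> Path:
    """Write a raster as an Esri ASCII grid; round-trips through the reader.

    Categorical rasters are written as integers regardless of ``decimals``;
    continuous values are fixed to ``decimals`` places (trailing zeros
    trimmed), so the round trip is exact to that precision.  With
    ``decimals=None`` values are written at full precision (``repr``) and
    the round trip is bit-exact.
    """
    if decimals is not None and decimals < 0:
        raise ValueError("decimals must be >= 0")
    path = Path(path)
    spec = raster.spec
    is_cat = isinstance(raster, CategoricalRaster)
    nodata = int(spec.nodata) if is_cat else spec.nodata

    def fmt(v) -> str:
        if is_cat:
            return str(int(v))
        if decimals is None:
            return repr(float(v))
        if v == spec.nodata:
            return _trim(f"{spec.nodata:.{max(decimals, 0)}f}")
        return _trim(f"{v:.{decimals}f}")

    lines = [
        f"ncols {spec.ncols}",
        f"nrows {spec.nrows}",
        f"xllcorner {_trim(f'{spec.xll:.6f}')}",
        f"yllcorner {_trim(f'{spec.yll:.6f}')}",
        f"cellsize {_trim(f'{spec.cellsize:.6f}')}",
        f"nodata_value {nodata if is_cat else _trim(f'{nodata:.6f}')}",
    ]
    for row in raster.values:
        lines.append(" ".join(fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _trim(s: str) -> str:
    """Drop trailing zeros from a fixed-point literal ('1.2500' -> '1.25')."""
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s or "0"
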