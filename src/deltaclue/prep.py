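"""Land-cover preparation: reclassification, majority aggregation, freezing.

Fine-grained land-cover categories (e.g. a 100 m inventory with dozens of
codes) are first mapped onto the six analysis classes, then aggregated to
the 1 km analysis grid by majority rule; classes that should never change
(water in the study) are frozen out of the active map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grid import CategoricalRaster, ContinuousRaster, DimensionError, GridSpec

__all__ = ["ReclassTable", "MappingError", "reclassify", "majority_aggregate", "freeze_classes"]


class MappingError(ValueError):
    """A fine category code has no entry in the reclassification table."""


@dataclasses.dataclass
class ReclassTable:
    """Total mapping from fine category codes to analysis class codes."""

    mapping: dict[int, int]

    @classmethod
    def from_text(cls, path) -> "ReclassTable":
        """Two whitespace-separated integer columns: fine_code class_code."""
        mapping = {}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fine, coarse = line.split()
            mapping[int(fine)] = int(coarse)
        return cls(mapping)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for fine in sorted(self.mapping):
                fh.write(f"{fine} {self.mapping[fine]}\n")


def reclassify(fine_map: CategoricalRaster, table: ReclassTable) -> CategoricalRaster:
    """Cellwise substitution of fine codes by analysis class codes.

    Nodata is preserved; any non-nodata code missing from the table raises
    :class:`MappingError` listing every offending code.
    """
    vals = fine_map.values
    mask = fine_map.data_mask
    present = np.unique(vals[mask])
    unmapped = [int(c) for c in present if int(c) not in table.mapping]
    if unmapped:
        raise MappingError(f"fine codes missing from reclass table: {unmapped}")
    out = vals.copy()
    for fine, coarse in table.mapping.items():
        out[mask & (vals == fine)] = coarse
    return CategoricalRaster(fine_map.spec, out)


def majority_aggregate(
    fine_map: CategoricalRaster, factor: int, pad: bool = False
) -> tuple[CategoricalRaster, ContinuousRaster]:
    """Aggregate a class map by blocks of ``factor x factor`` cells.

    Each coarse cell takes the modal class of its block (nodata fine cells
    excluded; ties broken by the lowest class code) and the companion
    prevalence raster records modal count / non-nodata count.  A coarse
    cell is nodata iff its whole block is nodata.  When the dimensions are
    not divisible by ``factor``, ``pad=True`` pads the south/east edges
    with nodata, otherwise a :class:`DimensionError` is raised.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    spec = fine_map.spec
    vals = fine_map.values
    nr, nc = vals.shape
    if nr % factor or nc % factor:
        if not pad:
            raise DimensionError(
                f"grid {nr}x{nc} not divisible by factor {factor} (enable padding)"
            )
        nr_p = -(-nr // factor) * factor
        nc_p = -(-nc // factor) * factor
        padded = np.full((nr_p, nc_p), int(spec.nodata), dtype=vals.dtype)
        padded[:nr, :nc] = vals
        vals = padded
        nr, nc = nr_p, nc_p

    blocks = vals.reshape(nr // factor, factor, nc // factor, factor)
    nodata = int(spec.nodata)
    codes = sorted(int(c) for c in np.unique(vals) if c != nodata)
    valid = (blocks != nodata).sum(axis=(1, 3))

    if codes:
        # per-class block counts; argmax over ascending codes => lowest wins ties
        counts = np.stack(
            [(blocks == c).sum(axis=(1, 3)) for c in codes], axis=0
        )
        best = np.argmax(counts, axis=0)
        modal_count = np.take_along_axis(counts, best[None], axis=0)[0]
        coarse = np.asarray(codes, dtype=np.int64)[best]
    else:
        coarse = np.full((nr // factor, nc // factor), nodata, dtype=np.int64)
        modal_count = np.zeros_like(coarse)

    empty = valid == 0
    coarse = np.where(empty, nodata, coarse)
    with np.errstate(invalid="ignore", divide="ignore"):
        prevalence = np.where(empty, float(spec.nodata), modal_count / np.maximum(valid, 1))

    coarse_spec = GridSpec(
        ncols=nc // factor,
        nrows=nr // factor,
        xll=spec.xll,
        yll=spec.yll + (fine_map.spec.nrows - nr) * spec.cellsize,
        cellsize=spec.cellsize * factor,
        nodata=spec.nodata,
        crs_code=spec.crs_code,
    )
    return (
        CategoricalRaster(coarse_spec, coarse),
        ContinuousRaster(coarse_spec, prevalence, name="modal_prevalence", units="fraction"),
    )


def freeze_classes(
    landuse: CategoricalRaster, classes
) -> tuple[CategoricalRaster, np.ndarray]:
    """Remove the listed classes from the active map.

    Returns the active map (frozen cells set to nodata, all other cells
    unchanged) and the boolean frozen mask.  Frozen cells take no part in
    demand totals or allocation.
    """
    classes = set(int(c) for c in classes)
    mask = np.isin(landuse.values, list(classes)) & landuse.data_mask
    active = landuse.values.copy()
    active[mask] = int(landuse.spec.nodata)
    return CategoricalRaster(landuse.spec, active), mask
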