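"""A named, aligned set of continuous driver rasters."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grid import AlignmentError, ContinuousRaster, GridSpec, check_aligned

__all__ = ["DriverStack"]


@dataclasses.dataclass
class DriverStack:
    """Ordered collection of aligned :class:`ContinuousRaster` layers.

    The layer order is the predictor-index order used by the legacy
    ``sc1gr<index>.<year>`` file naming and the regression-coefficient file.
    """

    spec: GridSpec
    layers: dict[str, ContinuousRaster] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.layers.values():
            if not self.spec.aligned_with(r.spec):
                raise AlignmentError(f"driver {r.name!r} is not on the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> ContinuousRaster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, raster: ContinuousRaster) -> None:
        if not self.spec.aligned_with(raster.spec):
            raise AlignmentError(f"driver {raster.name!r} is not on the stack grid")
        if not raster.name:
            raise ValueError("driver raster needs a name")
        self.layers[raster.name] = raster

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def data_mask(self) -> np.ndarray:
        """Cells with data in every layer."""
        mask = np.ones(self.spec.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.data_mask
        return mask

    def as_frame(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Flatten the stack to a cells x drivers table.

        ``mask`` selects cells (defaults to the joint data mask); the frame
        index holds the flat cell indices so predictions can be scattered
        back onto the grid.
        """
        if mask is None:
            mask = self.data_mask()
        idx = np.flatnonzero(mask.ravel())
        data = {name: r.values.ravel()[idx] for name, r in self.layers.items()}
        return pd.DataFrame(data, index=idx)

    def subset(self, names) -> "DriverStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"drivers not in stack: {missing}")
        return DriverStack(self.spec, {n: self.layers[n] for n in names})
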