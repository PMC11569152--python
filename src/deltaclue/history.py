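"""Historic transition analysis: counts, conversion elasticities, allow matrix.

The allocation engine needs to know which land-use conversions are
possible and how resistant each class is to leaving its current use.
Both are derived from a multi-snapshot historic map series: transitions
are counted over every consecutive snapshot pair, elasticities scale the
per-class change counts into [0, 1] (0 = converts freely, 1 = never
converts), and the allow matrix marks which ordered conversions were ever
observed often enough to be considered possible.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, check_aligned

__all__ = [
    "TransitionTable",
    "DegenerateDataError",
    "count_transitions",
    "derive_elasticity",
    "apply_scenario_overrides",
    "build_allow_matrix",
]


class DegenerateDataError(ValueError):
    """The change counts cannot be scaled (e.g. max equals min)."""


@dataclasses.dataclass
class TransitionTable:
    """Transition counts per ordered class pair, summed over snapshot pairs."""

    counts: pd.DataFrame  # index = from-class, columns = to-class

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("transition counts must be non-negative")

    @property
    def class_codes(self) -> list[int]:
        return [int(c) for c in self.counts.index]

    @property
    def per_class_changes(self) -> pd.Series:
        """Total transitions away from each class (off-diagonal row sums)."""
        c = self.counts
        return c.sum(axis=1) - pd.Series(np.diag(c.values), index=c.index)

    def to_csv(self, path) -> None:
        long = self.counts.stack()
        long.index.names = ["from_class", "to_class"]
        long.rename("count").reset_index().to_csv(path, index=False)


def count_transitions(
    snapshots: Sequence[CategoricalRaster],
    frozen_mask: np.ndarray | None = None,
    class_codes: Sequence[int] | None = None,
) -> TransitionTable:
    """Accumulate cell transitions over every consecutive snapshot pair.

    Cells that are nodata (or frozen) in either snapshot of a pair are
    excluded from that pair's counts.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots")
    check_aligned(*snapshots)
    if class_codes is None:
        codes = sorted({c for s in snapshots for c in s.class_codes()})
    else:
        codes = sorted(int(c) for c in class_codes)
    k = len(codes)
    code_pos = {c: i for i, c in enumerate(codes)}
    acc = np.zeros((k, k), dtype=np.int64)
    lookup = np.full(max(codes) + 1, -1, dtype=np.int64)
    for c, i in code_pos.items():
        lookup[c] = i
    for a, b in zip(snapshots[:-1], snapshots[1:]):
        ok = a.data_mask & b.data_mask
        if frozen_mask is not None:
            ok &= ~frozen_mask
        va = a.values[ok]
        vb = b.values[ok]
        bad = sorted(set(np.unique(va)) | set(np.unique(vb)) - set(codes))
        bad = [int(v) for v in bad if int(v) not in code_pos]
        if bad:
            raise ValueError(f"snapshot classes {bad} missing from class_codes")
        np.add.at(acc, (lookup[va], lookup[vb]), 1)
    frame = pd.DataFrame(acc, index=pd.Index(codes, name="from_class"),
                         columns=pd.Index(codes, name="to_class"))
    return TransitionTable(frame)


def derive_elasticity(
    table: TransitionTable | pd.Series,
    method: str = "minmax",
    values: Mapping | pd.Series | None = None,
) -> pd.Series:
    """Per-class conversion elasticity in [0, 1].

    method="table"
        Return the user-supplied ``values`` verbatim (the canonical path:
        the study publishes its elasticity table rather than the exact
        scaling function).
    method="minmax"
        ``1 - (changes_c - min) / (max - min)``, rounded to 2 decimals —
        a documented approximation of scaling change counts to [0, 1].
    """
    changes = table.per_class_changes if isinstance(table, TransitionTable) else table
    if method == "table":
        if values is None:
            raise ValueError('method="table" needs the elasticity values')
        out = pd.Series(dict(values), dtype=float)
        if ((out < 0) | (out > 1)).any():
            raise ValueError("elasticities must lie in [0, 1]")
        return out
    if method == "minmax":
        lo, hi = float(changes.min()), float(changes.max())
        if hi == lo:
            raise DegenerateDataError("all classes changed equally often; min-max scaling undefined")
        scaled = 1.0 - (changes.astype(float) - lo) / (hi - lo)
        return scaled.round(2)
    raise ValueError(f"unknown method {method!r}")


def apply_scenario_overrides(elas: pd.Series, overrides: Mapping) -> pd.Series:
    """Replace the listed classes' elasticities (scenario-specific tweaks)."""
    out = elas.copy()
    for cls, val in overrides.items():
        if cls not in out.index:
            raise KeyError(f"unknown class {cls!r}")
        if not 0.0 <= float(val) <= 1.0:
            raise ValueError(f"override for {cls!r} outside [0, 1]")
        out[cls] = float(val)
    return out


def build_allow_matrix(
    table: TransitionTable,
    min_count: int = 0,
    frozen_classes: Sequence[int] = (),
) -> pd.DataFrame:
    """0/1 matrix of permitted conversions (row = from, column = to).

    A conversion is allowed iff it was observed at least ``min_count``
    times or is the identity; frozen classes get identity rows/columns.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    c = table.counts
    allow = (c.values >= min_count).astype(np.int64)
    np.fill_diagonal(allow, 1)
    codes = table.class_codes
    for fc in frozen_classes:
        if fc in codes:
            i = codes.index(fc)
            allow[i, :] = 0
            allow[:, i] = 0
            allow[i, i] = 1
    return pd.DataFrame(allow, index=c.index, columns=c.columns)
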