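"""Dynamic driver generation: the per-year predictor stack.

Most predictors change over the simulated period.  This module covers the
recipes used to build each year's stack: the weighted flood-depth
composite, linear interpolation of an endpoint map back to the start map,
fractional endpoints (e.g. a low-warming scenario taking the map from
three quarters of the way through the period), dated distance-to-feature
rasters that honour opening and closing years, moving-average climate
series, and the relative land-price regression.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree

from .grid import ContinuousRaster, GridSpec, check_aligned

__all__ = [
    "FloodDepthSet",
    "Feature",
    "FeatureSchedule",
    "flood_composite",
    "interpolate_year",
    "fractional_endpoint",
    "distance_raster",
    "moving_average_climate",
    "landprice_model",
    "landprice_predict",
    "FAR_DISTANCE",
]

#: Distance sentinel when no feature is open (finite so rasters stay valid).
FAR_DISTANCE = 1e30

#: Flood-composite weights: the annual exceedance probability of each event.
FLOOD_WEIGHTS = {"d10": 0.1, "d100": 0.01, "d1000": 0.001, "d100000": 0.00001}


@dataclasses.dataclass
class FloodDepthSet:
    """Max inundation depth (m) for 1-in-10/100/1000/100,000-year events."""

    d10: ContinuousRaster
    d100: ContinuousRaster
    d1000: ContinuousRaster
    d100000: ContinuousRaster

    def __post_init__(self) -> None:
        check_aligned(self.d10, self.d100, self.d1000, self.d100000)
        for name in FLOOD_WEIGHTS:
            r = getattr(self, name)
            if (r.values[r.data_mask] < 0).any():
                raise ValueError(f"negative flood depth in {name}")


def flood_composite(depths: FloodDepthSet) -> ContinuousRaster:
    """Probability-weighted flood-depth composite.

    0.1 * d10 + 0.01 * d100 + 0.001 * d1000 + 0.00001 * d100000, cellwise;
    unit depths everywhere give 0.11101.
    """
    spec = depths.d10.spec
    mask = np.ones(spec.shape, dtype=bool)
    out = np.zeros(spec.shape)
    for name, w in FLOOD_WEIGHTS.items():
        r = getattr(depths, name)
        mask &= r.data_mask
        out = out + w * r.values
    out = np.where(mask, out, spec.nodata)
    return ContinuousRaster(spec, out, name="flood_risk", units="m (weighted)")


def interpolate_year(
    map_start: ContinuousRaster,
    map_end: ContinuousRaster,
    year: float,
    year_start: float,
    year_end: float,
) -> ContinuousRaster:
    """Cellwise linear interpolation between two dated maps."""
    check_aligned(map_start, map_end)
    if not year_start <= year <= year_end:
        raise ValueError(f"year {year} outside [{year_start}, {year_end}]")
    if year_end == year_start:
        return map_start
    w = (year - year_start) / (year_end - year_start)
    spec = map_start.spec
    mask = map_start.data_mask & map_end.data_mask
    vals = np.where(
        mask, map_start.values + w * (map_end.values - map_start.values), spec.nodata
    )
    return ContinuousRaster(spec, vals, name=map_start.name, units=map_start.units)


def fractional_endpoint(
    map_start: ContinuousRaster, map_end: ContinuousRaster, fraction: float
) -> ContinuousRaster:
    """The map at a fractional position along the start-to-end trajectory.

    Used e.g. for a milder scenario that takes the value from three
    quarters of the way through the period as its own endpoint.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return interpolate_year(map_start, map_end, fraction, 0.0, 1.0)


@dataclasses.dataclass
class Feature:
    """A point or polyline feature with an opening (and optional closing) year."""

    feature_id: str
    coords: np.ndarray  # (k, 2) of x, y in grid units (m)
    open_year: float = -np.inf
    close_year: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")
        if self.close_year is not None and self.open_year > self.close_year:
            raise ValueError("open_year must be <= close_year")

    def is_open(self, year: float) -> bool:
        return self.open_year <= year and (self.close_year is None or year < self.close_year)

    def densified(self, step: float) -> np.ndarray:
        """Vertices plus intermediate points every <= step along segments."""
        pts = [self.coords[0]]
        for a, b in zip(self.coords[:-1], self.coords[1:]):
            seg = np.linalg.norm(b - a)
            n = max(1, int(np.ceil(seg / step)))
            for i in range(1, n + 1):
                pts.append(a + (b - a) * i / n)
        return np.unique(np.array(pts), axis=0)


@dataclasses.dataclass
class FeatureSchedule:
    """Dated feature set for one distance predictor."""

    features: list[Feature]

    def open_at(self, year: float) -> list[Feature]:
        return [f for f in self.features if f.is_open(year)]

    @classmethod
    def from_csv(cls, path) -> "FeatureSchedule":
        """CSV columns: id, open_year, close_year (blank = never), x1, y1 [, x2, y2 ...]."""
        feats = []
        frame = pd.read_csv(path)
        for _, row in frame.iterrows():
            xy = row.drop(["id", "open_year", "close_year"]).dropna().to_numpy(float)
            close = row["close_year"]
            feats.append(
                Feature(
                    str(row["id"]),
                    xy.reshape(-1, 2),
                    float(row["open_year"]),
                    None if pd.isna(close) else float(close),
                )
            )
        return cls(feats)

    def to_csv(self, path) -> None:
        width = max(len(f.coords) for f in self.features) if self.features else 1
        rows = []
        for f in self.features:
            row = {"id": f.feature_id, "open_year": f.open_year, "close_year": f.close_year}
            for i in range(width):
                if i < len(f.coords):
                    row[f"x{i + 1}"], row[f"y{i + 1}"] = f.coords[i]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def distance_raster(
    spec: GridSpec,
    schedule: FeatureSchedule,
    year: float,
    metric: str = "euclidean",
    name: str = "distance",
) -> ContinuousRaster:
    """Distance (m) from every cell center to the nearest open feature.

    Polylines are densified to points at a step of half the cellsize, so
    the point-set distance approximates the true segment distance to well
    under a cell.  With no open feature the raster is filled with
    :data:`FAR_DISTANCE` and a warning is emitted.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    open_feats = schedule.open_at(year)
    if not open_feats:
        warnings.warn(f"no feature open in {year}; returning far-distance raster", stacklevel=2)
        return ContinuousRaster(
            spec, np.full(spec.shape, FAR_DISTANCE), name=name, units="m"
        )
    step = spec.cellsize / 2.0
    pts = np.vstack([f.densified(step) for f in open_feats])
    xs, ys = spec.cell_centers()
    tree = cKDTree(pts)
    d, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    return ContinuousRaster(spec, d.reshape(spec.shape), name=name, units="m")


def moving_average_climate(
    annual_series: Mapping[int, ContinuousRaster],
    window: int,
    years: Sequence[int] | None = None,
) -> dict[int, ContinuousRaster]:
    """Trailing moving average of an annual raster series.

    For each requested year, the cellwise mean of the ``window`` series
    years ending at that year.  When fewer than ``window`` years are
    available the mean of the available prefix is used and a warning is
    emitted (the study accepted a shortened window for its climate files).
    """
    if not annual_series:
        raise ValueError("empty climate series")
    avail = sorted(annual_series)
    spec = check_aligned(*[annual_series[y] for y in avail])
    if years is None:
        years = avail
    out = {}
    for year in years:
        if year not in annual_series:
            raise KeyError(f"year {year} not in the series")
        use = [y for y in avail if year - window < y <= year]
        if len(use) < window:
            warnings.warn(
                f"only {len(use)} of {window} years available before {year}; "
                "using the shortened window",
                stacklevel=2,
            )
        first = annual_series[use[0]]
        acc = np.zeros(spec.shape)
        mask = np.ones(spec.shape, dtype=bool)
        for y in use:
            r = annual_series[y]
            acc += np.where(r.data_mask, r.values, 0.0)
            mask &= r.data_mask
        vals = np.where(mask, acc / len(use), spec.nodata)
        out[year] = ContinuousRaster(spec, vals, name=first.name, units=first.units)
    return out


@dataclasses.dataclass
class LandPriceModel:
    """OLS of land price on environmental/accessibility covariates."""

    params: pd.Series
    covariate_names: tuple[str, ...]
    r_squared: float
    train_max: float


def landprice_model(
    train_price: ContinuousRaster, covariates: "DriverStack"
) -> LandPriceModel:
    """Fit the land-price regression on the joint data cells."""
    check_aligned(train_price, covariates.spec)
    mask = train_price.data_mask & covariates.data_mask()
    frame = covariates.as_frame(mask)
    y = train_price.values[mask]
    if np.unique(y).size < 2:
        raise ValueError("need at least two distinct price values")
    X = sm.add_constant(frame, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; OLS uses the pseudoinverse solution", stacklevel=2)
    res = sm.OLS(y, X).fit()
    return LandPriceModel(
        params=res.params,
        covariate_names=tuple(frame.columns),
        r_squared=float(res.rsquared),
        train_max=float(y.max()),
    )


def landprice_predict(model: LandPriceModel, covariates: "DriverStack") -> ContinuousRaster:
    """Predict land price and rescale so the maximum equals the training max.

    Only relative spatial differences carry information, so predictions
    are anchored to the observed price level rather than read as absolute
    future prices.
    """
    missing = [n for n in model.covariate_names if n not in covariates]
    if missing:
        raise KeyError(f"covariates missing from stack: {missing}")
    spec = covariates.spec
    mask = covariates.data_mask()
    frame = covariates.as_frame(mask)
    pred = np.full(len(frame), float(model.params["const"]))
    for name in model.covariate_names:
        pred += float(model.params[name]) * frame[name].to_numpy()
    peak = pred.max()
    if peak != 0:
        pred = pred * (model.train_max / peak)
    out = np.full(spec.shape, spec.nodata)
    out.ravel()[frame.index.to_numpy()] = pred
    return ContinuousRaster(spec, out, name="land_price", units="relative")
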