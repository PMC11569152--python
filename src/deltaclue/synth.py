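"""Synthetic study regions with known ground truth.

Real inputs of the study — a national land-cover series and a stack of
environmental/accessibility drivers — are out of scope, so every pipeline
stage is exercised on synthetic regions instead: spatially autocorrelated
driver fields, a land-use map whose classes depend log-linearly on the
drivers through a multinomial logit, a multi-snapshot history generated
from a known transition matrix, and scenario configurations with random
restriction masks.  Because the generating coefficients and transition
rates are known, suitability fitting and elasticity derivation can be
tested as parameter-recovery problems.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CategoricalRaster, ContinuousRaster, GridSpec, check_aligned
from .stack import DriverStack

__all__ = [
    "SyntheticWorld",
    "gen_driver_fields",
    "gen_landuse_from_logit",
    "gen_history",
    "gen_restriction_mask",
    "make_world",
    "DEFAULT_SPEC",
]

#: Default test grid: 50 x 50 cells of 1 km.
DEFAULT_SPEC = GridSpec(ncols=50, nrows=50, cellsize=1000.0)


@dataclasses.dataclass
class SyntheticWorld:
    """A fully known synthetic study region."""

    spec: GridSpec
    drivers: DriverStack
    true_coefficients: dict[int, tuple[float, dict[str, float]]]
    landuse0: CategoricalRaster
    history: list[CategoricalRaster]
    true_transition_rates: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        check_aligned(self.spec, self.drivers.spec, self.landuse0, *self.history)
        rates = self.true_transition_rates.to_numpy()
        if ((rates < 0) | (rates > 1)).any() or not np.allclose(rates.sum(axis=1), 1.0):
            raise ValueError("transition rates must be a stochastic matrix")


def gen_driver_fields(
    spec: GridSpec,
    n_drivers: int,
    smoothness: int = 0,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> DriverStack:
    """Standardised, optionally smoothed Gaussian random fields.

    White noise is smoothed by a square moving-average kernel of radius
    ``smoothness`` cells, then standardised to mean 0, sd 1; radius 0
    yields plain white noise, radius 5 on a 50 x 50 grid yields strong
    lag-1 spatial autocorrelation.  Deterministic given the seed.
    """
    if n_drivers < 1:
        raise ValueError("need at least one driver")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    size = 2 * smoothness + 1
    if size > min(spec.nrows, spec.ncols):
        raise ValueError("smoothness kernel larger than the grid")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"driver_{i}" for i in range(n_drivers)]
    stack = DriverStack(spec)
    for name in names[:n_drivers]:
        field = rng.standard_normal(spec.shape)
        if smoothness > 0:
            field = ndimage.uniform_filter(field, size=size, mode="reflect")
        field = (field - field.mean()) / field.std()
        stack.add(ContinuousRaster(spec, field, name=name, units="z-score"))
    return stack


def gen_landuse_from_logit(
    drivers: DriverStack,
    true_coefficients: Mapping[int, tuple[float, Mapping[str, float]]],
    seed: int = 0,
) -> CategoricalRaster:
    """Sample a class map from the softmax of per-class linear predictors.

    One coefficient set (intercept, {driver: coef}) per class; a
    multinomial logit yields exactly one class per cell while remaining
    consistent with one-vs-rest binary logistic fitting.
    """
    spec = drivers.spec
    codes = sorted(int(c) for c in true_coefficients)
    etas = []
    for c in codes:
        intercept, coefs = true_coefficients[c]
        missing = [n for n in coefs if n not in drivers]
        if missing:
            raise KeyError(f"class {c} references unknown drivers {missing}")
        eta = np.full(spec.shape, float(intercept))
        for name, coef in coefs.items():
            eta = eta + float(coef) * drivers[name].values
        etas.append(eta)
    eta = np.stack(etas)  # (K, nrows, ncols)
    eta -= eta.max(axis=0, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    u = rng.random(spec.shape)
    cum = np.cumsum(probs, axis=0)
    idx = (u[None] > cum).sum(axis=0)
    vals = np.asarray(codes, dtype=np.int64)[idx]
    mask = drivers.data_mask()
    vals = np.where(mask, vals, int(spec.nodata))
    return CategoricalRaster(spec, vals)


def gen_history(
    landuse0: CategoricalRaster,
    true_transition_rates: pd.DataFrame,
    n_steps: int,
    seed: int = 0,
) -> list[CategoricalRaster]:
    """Evolve a map by a per-cell Markov chain; returns n_steps + 1 snapshots.

    Rows of the rate matrix must sum to 1 (a stochastic matrix over the
    active classes).  Each cell transitions independently each step.
    """
    rates = true_transition_rates
    mat = rates.to_numpy(dtype=float)
    if ((mat < 0) | (mat > 1)).any() or not np.allclose(mat.sum(axis=1), 1.0):
        raise ValueError("transition rates must form a stochastic matrix")
    codes = [int(c) for c in rates.index]
    if list(rates.columns.astype(int)) != codes:
        raise ValueError("rate matrix rows and columns must share the class order")
    lookup = np.full(max(codes) + 1, -1, dtype=np.int64)
    lookup[codes] = np.arange(len(codes))
    rng = np.random.default_rng(seed)
    cum = np.cumsum(mat, axis=1)
    snaps = [landuse0]
    current = landuse0
    mask = landuse0.data_mask
    for _ in range(n_steps):
        vals = current.values
        idx = lookup[np.where(mask, vals, codes[0])]
        u = rng.random(vals.shape)
        nxt_idx = (u[..., None] > cum[idx]).sum(axis=-1)
        nxt = np.asarray(codes, dtype=np.int64)[nxt_idx]
        nxt = np.where(mask, nxt, int(current.spec.nodata))
        current = CategoricalRaster(current.spec, nxt)
        snaps.append(current)
    return snaps


def gen_restriction_mask(
    landuse: CategoricalRaster, fraction: float, seed: int = 0
) -> np.ndarray:
    """Randomly restrict the requested fraction of active cells (exact count)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("restriction fraction must lie in [0, 1]")
    active = np.flatnonzero(landuse.data_mask.ravel())
    n = int(round(fraction * active.size))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(active, size=n, replace=False) if n else np.empty(0, int)
    mask = np.zeros(landuse.spec.shape, dtype=bool)
    mask.ravel()[chosen] = True
    return mask


def make_world(
    spec: GridSpec = DEFAULT_SPEC,
    n_drivers: int = 3,
    smoothness: int = 2,
    class_codes: Sequence[int] = (0, 1, 2, 3, 5),
    coef_scale: float = 1.5,
    stay_prob: float = 0.9,
    n_steps: int = 4,
    seed: int = 0,
) -> SyntheticWorld:
    """Convenience constructor for a complete synthetic study region.

    Each class gets one dominant driver coefficient of magnitude
    ``coef_scale`` (sign alternating) so fitted models have a known
    identity/sign target; the history follows a stochastic matrix with
    ``stay_prob`` on the diagonal and class-dependent away-rates so
    elasticity derivation has a known propensity ordering.
    """
    rng = np.random.default_rng(seed)
    drivers = gen_driver_fields(spec, n_drivers, smoothness, seed=int(rng.integers(2**31)))
    names = drivers.names
    codes = sorted(int(c) for c in class_codes)
    coefs: dict[int, tuple[float, dict[str, float]]] = {}
    for i, c in enumerate(codes):
        dom = names[i % len(names)]
        sign = 1.0 if i % 2 == 0 else -1.0
        coefs[c] = (0.0, {dom: sign * coef_scale})
    landuse0 = gen_landuse_from_logit(drivers, coefs, seed=int(rng.integers(2**31)))
    k = len(codes)
    # away-rates spread over [0.02, 0.2] so the propensity ordering is strict
    away = np.linspace(0.02, 1.0 - stay_prob if stay_prob < 0.98 else 0.2, k)
    mat = np.zeros((k, k))
    for i in range(k):
        mat[i, :] = away[i] / (k - 1)
        mat[i, i] = 1.0 - away[i]
    rates = pd.DataFrame(mat, index=codes, columns=codes)
    history = gen_history(landuse0, rates, n_steps, seed=int(rng.integers(2**31)))
    return SyntheticWorld(
        spec=spec,
        drivers=drivers,
        true_coefficients=coefs,
        landuse0=landuse0,
        history=history,
        true_transition_rates=rates,
        seed=seed,
    )
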