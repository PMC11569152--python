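"""Location-suitability modelling.

Per land-use class, a one-vs-rest binary logistic regression maps the
driver stack to a per-cell suitability probability.  Highly correlated
predictors are screened out first (|Pearson r| above a threshold, 0.7 in
the study), then predictors are selected by bidirectional stepwise search
on the Akaike information criterion, starting from the full candidate
model.  The fitted coefficients feed the allocation engine directly;
discrimination is summarised by the area under the ROC curve
(Mann-Whitney form).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .grid import CategoricalRaster, ContinuousRaster, check_aligned
from .stack import DriverStack

__all__ = [
    "ClassLogit",
    "SuitabilityModel",
    "UndefinedMetricError",
    "correlation_screen",
    "fit_logistic_stepwise",
    "fit_all_classes",
    "auc_roc",
    "predict_suitability",
]

#: |coefficient| beyond which a fit is flagged as (near-)separated.
SEPARATION_CAP = 50.0


class UndefinedMetricError(ValueError):
    """A metric needs both classes present."""


@dataclasses.dataclass
class ClassLogit:
    """One class's fitted suitability model."""

    class_code: int
    intercept: float
    coefficients: dict[str, float]
    candidate_set: tuple[str, ...] = ()
    auc: float | None = None
    aic: float | None = None
    separation_flag: bool = False

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(frame), self.intercept)
        for name, coef in self.coefficients.items():
            eta = eta + coef * frame[name].to_numpy()
        return eta

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return _expit(self.linear_predictor(frame))


@dataclasses.dataclass
class SuitabilityModel:
    """Per-class logistic suitability models over a shared driver stack."""

    classes: dict[int, ClassLogit]

    def __getitem__(self, code: int) -> ClassLogit:
        return self.classes[code]

    @property
    def class_codes(self) -> list[int]:
        return sorted(self.classes)

    def report(self) -> pd.DataFrame:
        rows = []
        for code in self.class_codes:
            m = self.classes[code]
            rows.append({"class": code, "driver": "(intercept)", "coefficient": m.intercept,
                         "auc": m.auc, "aic": m.aic})
            for name, coef in m.coefficients.items():
                rows.append({"class": code, "driver": name, "coefficient": coef,
                             "auc": m.auc, "aic": m.aic})
        return pd.DataFrame(rows)


def _expit(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def correlation_screen(
    drivers: DriverStack | pd.DataFrame, threshold: float = 0.7
) -> list[str]:
    """Greedily drop one member of every too-correlated predictor pair.

    While any retained pair has |Pearson r| > threshold over the shared
    data cells, the worst pair is located and the member with the larger
    mean absolute correlation to all other retained predictors is dropped
    (ties: the alphabetically later name).  Constant predictors are
    dropped first with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frame = drivers.as_frame() if isinstance(drivers, DriverStack) else drivers
    if frame.shape[1] < 1:
        raise ValueError("need at least one driver")
    retained = list(frame.columns)
    for name in list(retained):
        if float(frame[name].std()) == 0.0:
            warnings.warn(f"dropping constant driver {name!r}", stacklevel=2)
            retained.remove(name)
    while len(retained) > 1:
        corr = frame[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= threshold:
            break
        i, j = np.unravel_index(int(np.argmax(corr.values)), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a = float(corr.loc[a].drop(a).mean())
        mean_b = float(corr.loc[b].drop(b).mean())
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # alphabetically later
        retained.remove(drop)
    return retained


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[sm.Logit, object, bool]:
    """Fit with an intercept; flag (near-)separation instead of failing."""
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(method="lbfgs", disp=0, maxiter=500)
            flagged = True
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > SEPARATION_CAP:
        flagged = True
        res.params[:] = np.clip(res.params, -SEPARATION_CAP, SEPARATION_CAP)
    return model, res, flagged


def fit_logistic_stepwise(
    labels: np.ndarray,
    drivers: DriverStack | pd.DataFrame,
    candidate_names: Sequence[str] | None = None,
    class_code: int = 0,
    start: str = "full",
) -> ClassLogit:
    """Bidirectional AIC-stepwise one-vs-rest logistic fit.

    Starting from the full candidate model (or the intercept-only model
    with ``start="empty"``), the single add-or-drop move that most
    decreases AIC = 2k - 2 log L is applied until no move decreases it.
    An empty final model (intercept only) is allowed.
    """
    frame = drivers.as_frame() if isinstance(drivers, DriverStack) else drivers
    if candidate_names is None:
        candidate_names = list(frame.columns)
    candidate_names = list(candidate_names)
    if not candidate_names:
        raise ValueError("need at least one candidate predictor")
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")

    def aic_of(names: tuple[str, ...]) -> tuple[float, object, bool]:
        X = frame[list(names)] if names else pd.DataFrame(index=frame.index)
        try:
            _, res, flag = _fit_logit(y, X)
        except Exception:  # unfittable design: exclude from the search
            return np.inf, None, True
        return float(res.aic), res, flag

    current = tuple(candidate_names) if start == "full" else ()
    cache: dict[tuple[str, ...], tuple[float, object, bool]] = {}

    def eval_model(names: tuple[str, ...]):
        key = tuple(sorted(names))
        if key not in cache:
            cache[key] = aic_of(key)
        return cache[key]

    best_aic, best_res, best_flag = eval_model(current)
    while True:
        moves = []
        for name in current:  # drops
            moves.append(tuple(n for n in current if n != name))
        for name in candidate_names:  # adds
            if name not in current:
                moves.append(tuple(list(current) + [name]))
        improved = False
        for cand in moves:
            aic, res, flag = eval_model(cand)
            if aic < best_aic - 1e-9:
                best_aic, best_res, best_flag = aic, res, flag
                current = tuple(sorted(cand))
                improved = True
        if not improved:
            break

    if best_res is None:
        raise ValueError("no candidate model could be fitted")
    params = best_res.params
    intercept = float(params["const"])
    coefs = {n: float(params[n]) for n in current}
    scores = best_res.predict()
    try:
        auc = auc_roc(scores, y)
    except UndefinedMetricError:
        auc = None
    return ClassLogit(
        class_code=class_code,
        intercept=intercept,
        coefficients=coefs,
        candidate_set=tuple(candidate_names),
        auc=auc,
        aic=best_aic,
        separation_flag=best_flag,
    )


def fit_all_classes(
    landuse: CategoricalRaster,
    drivers: DriverStack,
    candidates_per_class: Mapping[int, Sequence[str]] | None = None,
    screen_threshold: float | None = 0.7,
) -> SuitabilityModel:
    """One-vs-rest stepwise fit for every class present in the map."""
    check_aligned(landuse, drivers.spec)
    mask = landuse.data_mask & drivers.data_mask()
    frame = drivers.as_frame(mask)
    labels_all = landuse.values[mask]
    retained = (
        correlation_screen(frame, screen_threshold) if screen_threshold else list(frame.columns)
    )
    models = {}
    for code in landuse.class_codes():
        cands = list(candidates_per_class[code]) if candidates_per_class else retained
        cands = [c for c in cands if c in retained]
        y = (labels_all == code).astype(float)
        models[code] = fit_logistic_stepwise(y, frame, cands, class_code=code)
    return SuitabilityModel(models)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedMetricError("AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    rank_sum = float(ranks[labels == 1].sum())
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def predict_suitability(model: ClassLogit, drivers: DriverStack) -> ContinuousRaster:
    """Cellwise logistic suitability map for one class."""
    missing = [n for n in model.coefficients if n not in drivers]
    if missing:
        raise KeyError(f"drivers missing from stack: {missing}")
    spec = drivers.spec
    eta = np.full(spec.shape, model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        eta += coef * drivers[name].values
    mask = drivers.data_mask()
    out = np.where(mask, _expit(eta), spec.nodata)
    return ContinuousRaster(
        spec, out, name=f"suitability_{model.class_code}", units="probability"
    )
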