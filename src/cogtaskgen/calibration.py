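"""Expert-rating calibration: consistency, model fitting, and simulation.

The demand models shipped with the package were calibrated from 1-10 Likert
ratings that 20 rehabilitation professionals gave to 67 task variants.  This
module provides the statistical machinery to redo such a calibration from a
rating table:

* :func:`cronbach_alpha` -- internal consistency of a raters x items matrix;
* :func:`fit_demand_model` -- ordinary least-squares fit of ratings on
  encoded task parameters, with standard errors, t values and Gaussian
  AIC/BIC;
* :func:`screen_predictors` -- drop non-significant parameters and refit,
  degenerating to the grand-mean fallback when nothing survives;
* :func:`compare_models` -- AIC ranking of candidate fits;
* :func:`simulate_ratings` -- a seeded synthetic rating panel used to test
  the whole pipeline, since the original raw ratings are not deposited.

The estimator is deliberately a fixed-effects OLS rather than the random
slope / autoregressive multilevel fit a full panel analysis would use: the
presentation order is kept in the data model so an order covariate can be
added as a predictor, but between-rater structure is treated as noise.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .axes import AXES, RATING_MAX, RATING_MIN
from .errors import (
    CollinearityError,
    EmptyDesignError,
    IncomparableModelsError,
    UndefinedAlphaError,
    ValidationError,
)
from .models import DemandModel, ModelRegistry, evaluate_demand
from .params import Level, get_space


@dataclass(frozen=True)
class RatingRecord:
    """One expert's rating of one task variant on one axis."""

    rater_id: str
    task_id: str
    params: Mapping[str, Level]
    axis: str
    rating: float
    presentation_order: int

    def __post_init__(self):
        if not (RATING_MIN <= self.rating <= RATING_MAX):
            raise ValidationError(f"rating {self.rating} outside [1, 10]")
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")
        get_space(self.task_id).validate(self.params)
        if self.presentation_order < 1:
            raise ValidationError("presentation_order must be >= 1")


@dataclass(frozen=True)
class FittedModel:
    """An OLS demand-model fit with its uncertainty and quality measures.

    ``k`` counts the estimated parameters entering AIC/BIC: the intercept,
    the slope coefficients, and the residual variance.
    """

    model: DemandModel
    se: Mapping[str, float]           # per-coefficient SE, "intercept" included
    t_values: Mapping[str, float]
    p_values: Mapping[str, float]
    n_obs: int
    residual_variance: float          # ML estimate (RSS / n)
    log_likelihood: float
    aic: float
    bic: float
    records: Tuple[RatingRecord, ...] = field(repr=False, default=())
    records_digest: str = ""

    @property
    def k(self) -> int:
        return len(self.model.coefficients) + 2


def _records_digest(records: Sequence[RatingRecord]) -> str:
    h = hashlib.sha256()
    for r in sorted(
        records, key=lambda r: (r.rater_id, r.presentation_order, r.task_id, r.axis)
    ):
        h.update(
            repr(
                (r.rater_id, r.task_id, sorted(r.params.items()), r.axis,
                 round(r.rating, 9), r.presentation_order)
            ).encode()
        )
    return h.hexdigest()


def cronbach_alpha(ratings_matrix) -> float:
    """Cronbach's alpha of a raters x items rating matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with k the number of items (columns) and sample (n-1) variances.  Rows
    with missing cells are dropped listwise.
    """
    m = np.asarray(ratings_matrix, dtype=float)
    if m.ndim != 2:
        raise UndefinedAlphaError("ratings matrix must be 2-D (raters x items)")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if k < 2:
        raise UndefinedAlphaError("alpha needs at least 2 items")
    if n < 2:
        raise UndefinedAlphaError("alpha needs at least 2 raters")
    total_var = np.var(m.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise UndefinedAlphaError("zero variance of item sums")
    item_var = np.var(m, axis=0, ddof=1).sum()
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def _design_matrix(
    records: Sequence[RatingRecord], predictors: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    task_id = records[0].task_id
    space = get_space(task_id)
    cols = []
    for name in predictors:
        p = space.parameter(name)
        cols.append([p.encode(r.params[name]) for r in records])
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    y = np.array([r.rating for r in records], dtype=float)
    return X, y


def _aliased_predictors(X: np.ndarray, predictors: Sequence[str]) -> List[str]:
    """Name predictors implicated in rank deficiency: constant columns, plus
    columns whose removal restores full rank."""
    aliased = []
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    full_rank = np.linalg.matrix_rank(Xc)
    for j, name in enumerate(predictors):
        col = X[:, j]
        if np.allclose(col, col[0]):
            aliased.append(name)
            continue
        reduced = np.delete(Xc, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            aliased.append(name)
    return aliased or list(predictors)


def fit_demand_model(
    records: Sequence[RatingRecord], predictors: Sequence[str]
) -> FittedModel:
    """OLS fit of ratings on encoded predictors with intercept.

    All records must share one task and one axis.  AIC/BIC follow the
    Gaussian likelihood with the maximum-likelihood variance estimate:
    aic = 2k - 2 loglik, bic = k ln(n) - 2 loglik, k counting the intercept,
    slopes, and the residual variance.
    """
    records = tuple(records)
    if not records:
        raise ValidationError("no rating records")
    task_ids = {r.task_id for r in records}
    axes = {r.axis for r in records}
    if len(task_ids) != 1 or len(axes) != 1:
        raise ValidationError("records must cover exactly one task and one axis")
    predictors = list(predictors)
    if len(records) < len(predictors) + 2:
        raise ValidationError(
            f"need at least {len(predictors) + 2} records, got {len(records)}"
        )
    X, y = _design_matrix(records, predictors)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise CollinearityError(_aliased_predictors(X, predictors))
    res = sm.OLS(y, Xc).fit()
    n = len(y)
    sigma2 = float(res.ssr / n)
    if sigma2 <= 0:
        # Perfect interpolation: the Gaussian likelihood degenerates.
        loglik = math.inf
    else:
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = len(predictors) + 2
    names = ["intercept"] + predictors
    model = DemandModel(
        records[0].task_id,
        records[0].axis,
        intercept=float(res.params[0]),
        coefficients={nm: float(c) for nm, c in zip(predictors, res.params[1:])},
    )
    return FittedModel(
        model=model,
        se={nm: float(s) for nm, s in zip(names, res.bse)},
        t_values={nm: float(t) for nm, t in zip(names, res.tvalues)},
        p_values={nm: float(p) for nm, p in zip(names, res.pvalues)},
        n_obs=n,
        residual_variance=sigma2,
        log_likelihood=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        records=records,
        records_digest=_records_digest(records),
    )


def fit_mean_model(records: Sequence[RatingRecord]) -> FittedModel:
    """Intercept-only fit: the grand mean with its Gaussian AIC/BIC."""
    records = tuple(records)
    y = np.array([r.rating for r in records], dtype=float)
    n = len(y)
    mean = float(y.mean())
    sigma2 = float(((y - mean) ** 2).mean())
    loglik = (
        math.inf
        if sigma2 <= 0
        else -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    )
    k = 2  # mean + variance
    sd = float(y.std(ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n else 0.0
    model = DemandModel(records[0].task_id, records[0].axis, fallback_mean=mean)
    return FittedModel(
        model=model,
        se={"intercept": se},
        t_values={"intercept": mean / se if se else math.inf},
        p_values={"intercept": 0.0},
        n_obs=n,
        residual_variance=sigma2,
        log_likelihood=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        records=records,
        records_digest=_records_digest(records),
    )


def screen_predictors(fit: FittedModel, alpha_level: float = 0.05) -> FittedModel:
    """Keep only predictors significant at ``alpha_level`` (two-sided) and
    refit; with no survivors, return the grand-mean fallback fit."""
    if not (0 < alpha_level < 1):
        raise ValidationError("alpha_level must lie in (0, 1)")
    survivors = [
        name
        for name in fit.model.coefficients
        if fit.p_values[name] < alpha_level
    ]
    if not survivors:
        return fit_mean_model(fit.records)
    if set(survivors) == set(fit.model.coefficients):
        return fit
    return fit_demand_model(fit.records, survivors)


@dataclass(frozen=True)
class ModelRanking:
    """Fits ordered by ascending AIC with deltas versus the best."""

    fits: Tuple[FittedModel, ...]
    delta_aic: Tuple[float, ...]
    delta_bic: Tuple[float, ...]

    @property
    def best(self) -> FittedModel:
        return self.fits[0]


def compare_models(fits: Sequence[FittedModel]) -> ModelRanking:
    """Rank fits of the same records by AIC (ascending)."""
    fits = list(fits)
    if not fits:
        raise ValidationError("no fits to compare")
    digests = {f.records_digest for f in fits}
    if len(digests) != 1:
        raise IncomparableModelsError(
            "fits were computed on different record sets"
        )
    ordered = sorted(fits, key=lambda f: f.aic)
    best_aic = ordered[0].aic
    best_bic = min(f.bic for f in fits)
    return ModelRanking(
        fits=tuple(ordered),
        delta_aic=tuple(f.aic - best_aic for f in ordered),
        delta_bic=tuple(f.bic - best_bic for f in ordered),
    )


def study_design(
    n_variants: int = 67, seed: int = 0
) -> List[Tuple[str, Dict[str, Level]]]:
    """A stratified variant design emulating the rated study: ``n_variants``
    task configurations spread as evenly as possible over the 11 tasks,
    sampled without replacement from each task's grid."""
    from .params import TASK_IDS

    rng = random.Random(seed)
    per_task = n_variants // len(TASK_IDS)
    extras = n_variants - per_task * len(TASK_IDS)
    design: List[Tuple[str, Dict[str, Level]]] = []
    for i, task_id in enumerate(TASK_IDS):
        grid = list(get_space(task_id).grid())
        want = per_task + (1 if i < extras else 0)
        take = min(want, len(grid))
        for cfg in rng.sample(grid, take):
            design.append((task_id, cfg))
    return design


def simulate_ratings(
    registry: ModelRegistry,
    design: Sequence[Tuple[str, Mapping[str, Level]]],
    n_raters: int = 20,
    noise_sd: float = 1.0,
    rater_effect_sd: float = 0.0,
    seed: int = 0,
    axes: Sequence[str] = AXES,
    round_to_int: bool = False,
) -> List[RatingRecord]:
    """Synthetic expert panel: model prediction + rater intercept + noise.

    Each rater draws one normal intercept (sd ``rater_effect_sd``) shared
    across all their ratings, plus iid normal noise (sd ``noise_sd``) per
    rating; results are clamped to [1, 10] and optionally rounded to whole
    Likert points.  Each rater sees the design in their own shuffled
    presentation order.  Fixed seeds give identical record lists.
    """
    if n_raters < 2:
        raise ValidationError("need at least 2 raters")
    if noise_sd < 0 or rater_effect_sd < 0:
        raise ValidationError("standard deviations must be >= 0")
    design = list(design)
    if not design:
        raise EmptyDesignError("empty variant design")
    rng = random.Random(seed)
    records: List[RatingRecord] = []
    for i in range(n_raters):
        rater_id = f"rater{i + 1:02d}"
        offset = rng.gauss(0.0, rater_effect_sd) if rater_effect_sd else 0.0
        order = list(range(len(design)))
        rng.shuffle(order)
        for pos, idx in enumerate(order, start=1):
            task_id, cfg = design[idx]
            for axis in axes:
                pred = evaluate_demand(registry.get(task_id, axis), cfg)
                value = pred + offset + (rng.gauss(0.0, noise_sd) if noise_sd else 0.0)
                value = min(RATING_MAX, max(RATING_MIN, value))
                if round_to_int:
                    value = float(round(value))
                records.append(
                    RatingRecord(
                        rater_id=rater_id,
                        task_id=task_id,
                        params=dict(cfg),
                        axis=axis,
                        rating=value,
                        presentation_order=pos,
                    )
                )
    return records


def records_from_frame(frame: pd.DataFrame) -> List[RatingRecord]:
    """Build records from a ratings table.

    Expected columns: rater_id, task_id, axis, rating, order, then one
    column per task parameter (cells empty where a parameter does not apply
    to the row's task).
    """
    required = {"rater_id", "task_id", "axis", "rating", "order"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(
            f"ratings table missing columns: {', '.join(sorted(missing))}"
        )
    records = []
    for idx, row in frame.iterrows():
        task_id = str(row["task_id"])
        space = get_space(task_id)
        params: Dict[str, Level] = {}
        for p in space.parameters:
            if p.name not in frame.columns or pd.isna(row[p.name]):
                raise ValidationError(
                    f"row {idx}: missing value for parameter {p.name!r} "
                    f"of task {task_id!r}"
                )
            raw = row[p.name]
            if p.kind == "count":
                params[p.name] = int(raw)
            else:
                params[p.name] = str(raw)
        records.append(
            RatingRecord(
                rater_id=str(row["rater_id"]),
                task_id=task_id,
                params=params,
                axis=str(row["axis"]),
                rating=float(row["rating"]),
                presentation_order=int(row["order"]),
            )
        )
    return records


def records_to_frame(records: Sequence[RatingRecord]) -> pd.DataFrame:
    """Inverse of :func:`records_from_frame` (parameter columns merged)."""
    rows = []
    for r in records:
        row = {
            "rater_id": r.rater_id,
            "task_id": r.task_id,
            "axis": r.axis,
            "rating": r.rating,
            "order": r.presentation_order,
        }
        row.update(r.params)
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_records(
    records: Sequence[RatingRecord], alpha_level: float = 0.05
) -> Tuple[dict, dict]:
    """Full calibration of a rating table.

    Per task x axis: OLS fit on all task parameters, significance
    screening, and a quality block (SE, t, p, AIC, BIC, Cronbach alpha over
    the rater x variant matrix).  Returns ``(config, report)`` where
    ``config`` is loadable by :func:`cogtaskgen.models.load_model_registry`.
    Rank-deficient designs are reported, not fitted.
    """
    from .errors import CollinearityError as _CollinearityError

    groups: Dict[Tuple[str, str], List[RatingRecord]] = {}
    for r in records:
        groups.setdefault((r.task_id, r.axis), []).append(r)
    config: Dict[str, Dict[str, dict]] = {}
    report: Dict[str, Dict[str, dict]] = {}
    for (task_id, axis), recs in sorted(groups.items()):
        space = get_space(task_id)
        block: Dict[str, object] = {"n_obs": len(recs)}
        try:
            alpha = cronbach_alpha(
                ratings_to_matrix(recs, task_id=task_id, axis=axis).to_numpy()
            )
            block["cronbach_alpha"] = round(float(alpha), 4)
        except UndefinedAlphaError as exc:
            block["cronbach_alpha"] = None
            block["alpha_note"] = str(exc)
        try:
            fit = fit_demand_model(recs, space.parameter_names)
            screened = screen_predictors(fit, alpha_level)
        except _CollinearityError as exc:
            block["error"] = str(exc)
            report.setdefault(task_id, {})[axis] = block
            continue
        model = screened.model
        entry: Dict[str, object]
        if model.is_fallback:
            entry = {"mean": round(model.fallback_mean, 4)}
        else:
            entry = {
                "intercept": round(model.intercept, 4),
                "coefficients": {
                    k: round(v, 4) for k, v in model.coefficients.items()
                },
            }
        config.setdefault(task_id, {})[axis] = entry
        block.update(
            se={k: round(v, 4) for k, v in screened.se.items()},
            t_values={k: round(v, 4) for k, v in screened.t_values.items()},
            p_values={k: round(v, 6) for k, v in screened.p_values.items()},
            aic=round(screened.aic, 4),
            bic=round(screened.bic, 4),
            dropped=sorted(set(space.parameter_names) - set(model.coefficients)),
        )
        report.setdefault(task_id, {})[axis] = block
    return config, report


def ratings_to_matrix(
    records: Sequence[RatingRecord],
    task_id: Optional[str] = None,
    axis: Optional[str] = None,
) -> pd.DataFrame:
    """Pivot records to a raters x items DataFrame (items are variant x axis
    columns), optionally restricted to one task and/or axis."""
    rows = []
    for r in records:
        if task_id is not None and r.task_id != task_id:
            continue
        if axis is not None and r.axis != axis:
            continue
        item = (r.task_id, tuple(sorted(r.params.items())), r.axis)
        rows.append({"rater": r.rater_id, "item": repr(item), "rating": r.rating})
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError("no records match the requested task/axis")
    return frame.pivot_table(
        index="rater", columns="item", values="rating", aggfunc="mean"
    )
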