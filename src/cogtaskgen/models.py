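"""Linear cognitive-demand models and the per-task model registry.

Each task x axis pair carries one model of the form

    demand = intercept + sum_i  c_i * encoded_parameter_i

mapping a task configuration to a predicted expert rating on that axis,
clamped to the 1-10 rating scale.  When no parameter significantly moves an
axis, the model degenerates to a constant: the mean expert rating observed
for that task on that axis (the *fallback mean*).

Two tasks ship with published fixed-effect coefficients (problem resolution:
language and difficulty; comprehension of contexts: executive functions,
language and difficulty).  The remaining models are *endpoint calibrated*:
linear models constructed so that the prediction at the easiest grid corner
equals the published minimum rating for that task x axis, the prediction at
the hardest corner equals the published maximum, coefficient signs follow
the published customization guidelines, and the min-to-max span is
apportioned equally across the parameters the guidelines name.  Endpoint
calibration reproduces every published range while remaining overridable
through a coefficient configuration document once better estimates exist.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

from .axes import AXES, DemandProfile, clamp_rating
from .errors import InvalidParameterError, SchemaError, UnknownTaskError
from .params import DEFAULT_SPACES, TASK_IDS, Level, TaskParameterSpace, get_space


@dataclass(frozen=True)
class DemandModel:
    """One task x axis linear demand model (or a constant fallback mean)."""

    task_id: str
    axis: str
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)
    fallback_mean: Optional[float] = None

    def __post_init__(self):
        if self.axis not in AXES:
            raise SchemaError([f"unknown axis {self.axis!r} for {self.task_id}"])
        if not self.coefficients and self.fallback_mean is None:
            raise SchemaError(
                [f"{self.task_id}/{self.axis}: no coefficients and no mean"]
            )
        if self.coefficients and self.fallback_mean is not None:
            raise SchemaError(
                [f"{self.task_id}/{self.axis}: both coefficients and mean given"]
            )

    @property
    def is_fallback(self) -> bool:
        return self.fallback_mean is not None


@dataclass(frozen=True)
class TaskProfileRange:
    """Per-axis (min, max) achievable predicted demand over a task's grid."""

    task_id: str
    ranges: Mapping[str, Tuple[float, float]]

    def axis_range(self, axis: str) -> Tuple[float, float]:
        return self.ranges[axis]


def evaluate_demand(
    model: DemandModel,
    params: Mapping[str, Level],
    space: Optional[TaskParameterSpace] = None,
) -> float:
    """Predicted demand of one configuration on one axis, clamped to [1, 10].

    ``params`` may be a full assignment; only the parameters named by the
    model's coefficients enter the prediction.  Unknown parameter names and
    out-of-range levels raise.
    """
    space = space or get_space(model.task_id)
    for name in params:
        space.parameter(name)  # unknown-name check
    if model.is_fallback:
        # Constant axes ignore the parameters but still validate given levels.
        for name, level in params.items():
            space.parameter(name).encode(level)
        return clamp_rating(model.fallback_mean)
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in params:
            raise InvalidParameterError(
                f"{model.task_id}/{model.axis}: parameter {name!r} required"
            )
        total += coef * space.parameter(name).encode(params[name])
    return clamp_rating(total)


# --------------------------------------------------------------------------
# Published numbers driving the default registry
# --------------------------------------------------------------------------

# Mean and (min, max) expert rating per task and axis, in AXES order.
_R = Tuple[float, float, float]  # (mean, min, max)
TASK_RATING_SUMMARY: Dict[str, Dict[str, _R]] = {
    "word_search": {
        "memory": (5.52, 5.05, 6.20),
        "executive_functions": (6.04, 5.60, 6.55),
        "attention": (6.93, 6.50, 7.60),
        "language": (5.65, 5.25, 6.00),
        "difficulty": (6.37, 5.70, 7.00),
    },
    "problem_resolution": {
        "memory": (6.10, 6.10, 6.10),
        "executive_functions": (7.23, 7.15, 7.30),
        "attention": (6.97, 6.90, 7.05),
        "language": (5.20, 4.65, 5.75),
        "difficulty": (6.19, 5.35, 7.20),
    },
    "numeric_sequences": {
        "memory": (5.30, 5.00, 5.60),
        "executive_functions": (6.65, 6.50, 6.80),
        "attention": (6.87, 6.65, 7.10),
        "language": (4.68, 4.45, 4.90),
        "difficulty": (3.06, 1.38, 4.50),
    },
    "action_sequencing": {
        "memory": (4.72, 3.35, 5.65),
        "executive_functions": (4.79, 3.90, 5.65),
        "attention": (5.35, 3.80, 6.40),
        "language": (4.83, 3.50, 5.75),
        "difficulty": (4.74, 3.15, 6.20),
    },
    "association": {
        "memory": (3.37, 2.65, 4.25),
        "executive_functions": (3.92, 3.40, 4.35),
        "attention": (3.95, 3.00, 4.95),
        "language": (3.28, 3.00, 3.85),
        "difficulty": (3.78, 3.10, 4.90),
    },
    "cancellation": {
        "memory": (3.59, 2.60, 4.50),
        "executive_functions": (3.98, 2.95, 5.00),
        "attention": (5.09, 4.05, 6.15),
        "language": (2.94, 2.25, 3.60),
        "difficulty": (4.08, 2.85, 5.05),
    },
    "categorization": {
        "memory": (3.60, 2.20, 5.00),
        "executive_functions": (4.43, 2.85, 5.95),
        "attention": (4.18, 2.60, 5.65),
        "language": (3.87, 2.80, 4.70),
        "difficulty": (4.22, 2.35, 6.05),
    },
    "comprehension_of_contexts": {
        "memory": (2.63, 2.60, 2.65),
        "executive_functions": (3.25, 2.65, 3.85),
        "attention": (3.40, 3.20, 3.60),
        "language": (3.95, 3.45, 4.45),
        "difficulty": (2.93, 2.55, 3.30),
    },
    "image_pairs": {
        "memory": (6.97, 5.85, 8.40),
        "executive_functions": (5.55, 4.75, 6.40),
        "attention": (6.75, 5.75, 8.10),
        "language": (4.62, 3.90, 5.45),
        "difficulty": (6.35, 4.90, 7.95),
    },
    "mazes": {
        "memory": (3.87, 2.90, 4.90),
        "executive_functions": (5.17, 3.70, 6.45),
        "attention": (5.23, 4.10, 6.50),
        "language": (3.28, 2.65, 3.70),
        "difficulty": (4.63, 3.20, 6.10),
    },
    "memory_of_stories": {
        "memory": (6.36, 4.40, 7.70),
        "executive_functions": (4.89, 3.25, 6.15),
        "attention": (6.67, 4.90, 7.90),
        "language": (5.41, 4.15, 6.65),
        "difficulty": (5.95, 3.85, 7.40),
    },
}

# Published fixed-effect models, used verbatim.
_PRINTED_MODELS: Dict[Tuple[str, str], Tuple[float, Dict[str, float]]] = {
    ("problem_resolution", "language"): (4.65, {"type": 1.10}),
    ("problem_resolution", "difficulty"): (4.870, {"operations": 0.542, "digits": 0.365}),
    ("comprehension_of_contexts", "executive_functions"): (0.25, {"descriptions": 1.20}),
    ("comprehension_of_contexts", "language"): (1.45, {"descriptions": 1.00}),
    ("comprehension_of_contexts", "difficulty"): (1.05, {"descriptions": 0.75}),
}

# Which parameters the expert-derived customization guidelines name as
# significant drivers of each axis.  An empty list means the axis is
# parameter independent and falls back to the mean rating.
GUIDELINE_PREDICTORS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "word_search": {
        "memory": ("words", "clue"),
        "executive_functions": ("words", "clue"),
        "attention": ("words", "clue"),
        "language": (),
        "difficulty": ("words", "clue"),
    },
    "problem_resolution": {
        "memory": (),
        "executive_functions": (),
        "attention": (),
        # language / difficulty use the printed models above
    },
    "numeric_sequences": {
        "memory": ("missing", "position"),
        "executive_functions": ("missing", "position"),
        "attention": ("missing", "position"),
        "language": ("missing", "position"),
        "difficulty": ("step", "direction"),
    },
    "action_sequencing": {
        "memory": ("actions",),
        "executive_functions": ("actions",),
        "attention": ("actions", "goal"),
        "language": ("actions", "goal"),
        "difficulty": (),
    },
    "association": {axis: ("pairs",) for axis in AXES},
    "cancellation": {
        "memory": ("stimulus", "targets", "distractors"),
        "executive_functions": ("stimulus", "targets", "distractors"),
        "attention": ("stimulus", "targets", "distractors"),
        "language": ("stimulus", "distractors"),
        "difficulty": ("stimulus", "targets", "distractors"),
    },
    "categorization": {
        "memory": ("categories",),
        "executive_functions": ("categories",),
        "attention": ("categories", "items"),
        "language": ("categories",),
        "difficulty": ("categories",),
    },
    "comprehension_of_contexts": {
        "memory": (),
        "attention": (),
        # executive_functions / language / difficulty printed
    },
    "image_pairs": {axis: ("pairs",) for axis in AXES},
    "mazes": {axis: ("size",) for axis in AXES},
    "memory_of_stories": {
        "memory": ("size", "questions"),
        "executive_functions": ("size",),
        "attention": ("size", "questions"),
        "language": ("size",),
        "difficulty": ("size", "questions"),
    },
}


def _endpoint_calibrated(
    task_id: str, axis: str, predictors: Tuple[str, ...]
) -> DemandModel:
    """Linear model hitting the published (min, max) at the grid corners.

    The span is split equally across the named predictors; each coefficient
    is the per-predictor share divided by that predictor's encoding range,
    so all coefficients are positive (demand rises with every encoding, by
    construction of the encodings).
    """
    space = get_space(task_id)
    _, lo, hi = TASK_RATING_SUMMARY[task_id][axis]
    span = hi - lo
    share = span / len(predictors)
    coefficients = {}
    intercept = lo
    for name in predictors:
        p = space.parameter(name)
        width = p.max_encoding - p.min_encoding
        coef = share / width
        coefficients[name] = coef
        intercept -= coef * p.min_encoding
    return DemandModel(task_id, axis, intercept, coefficients)


class ModelRegistry:
    """All 55 task x axis demand models, with profile and range helpers."""

    def __init__(self, models: Iterable[DemandModel]):
        self._models: Dict[Tuple[str, str], DemandModel] = {}
        for m in models:
            self._models[(m.task_id, m.axis)] = m
        self._grid_cache: Dict[str, Tuple[list, dict]] = {}

    def get(self, task_id: str, axis: str) -> DemandModel:
        if task_id not in TASK_IDS:
            raise UnknownTaskError(f"unknown task {task_id!r}")
        return self._models[(task_id, axis)]

    @property
    def task_ids(self) -> Tuple[str, ...]:
        return TASK_IDS

    def __len__(self) -> int:
        return len(self._models)

    def profile(self, task_id: str, params: Mapping[str, Level]) -> DemandProfile:
        space = get_space(task_id)
        space.validate(params)
        return DemandProfile(
            **{a: evaluate_demand(self.get(task_id, a), params, space) for a in AXES}
        )

    def grid_profiles(self, task_id: str):
        """All (configuration, profile) pairs of a task, cached, in
        lexicographic grid order."""
        if task_id not in self._grid_cache:
            space = get_space(task_id)
            configs = list(space.grid())
            profiles = [self.profile(task_id, c) for c in configs]
            self._grid_cache[task_id] = (configs, profiles)
        return self._grid_cache[task_id]

    def task_profile_range(self, task_id: str) -> TaskProfileRange:
        """Exhaustively enumerated (min, max) demand per axis."""
        _, profiles = self.grid_profiles(task_id)
        ranges = {}
        for axis in AXES:
            values = [getattr(p, axis) for p in profiles]
            ranges[axis] = (min(values), max(values))
        return TaskProfileRange(task_id, ranges)

    def to_config(self) -> Dict[str, Dict[str, dict]]:
        """Dump all models in the coefficient-config JSON structure."""
        out: Dict[str, Dict[str, dict]] = {}
        for task_id in TASK_IDS:
            out[task_id] = {}
            for axis in AXES:
                m = self.get(task_id, axis)
                if m.is_fallback:
                    out[task_id][axis] = {"mean": m.fallback_mean}
                else:
                    out[task_id][axis] = {
                        "intercept": m.intercept,
                        "coefficients": dict(m.coefficients),
                    }
        return out


def build_default_registry() -> ModelRegistry:
    """The shipped registry: printed models verbatim, the rest endpoint
    calibrated against the published rating summaries."""
    models = []
    for task_id in TASK_IDS:
        for axis in AXES:
            key = (task_id, axis)
            if key in _PRINTED_MODELS:
                intercept, coefs = _PRINTED_MODELS[key]
                models.append(DemandModel(task_id, axis, intercept, dict(coefs)))
                continue
            predictors = GUIDELINE_PREDICTORS[task_id].get(axis, ())
            if not predictors:
                mean = TASK_RATING_SUMMARY[task_id][axis][0]
                models.append(DemandModel(task_id, axis, fallback_mean=mean))
            else:
                models.append(_endpoint_calibrated(task_id, axis, predictors))
    return ModelRegistry(models)


def _model_from_config(task_id: str, axis: str, spec: Mapping, offences: list):
    if not isinstance(spec, Mapping):
        offences.append(f"{task_id}/{axis}: expected an object")
        return None
    if "mean" in spec:
        extra = set(spec) - {"mean"}
        if extra:
            offences.append(f"{task_id}/{axis}: mean model with extra keys {sorted(extra)}")
            return None
        return DemandModel(task_id, axis, fallback_mean=float(spec["mean"]))
    if "intercept" not in spec or "coefficients" not in spec:
        offences.append(f"{task_id}/{axis}: need 'mean' or 'intercept'+'coefficients'")
        return None
    space = get_space(task_id)
    coefs = {}
    for name, value in dict(spec["coefficients"]).items():
        if name not in space.parameter_names:
            offences.append(f"{task_id}/{axis}: unknown parameter {name!r}")
            continue
        if not math.isfinite(float(value)):
            offences.append(f"{task_id}/{axis}: non-finite coefficient for {name!r}")
            continue
        coefs[name] = float(value)
    if not coefs:
        offences.append(f"{task_id}/{axis}: empty coefficient set")
        return None
    return DemandModel(task_id, axis, float(spec["intercept"]), coefs)


def load_model_registry(
    config: Union[None, str, Path, Mapping] = None,
) -> ModelRegistry:
    """Build the registry, optionally overriding models from a config
    document ``{task_id: {axis: {"intercept":..,"coefficients":{..}} |
    {"mean":..}}}``.  Only the overridden task x axis models change."""
    registry = build_default_registry()
    if config is None:
        return registry
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    if not isinstance(config, Mapping):
        raise SchemaError(["top level must be an object keyed by task_id"])
    offences: list = []
    overrides = []
    for task_id, axes_spec in config.items():
        if task_id not in TASK_IDS:
            offences.append(f"unknown task {task_id!r}")
            continue
        if not isinstance(axes_spec, Mapping):
            offences.append(f"{task_id}: expected an object keyed by axis")
            continue
        for axis, spec in axes_spec.items():
            if axis not in AXES:
                offences.append(f"{task_id}: unknown axis {axis!r}")
                continue
            model = _model_from_config(task_id, axis, spec, offences)
            if model is not None:
                overrides.append(model)
    if offences:
        raise SchemaError(offences)
    merged = {(m.task_id, m.axis): m for m in registry._models.values()}
    for m in overrides:
        merged[(m.task_id, m.axis)] = m
    return ModelRegistry(merged.values())
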