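"""Patient profiles and inverse matching of task parameters.

The forward direction of the demand models predicts how taxing a task
configuration is; personalization needs the inverse: given a target demand
profile for a patient, find the configuration of each task whose predicted
profile comes closest.  Because every parameter grid is small, the inverse
is solved exactly by exhaustive enumeration under a weighted Euclidean
distance, with a deterministic lexicographic tie-break.

Patient targets come either directly as five 1-10 values or from Montreal
Cognitive Assessment (MoCA) subscores mapped linearly onto the rating
scale.  The default mapping sends higher subscores to higher demand targets
(training at the level the patient can sustain); an ``invert`` flag flips
the convention for deficit-focused parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .axes import AXES, DemandProfile
from .errors import ValidationError
from .models import ModelRegistry
from .params import TASK_IDS, Level

#: MoCA component maxima: attention 0-6, delayed recall + orientation 0-11,
#: visuospatial/executive + abstraction 0-7, naming + language 0-6, total 0-30.
MOCA_MAXIMA = {
    "attention": 6,
    "memory": 11,
    "executive": 7,
    "language": 6,
    "total": 30,
}

#: MoCA component feeding each profile axis.
_AXIS_COMPONENT = {
    "attention": "attention",
    "memory": "memory",
    "executive_functions": "executive",
    "language": "language",
    "difficulty": "total",
}


@dataclass(frozen=True)
class MoCAScores:
    """Montreal Cognitive Assessment subscores used for profiling."""

    attention: int
    memory: int
    executive: int
    language: int
    total: int

    def __post_init__(self):
        for name, maximum in MOCA_MAXIMA.items():
            v = getattr(self, name)
            if not isinstance(v, int) or not (0 <= v <= maximum):
                raise ValidationError(
                    f"MoCA component {name!r} must be an integer in [0, {maximum}], "
                    f"got {v!r}"
                )
        components = [self.attention, self.memory, self.executive, self.language]
        if self.total < max(components):
            raise ValidationError("MoCA total cannot be below any component score")


def moca_to_profile(scores: MoCAScores, invert: bool = False) -> DemandProfile:
    """Map MoCA components linearly onto the 1-10 profile scale.

    value = 1 + 9 * score / maximum, so a zero component maps to 1 and a
    full component to 10.  With ``invert`` the fraction is reversed.
    """
    values = {}
    for axis, component in _AXIS_COMPONENT.items():
        frac = getattr(scores, component) / MOCA_MAXIMA[component]
        if invert:
            frac = 1.0 - frac
        values[axis] = 1.0 + 9.0 * frac
    return DemandProfile(**values)


def moca_parse(source: Union[str, Path, Mapping]) -> MoCAScores:
    """Read MoCA scores from a key-value JSON document (path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = dict(source)
    missing = [k for k in MOCA_MAXIMA if k not in data]
    if missing:
        raise ValidationError(f"MoCA record missing fields: {', '.join(missing)}")
    unknown = sorted(set(data) - set(MOCA_MAXIMA))
    if unknown:
        raise ValidationError(f"unknown MoCA fields: {', '.join(unknown)}")
    values = {}
    for key in MOCA_MAXIMA:
        v = data[key]
        if isinstance(v, bool) or not isinstance(v, (int, float)) or v != int(v):
            raise ValidationError(f"MoCA field {key!r} must be an integer")
        values[key] = int(v)
    return MoCAScores(**values)


def load_profile(source: Union[str, Path, Mapping]) -> DemandProfile:
    """Read a five-axis patient profile from key-value JSON."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = dict(source)
    return DemandProfile.from_dict(data)


@dataclass(frozen=True)
class MatchResult:
    """Best-matching configuration of one task for a target profile."""

    task_id: str
    params: Mapping[str, Level]
    predicted: DemandProfile
    distance: float
    included: bool = True

    def as_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "params": dict(self.params),
            "predicted_profile": self.predicted.rounded().as_dict(),
            "distance": round(self.distance, 4),
            "included": self.included,
        }


def match_task(
    registry: ModelRegistry,
    target: DemandProfile,
    task_id: str,
    weights: Optional[Mapping[str, float]] = None,
) -> MatchResult:
    """Exhaustive inverse lookup over one task's parameter grid.

    Returns the configuration minimizing the weighted Euclidean distance
    between its predicted profile and the target.  Grid enumeration is
    lexicographic (declared parameter order, lowest levels first) and only a
    strictly smaller distance replaces the incumbent, so ties resolve to the
    lexicographically first optimum.
    """
    configs, profiles = registry.grid_profiles(task_id)
    best_cfg = None
    best_profile = None
    best_d = float("inf")
    for cfg, profile in zip(configs, profiles):
        d = profile.distance(target, weights)
        if d < best_d:
            best_cfg, best_profile, best_d = cfg, profile, d
    return MatchResult(task_id, dict(best_cfg), best_profile, best_d)


def task_subseed(program_seed: int, task_id: str) -> int:
    """Stable per-task sub-seed so one program seed reproduces all content."""
    digest = hashlib.sha256(f"{program_seed}/{task_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class ProgramResult:
    """A full training program: one match per task, documents for the
    included ones."""

    target: DemandProfile
    matches: Tuple[MatchResult, ...]
    documents: Tuple  # of TaskDocument, included tasks only
    seed: int
    filter_close: bool
    threshold: Optional[float]

    def manifest(self) -> dict:
        return {
            "target_profile": self.target.as_dict(),
            "seed": self.seed,
            "filter_close": self.filter_close,
            "threshold": self.threshold,
            "tasks": [m.as_dict() for m in self.matches],
        }


def generate_program(
    registry: ModelRegistry,
    target: DemandProfile,
    seed: int,
    filter_close: bool = False,
    threshold: float = 1.5,
    weights: Optional[Mapping[str, float]] = None,
    bank=None,
) -> ProgramResult:
    """Match all 11 tasks to the target and generate content for the
    included ones.

    With ``filter_close`` set, tasks whose match distance exceeds
    ``threshold`` are marked excluded and produce no document; otherwise all
    11 documents are generated.  Content randomness is derived per task from
    the program seed, so a single seed reproduces the whole program.
    """
    if filter_close and not (threshold > 0):
        raise ValidationError("threshold must be positive when filtering")
    from .generation import generate_task  # local import: generation pulls banks

    matches: List[MatchResult] = []
    documents = []
    for task_id in TASK_IDS:
        match = match_task(registry, target, task_id, weights)
        included = (not filter_close) or match.distance <= threshold
        match = MatchResult(
            match.task_id, match.params, match.predicted, match.distance, included
        )
        matches.append(match)
        if included:
            documents.append(
                generate_task(
                    task_id,
                    match.params,
                    seed=task_subseed(seed, task_id),
                    bank=bank,
                    registry=registry,
                )
            )
    return ProgramResult(
        target=target,
        matches=tuple(matches),
        documents=tuple(documents),
        seed=seed,
        filter_close=filter_close,
        threshold=threshold if filter_close else None,
    )
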