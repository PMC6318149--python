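"""The five rating axes and the demand/patient profile container.

Every training task is rated by rehabilitation experts on four cognitive
domains -- memory, executive functions, attention, language -- plus an
overall difficulty axis, each on a 1-10 Likert scale.  A
:class:`DemandProfile` is one point in that five-dimensional rating space:
it describes either how taxing a concrete task configuration is, or the
training intensity targeted for a patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping, Optional

from .errors import ValidationError

#: Canonical axis order used everywhere (serialization, distances, reports).
AXES = (
    "memory",
    "executive_functions",
    "attention",
    "language",
    "difficulty",
)

#: The four cognitive domains (difficulty excluded).
COGNITIVE_AXES = AXES[:4]

RATING_MIN = 1.0
RATING_MAX = 10.0


def clamp_rating(value: float) -> float:
    """Clamp a predicted demand onto the 1-10 rating scale."""
    return min(RATING_MAX, max(RATING_MIN, float(value)))


def round_rating(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching the printed two-decimal precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DemandProfile:
    """Five demand values on the 1-10 expert rating scale."""

    memory: float
    executive_functions: float
    attention: float
    language: float
    difficulty: float

    def __post_init__(self):
        for axis in AXES:
            v = getattr(self, axis)
            if not math.isfinite(v) or not (RATING_MIN <= v <= RATING_MAX):
                raise ValidationError(
                    f"profile axis {axis!r} must lie in [1, 10], got {v!r}"
                )

    def as_dict(self) -> Dict[str, float]:
        return {axis: float(getattr(self, axis)) for axis in AXES}

    def rounded(self, ndigits: int = 2) -> "DemandProfile":
        return DemandProfile(**{a: round_rating(getattr(self, a), ndigits) for a in AXES})

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "DemandProfile":
        missing = [a for a in AXES if a not in data]
        if missing:
            raise ValidationError(f"profile missing axes: {', '.join(missing)}")
        unknown = [k for k in data if k not in AXES]
        if unknown:
            raise ValidationError(f"unknown profile axes: {', '.join(sorted(unknown))}")
        return cls(**{a: float(data[a]) for a in AXES})

    def distance(
        self,
        other: "DemandProfile",
        weights: Optional[Mapping[str, float]] = None,
        axes: Iterable[str] = AXES,
    ) -> float:
        """Weighted Euclidean distance to another profile.

        Weights default to 1 on every axis; negative weights are rejected and
        an all-zero weighting is meaningless for matching.
        """
        w = dict.fromkeys(AXES, 1.0)
        if weights is not None:
            for k, v in weights.items():
                if k not in AXES:
                    raise ValidationError(f"unknown axis in weights: {k!r}")
                if v < 0:
                    raise ValidationError(f"negative weight for axis {k!r}")
                w[k] = float(v)
        axes = tuple(axes)
        if not any(w[a] > 0 for a in axes):
            raise ValidationError("at least one axis weight must be positive")
        return math.sqrt(
            sum(w[a] * (getattr(self, a) - getattr(other, a)) ** 2 for a in axes)
        )
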