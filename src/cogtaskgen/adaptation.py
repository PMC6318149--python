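"""Between-session difficulty adaptation.

After each training session the clinician scores every completed sheet on a
0-100% scale.  The mean performance drives a simple staircase on the
difficulty axis only: sustained success (mean >= 70%) raises difficulty by
0.5 rating points, poor performance (mean <= 50%) lowers it by 0.5, and the
50-70% band leaves the profile untouched.  The four cognitive axes are
never altered by session scores -- they change only through reassessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .axes import DemandProfile, clamp_rating
from .errors import ValidationError
from .matching import MoCAScores, moca_to_profile

#: Performance band edges (inclusive): mean >= RAISE_AT raises difficulty,
#: mean <= LOWER_AT lowers it.
RAISE_AT = 70.0
LOWER_AT = 50.0
STEP = 0.5


@dataclass(frozen=True)
class SessionResult:
    """Per-task performance scores (0-100%) for one training session."""

    scores: Mapping[str, float]
    date: str = ""

    def __post_init__(self):
        if not self.scores:
            raise ValidationError("session holds no task scores")
        for task, score in self.scores.items():
            if not (0.0 <= float(score) <= 100.0):
                raise ValidationError(
                    f"score for {task!r} must lie in [0, 100], got {score!r}"
                )

    @property
    def mean_score(self) -> float:
        return sum(float(v) for v in self.scores.values()) / len(self.scores)


def update_profile(profile: DemandProfile, session: SessionResult) -> DemandProfile:
    """Apply the three-branch difficulty staircase to a profile."""
    mean = session.mean_score
    difficulty = profile.difficulty
    if mean >= RAISE_AT:
        difficulty += STEP
    elif mean <= LOWER_AT:
        difficulty -= STEP
    return DemandProfile(
        memory=profile.memory,
        executive_functions=profile.executive_functions,
        attention=profile.attention,
        language=profile.language,
        difficulty=clamp_rating(difficulty),
    )


def reassess(new_moca: MoCAScores, invert: bool = False) -> DemandProfile:
    """Rebuild the profile from a fresh MoCA assessment; the prior profile
    is discarded."""
    return moca_to_profile(new_moca, invert=invert)
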