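"""Task parameter spaces: the discrete levels each training task can take.

Each of the 11 paper-and-pencil tasks exposes a small set of parameters
(word count, number of operations, maze size, ...).  A
:class:`TaskParameterSpace` records, per parameter, the allowed levels and a
numeric encoding of each level; the encodings are the independent variables
the linear demand models act on.  Indicator encodings place the easier level
at 0 (numeric problems before textual ones, no clue before picture clues);
ordered categorical levels are encoded 0, 1, 2 in increasing-demand order.

The grids are deliberately small: the full Cartesian product of any task is
enumerable in well under a second, which is what makes exhaustive profile
matching and range computation practical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple, Union

from .errors import InvalidParameterError, OutOfRangeError, UnknownTaskError

Level = Union[int, str]


@dataclass(frozen=True)
class Parameter:
    """One tunable task parameter.

    kind is ``count`` (integer levels, identity encoding), ``binary`` or
    ``categorical`` (explicit per-level encoding).
    """

    name: str
    kind: str
    levels: Tuple[Level, ...]
    encoding: Mapping[Level, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError(f"parameter {self.name!r} needs >= 2 levels")
        if self.encoding is None:
            object.__setattr__(
                self, "encoding", {lv: float(lv) for lv in self.levels}
            )
        for lv in self.levels:
            if lv not in self.encoding:
                raise ValueError(f"parameter {self.name!r}: level {lv!r} unencoded")

    def encode(self, level: Level) -> float:
        if level not in self.encoding:
            raise OutOfRangeError(
                f"level {level!r} not allowed for parameter {self.name!r}; "
                f"allowed: {list(self.levels)}"
            )
        return float(self.encoding[level])

    @property
    def min_encoding(self) -> float:
        return min(self.encoding[lv] for lv in self.levels)

    @property
    def max_encoding(self) -> float:
        return max(self.encoding[lv] for lv in self.levels)


@dataclass(frozen=True)
class TaskParameterSpace:
    """Ordered parameter collection of one task; supports grid enumeration."""

    task_id: str
    parameters: Tuple[Parameter, ...]

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate parameter names in {self.task_id}")

    @property
    def parameter_names(self) -> List[str]:
        return [p.name for p in self.parameters]

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise InvalidParameterError(
            f"task {self.task_id!r} has no parameter {name!r}; "
            f"known: {self.parameter_names}"
        )

    def validate(self, assignment: Mapping[str, Level]) -> None:
        """Check a full assignment: every parameter present, every level legal."""
        for name in assignment:
            self.parameter(name)  # raises on unknown names
        for p in self.parameters:
            if p.name not in assignment:
                raise InvalidParameterError(
                    f"task {self.task_id!r}: missing parameter {p.name!r}"
                )
            p.encode(assignment[p.name])

    def encode(self, assignment: Mapping[str, Level]) -> Dict[str, float]:
        return {p.name: p.encode(assignment[p.name]) for p in self.parameters
                if p.name in assignment}

    def grid(self) -> Iterator[Dict[str, Level]]:
        """All configurations in lexicographic order (declared parameter
        order, lowest/first-declared levels first)."""
        names = self.parameter_names
        for combo in itertools.product(*(p.levels for p in self.parameters)):
            yield dict(zip(names, combo))

    def grid_size(self) -> int:
        n = 1
        for p in self.parameters:
            n *= len(p.levels)
        return n


def _space(task_id: str, *params: Parameter) -> TaskParameterSpace:
    return TaskParameterSpace(task_id, tuple(params))


def _count(name: str, lo: int, hi: int, step: int = 1) -> Parameter:
    return Parameter(name, "count", tuple(range(lo, hi + 1, step)))


#: The 11 task identifiers, in canonical program order.
TASK_IDS = (
    "word_search",
    "problem_resolution",
    "numeric_sequences",
    "action_sequencing",
    "association",
    "cancellation",
    "categorization",
    "comprehension_of_contexts",
    "image_pairs",
    "mazes",
    "memory_of_stories",
)

DEFAULT_SPACES: Dict[str, TaskParameterSpace] = {
    s.task_id: s
    for s in (
        _space(
            "word_search",
            _count("words", 4, 10),
            # Only picture clues were reported to raise demand; word clues are
            # encoded with the no-clue baseline.
            Parameter("clue", "categorical", ("none", "word", "picture"),
                      {"none": 0.0, "word": 0.0, "picture": 1.0}),
        ),
        _space(
            "problem_resolution",
            Parameter("type", "binary", ("numeric", "textual"),
                      {"numeric": 0.0, "textual": 1.0}),
            _count("operations", 1, 4),
            Parameter("digits", "binary", ("ones", "tens"),
                      {"ones": 0.0, "tens": 1.0}),
        ),
        _space(
            "numeric_sequences",
            _count("step", 1, 5),
            Parameter("direction", "binary", ("ascending", "descending"),
                      {"ascending": 0.0, "descending": 1.0}),
            _count("missing", 1, 3),
            # Omitting numbers at the start of the sequence is the demanding
            # variant; middle and end share the baseline encoding.
            Parameter("position", "categorical", ("start", "middle", "end"),
                      {"start": 1.0, "middle": 0.0, "end": 0.0}),
        ),
        _space(
            "action_sequencing",
            _count("actions", 3, 8),
            Parameter("goal", "binary", ("given", "hidden"),
                      {"given": 0.0, "hidden": 1.0}),
        ),
        _space("association", _count("pairs", 3, 10)),
        _space(
            "cancellation",
            # Ordered by reported demand: numbers < letters < symbols.
            Parameter("stimulus", "categorical", ("numbers", "letters", "symbols"),
                      {"numbers": 0.0, "letters": 1.0, "symbols": 2.0}),
            _count("targets", 1, 3),
            _count("distractors", 2, 8),
            _count("pool", 50, 200, 25),
            Parameter("arrangement", "binary", ("random", "grid"),
                      {"random": 0.0, "grid": 1.0}),
        ),
        _space(
            "categorization",
            _count("categories", 2, 5),
            _count("items", 3, 8),
        ),
        # The study rated context-comprehension variants with 2 or 3
        # descriptions; the published demand ranges span exactly that grid.
        _space("comprehension_of_contexts", _count("descriptions", 2, 3)),
        _space("image_pairs", _count("pairs", 3, 10)),
        _space("mazes", _count("size", 5, 15, 2)),
        _space(
            "memory_of_stories",
            Parameter("type", "binary", ("textual", "pictorial"),
                      {"textual": 0.0, "pictorial": 1.0}),
            Parameter("size", "categorical", ("short", "medium", "long"),
                      {"short": 0.0, "medium": 1.0, "long": 2.0}),
            _count("questions", 2, 6),
        ),
    )
}


def get_space(task_id: str) -> TaskParameterSpace:
    try:
        return DEFAULT_SPACES[task_id]
    except KeyError:
        raise UnknownTaskError(
            f"unknown task {task_id!r}; known tasks: {', '.join(TASK_IDS)}"
        ) from None
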