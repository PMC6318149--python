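"""Content banks: the fixed text collections the generators draw from.

Banks hold word lists, association pairs, category sets, activities-of-
daily-living action sequences, context scenes, story templates and textual
problem templates.  Image-based content (picture clues, image pairs,
pictorial stories, scene drawings) is represented by stable asset
identifiers (``img:...``) plus alt text; rendering embeds placeholders, the
package ships no artwork.

Stories and scene descriptions are *templates* with randomized slot fillers
(names, counts, objects), so the procedural generators can produce far more
distinct documents than the bank holds verbatim entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import BankExhaustedError, SchemaError

_DATA_PACKAGE = "cogtaskgen.data.banks"


@dataclass(frozen=True)
class WordEntry:
    word: str
    picture: str  # asset identifier for the picture clue


@dataclass(frozen=True)
class AssociationPair:
    left: str
    right: str


@dataclass(frozen=True)
class ActionSequence:
    goal: str
    steps: Tuple[str, ...]  # canonical correct order


@dataclass(frozen=True)
class SceneFact:
    """One fact of a scene: a description template with one blank, the
    correct filler, and foil fillers that make the description false."""

    template: str
    correct: str
    foils: Tuple[str, ...]

    def render(self, filler: str) -> str:
        return self.template.replace("{}", filler)

    @property
    def correct_text(self) -> str:
        return self.render(self.correct)


@dataclass(frozen=True)
class Scene:
    scene_id: str
    title: str
    asset: str
    facts: Tuple[SceneFact, ...]

    def correct_renders(self) -> List[str]:
        return [f.correct_text for f in self.facts]

    def incorrect_renders(self) -> List[str]:
        return [f.render(foil) for f in self.facts for foil in f.foils]


@dataclass(frozen=True)
class StoryQuestion:
    question: str  # template over the story slots
    answer: str    # template over the story slots (plus derived values)


@dataclass(frozen=True)
class StoryTemplate:
    """A story with randomized slots; answers derive from the slot values."""

    story_id: str
    length: str                      # short | medium | long
    text: str                        # template over slots
    panels: Tuple[str, ...]          # pictorial asset-id templates
    slots: Mapping[str, Tuple[str, ...]]
    derived: Mapping[str, Tuple[str, ...]]  # name -> slot names summed
    questions: Tuple[StoryQuestion, ...]

    def instantiate(self, rng) -> Dict[str, Union[str, int]]:
        """Draw one value per slot and compute derived sums."""
        elements: Dict[str, Union[str, int]] = {}
        for name in sorted(self.slots):
            choice = rng.choice(list(self.slots[name]))
            elements[name] = int(choice) if isinstance(choice, int) else choice
        for name in sorted(self.derived):
            elements[name] = sum(int(elements[s]) for s in self.derived[name])
        return elements


@dataclass(frozen=True)
class ProblemTemplate:
    """A daily-living word-problem template; operand slots are {0}, {1}, ..."""

    ops: Tuple[str, ...]  # "+" / "-" between consecutive operands
    text: str


class ContentBank:
    """All content collections, loaded from JSON documents."""

    def __init__(
        self,
        words: Sequence[WordEntry],
        associations: Sequence[AssociationPair],
        categories: Mapping[str, Sequence[str]],
        actions: Sequence[ActionSequence],
        scenes: Sequence[Scene],
        stories: Sequence[StoryTemplate],
        problems: Sequence[ProblemTemplate],
    ):
        self.words = list(words)
        self.associations = list(associations)
        self.categories = {k: list(v) for k, v in categories.items()}
        self.actions = list(actions)
        self.scenes = list(scenes)
        self.stories = list(stories)
        self.problems = list(problems)

    # -- selection helpers -------------------------------------------------

    def require_words(self, n: int, max_len: Optional[int] = None) -> List[WordEntry]:
        pool = [w for w in self.words if max_len is None or len(w.word) <= max_len]
        if len(pool) < n:
            raise BankExhaustedError(
                f"word bank holds {len(pool)} eligible words, need {n}"
            )
        return pool

    def stories_of(self, length: str) -> List[StoryTemplate]:
        pool = [s for s in self.stories if s.length == length]
        if not pool:
            raise BankExhaustedError(f"story bank has no {length!r} stories")
        return pool

    def story(self, story_id: str) -> StoryTemplate:
        for s in self.stories:
            if s.story_id == story_id:
                return s
        raise BankExhaustedError(f"story bank has no story {story_id!r}")

    def scene(self, scene_id: str) -> Scene:
        for s in self.scenes:
            if s.scene_id == scene_id:
                return s
        raise BankExhaustedError(f"scene bank has no scene {scene_id!r}")

    def problems_with_ops(self, n_ops: int) -> List[ProblemTemplate]:
        pool = [p for p in self.problems if len(p.ops) == n_ops]
        if not pool:
            raise BankExhaustedError(
                f"problem bank has no template with {n_ops} operations"
            )
        return pool

    # -- loading -----------------------------------------------------------

    @classmethod
    def default(cls) -> "ContentBank":
        """The bank shipped with the package."""
        root = resources.files(_DATA_PACKAGE)
        return cls.from_files({
            name: json.loads((root / f"{name}.json").read_text(encoding="utf-8"))
            for name in (
                "words", "associations", "categories", "actions",
                "scenes", "stories", "problems",
            )
        })

    @classmethod
    def from_dir(cls, path: Union[str, Path]) -> "ContentBank":
        path = Path(path)
        data = {}
        for name in ("words", "associations", "categories", "actions",
                     "scenes", "stories", "problems"):
            with open(path / f"{name}.json", encoding="utf-8") as fh:
                data[name] = json.load(fh)
        return cls.from_files(data)

    @classmethod
    def from_files(cls, data: Mapping[str, object]) -> "ContentBank":
        try:
            words = [WordEntry(e["word"].upper(), e["picture"]) for e in data["words"]]
            associations = [
                AssociationPair(e["left"], e["right"]) for e in data["associations"]
            ]
            categories = {k: list(v) for k, v in data["categories"].items()}
            actions = [
                ActionSequence(e["goal"], tuple(e["steps"])) for e in data["actions"]
            ]
            scenes = [
                Scene(
                    e["id"], e["title"], e["asset"],
                    tuple(
                        SceneFact(f["template"], f["correct"], tuple(f["foils"]))
                        for f in e["facts"]
                    ),
                )
                for e in data["scenes"]
            ]
            stories = [
                StoryTemplate(
                    e["id"], e["length"], e["text"], tuple(e.get("panels", ())),
                    {k: tuple(v) for k, v in e["slots"].items()},
                    {k: tuple(v) for k, v in e.get("derived", {}).items()},
                    tuple(StoryQuestion(q["q"], q["a"]) for q in e["questions"]),
                )
                for e in data["stories"]
            ]
            problems = [
                ProblemTemplate(tuple(e["ops"]), e["text"]) for e in data["problems"]
            ]
        except (KeyError, TypeError, AttributeError) as exc:
            raise SchemaError([f"malformed content bank: {exc!r}"]) from exc
        _validate(categories, stories, scenes)
        return cls(words, associations, categories, actions, scenes, stories, problems)


def _validate(categories, stories, scenes):
    offences = []
    seen: Dict[str, str] = {}
    for cat, items in categories.items():
        for item in items:
            if item in seen:
                offences.append(
                    f"item {item!r} in both {seen[item]!r} and {cat!r}"
                )
            seen[item] = cat
    for s in stories:
        refs = set(s.slots) | set(s.derived)
        for q in s.questions:
            for field in (q.question, q.answer):
                for token in _format_fields(field):
                    if token not in refs:
                        offences.append(
                            f"story {s.story_id}: question references unknown "
                            f"slot {token!r}"
                        )
        for name, parts in s.derived.items():
            for part in parts:
                if part not in s.slots:
                    offences.append(
                        f"story {s.story_id}: derived {name!r} uses unknown "
                        f"slot {part!r}"
                    )
    for sc in scenes:
        for f in sc.facts:
            if "{}" not in f.template:
                offences.append(f"scene {sc.scene_id}: template without blank")
    if offences:
        raise SchemaError(offences)


def _format_fields(template: str):
    import string

    for _, field, _, _ in string.Formatter().parse(template):
        if field:
            yield field
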