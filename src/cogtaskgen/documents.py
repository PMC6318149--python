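"""The printable task document: parameters, content, answer key, profile.

A :class:`TaskDocument` is the unit the generators produce: everything
needed to print one worksheet plus its answer key, together with the
configuration it was generated from, its predicted demand profile (rounded
to the two decimals the rating summaries use), and the seed that makes the
document reproducible.  Serialization is canonical JSON (sorted keys, fixed
separators) so identical documents are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping

from .errors import ValidationError


@dataclass(frozen=True)
class TaskDocument:
    task_id: str
    params: Mapping[str, Any]
    content: Mapping[str, Any]
    answer_key: Mapping[str, Any]
    profile: Mapping[str, float]
    seed: int
    locale: str = "en"

    def to_dict(self) -> Dict[str, Any]:
        return {
            "task_id": self.task_id,
            "params": dict(self.params),
            "content": self.content,
            "answer_key": self.answer_key,
            "profile": dict(self.profile),
            "seed": self.seed,
            "locale": self.locale,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "TaskDocument":
        required = {"task_id", "params", "content", "answer_key", "profile", "seed"}
        missing = required - set(data)
        if missing:
            raise ValidationError(
                f"document missing fields: {', '.join(sorted(missing))}"
            )
        return cls(
            task_id=data["task_id"],
            params=dict(data["params"]),
            content=data["content"],
            answer_key=data["answer_key"],
            profile=dict(data["profile"]),
            seed=int(data["seed"]),
            locale=data.get("locale", "en"),
        )

    @classmethod
    def from_json(cls, text: str) -> "TaskDocument":
        return cls.from_dict(json.loads(text))
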