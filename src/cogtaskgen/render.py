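"""Plain-text and HTML rendering of task documents.

The sheet (what the patient receives) and the answer key (what the
clinician keeps) are rendered separately.  Image content appears as
``[image: ...]`` placeholders around stable asset identifiers.
"""

from __future__ import annotations

import html
from typing import Callable, Dict, List, Tuple

from .documents import TaskDocument
from .errors import UnknownTaskError

_TITLES = {
    "word_search": "Word search",
    "problem_resolution": "Problem resolution",
    "numeric_sequences": "Numeric sequences",
    "action_sequencing": "Action sequencing",
    "association": "Association",
    "cancellation": "Cancellation",
    "categorization": "Categorization",
    "comprehension_of_contexts": "Comprehension of contexts",
    "image_pairs": "Image pairs",
    "mazes": "Maze",
    "memory_of_stories": "Memory of stories",
}


def _seq_line(terms) -> str:
    return "  ".join("____" if t is None else str(t) for t in terms)


def _sheet_word_search(doc) -> List[str]:
    lines = ["Find all the hidden words. Words read forward, down, up, "
             "or diagonally and may share letters."]
    lines.append("")
    lines += [" ".join(row) for row in doc.content["grid"]]
    if doc.content["clue_mode"] == "word":
        lines += ["", "Words to find:"]
        lines += [f"  - {w}" for w in doc.content["clues"]]
    elif doc.content["clue_mode"] == "picture":
        lines += ["", "Picture clues:"]
        lines += [f"  - [image: {p}]" for p in doc.content["clues"]]
    return lines


def _key_word_search(doc) -> List[str]:
    return [
        f"{p['word']}: row {p['row'] + 1}, column {p['col'] + 1}, {p['direction']}"
        for p in doc.answer_key["placements"]
    ]


def _sheet_cancellation(doc) -> List[str]:
    lines = [f"Cross out every occurrence of: {'  '.join(doc.content['targets'])}"]
    lines.append("")
    if doc.content["arrangement"] == "grid":
        lines += [" ".join(f"{s:>2}" for s in row) for row in doc.content["cells"]]
    else:
        canvas = doc.content["canvas"]
        board = [["  "] * canvas for _ in range(canvas)]
        for it in doc.content["items"]:
            board[it["y"]][it["x"]] = f"{it['s']:>2}"
        lines += ["".join(row) for row in board]
    return lines


def _key_cancellation(doc) -> List[str]:
    lines = [f"Total targets: {doc.answer_key['count']}"]
    if doc.content["arrangement"] == "grid":
        lines.append("Positions (row, column): " + ", ".join(
            f"({r + 1},{c + 1})" for r, c in doc.answer_key["positions"]
        ))
    else:
        lines.append("Item numbers: " + ", ".join(
            str(i + 1) for i in doc.answer_key["indices"]
        ))
    return lines


def _sheet_numeric_sequences(doc) -> List[str]:
    lines = ["Fill in the missing numbers of each sequence."]
    lines.append("")
    for i, seq in enumerate(doc.content["sequences"], 1):
        lines.append(f"{i}.  {_seq_line(seq['terms'])}")
    return lines


def _key_numeric_sequences(doc) -> List[str]:
    return [
        f"{i}.  {', '.join(str(v) for v in ans)}"
        for i, ans in enumerate(doc.answer_key["answers"], 1)
    ]


def _sheet_maze(doc) -> List[str]:
    return ["Find the way from S to E.", ""] + doc.content["ascii"]


def _key_maze(doc) -> List[str]:
    path = doc.answer_key["path"]
    return ["Solution path (row, column): " + " -> ".join(
        f"({r + 1},{c + 1})" for r, c in path
    )]


def _sheet_arithmetic(doc) -> List[str]:
    if doc.content["type"] == "numeric":
        return ["Solve:", "", f"   {doc.content['expression']} = ______"]
    return [doc.content["text"], "", "Answer: ______"]


def _key_arithmetic(doc) -> List[str]:
    return [f"Result: {doc.answer_key['result']}"]


def _sheet_association(doc) -> List[str]:
    lines = ["Draw a line between each item on the left and the item it "
             "belongs with on the right.", ""]
    for lft, rgt in zip(doc.content["left"], doc.content["right"]):
        lines.append(f"  {lft:<15}        {rgt}")
    return lines


def _key_association(doc) -> List[str]:
    return [f"{lft} - {rgt}" for lft, rgt in doc.answer_key["pairs"].items()]


def _sheet_categorization(doc) -> List[str]:
    lines = [
        f"Group these items into {doc.content['n_categories']} categories. "
        "The categories are not given: find them yourself.", "",
    ]
    lines += [f"  {item}" for item in doc.content["items"]]
    return lines


def _key_categorization(doc) -> List[str]:
    return [
        f"{cat}: {', '.join(items)}"
        for cat, items in doc.answer_key["groups"].items()
    ]


def _sheet_image_pairs(doc) -> List[str]:
    lines = [doc.content["instruction"], "", "Memorize:"]
    for p in doc.content["pairs"]:
        lines.append(f"  [image: {p['a']}] - [image: {p['b']}]")
    lines += ["", "Recall page (after 30 minutes) - complete each pair:"]
    for a in doc.content["recall_order"]:
        lines.append(f"  [image: img:{a}] - ____________")
    return lines


def _key_image_pairs(doc) -> List[str]:
    return [f"{a} - {b}" for a, b in doc.answer_key["pairs"].items()]


def _sheet_action_sequencing(doc) -> List[str]:
    lines = []
    if doc.content["goal"]:
        lines.append(f"Goal: {doc.content['goal']}")
    else:
        lines.append("Put the actions in the right order and name the goal.")
    lines += ["", "Number the actions in the correct order:"]
    lines += [f"  ___  {a}" for a in doc.content["actions"]]
    return lines


def _key_action_sequencing(doc) -> List[str]:
    lines = [f"Goal: {doc.answer_key['goal']}"]
    lines += [
        f"{i + 1}. {step}" for i, step in enumerate(doc.answer_key["canonical"])
    ]
    return lines


def _sheet_comprehension(doc) -> List[str]:
    lines = [
        f"{doc.content['title']}  [image: {doc.content['asset']}]", "",
        "Mark the descriptions that match the scene:",
    ]
    for i, d in enumerate(doc.content["descriptions"], 1):
        lines.append(f"  [ ] {i}. {d}")
    return lines


def _key_comprehension(doc) -> List[str]:
    return ["Correct descriptions: " + ", ".join(
        str(i + 1) for i in doc.answer_key["correct_indices"]
    )]


def _sheet_memory_of_stories(doc) -> List[str]:
    if doc.content["mode"] == "pictorial":
        lines = ["Look carefully at the picture story:", ""]
        lines += [f"  [image: {p}]" for p in doc.content["panels"]]
    else:
        lines = ["Read the story carefully:", "", doc.content["text"]]
    lines += ["", "Now answer without looking back:"]
    for i, q in enumerate(doc.content["questions"], 1):
        lines.append(f"  {i}. {q}")
    return lines


def _key_memory_of_stories(doc) -> List[str]:
    return [
        f"{i}. {a}" for i, a in enumerate(doc.answer_key["answers"], 1)
    ]


_SHEETS: Dict[str, Tuple[Callable, Callable]] = {
    "word_search": (_sheet_word_search, _key_word_search),
    "cancellation": (_sheet_cancellation, _key_cancellation),
    "numeric_sequences": (_sheet_numeric_sequences, _key_numeric_sequences),
    "mazes": (_sheet_maze, _key_maze),
    "problem_resolution": (_sheet_arithmetic, _key_arithmetic),
    "association": (_sheet_association, _key_association),
    "categorization": (_sheet_categorization, _key_categorization),
    "image_pairs": (_sheet_image_pairs, _key_image_pairs),
    "action_sequencing": (_sheet_action_sequencing, _key_action_sequencing),
    "comprehension_of_contexts": (_sheet_comprehension, _key_comprehension),
    "memory_of_stories": (_sheet_memory_of_stories, _key_memory_of_stories),
}


def render_text(doc: TaskDocument) -> Tuple[str, str]:
    """Render (worksheet, answer key) as plain text."""
    if doc.task_id not in _SHEETS:
        raise UnknownTaskError(f"unknown task {doc.task_id!r}")
    sheet_fn, key_fn = _SHEETS[doc.task_id]
    title = _TITLES[doc.task_id]
    profile = "  ".join(f"{k}={v:.2f}" for k, v in doc.profile.items())
    header = [title, "=" * len(title), ""]
    sheet = header + sheet_fn(doc) + ["", f"[task profile: {profile}]",
                                      f"[seed: {doc.seed}]"]
    key = [f"{title} - answer key", "-" * (len(title) + 13), ""] + key_fn(doc)
    return "\n".join(sheet) + "\n", "\n".join(key) + "\n"


def render_html(doc: TaskDocument) -> str:
    """Single-page HTML: worksheet, then the key on a separate section."""
    sheet, key = render_text(doc)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(_TITLES[doc.task_id])}</title></head><body>"
        f"<pre>{html.escape(sheet)}</pre>"
        "<hr style='page-break-before: always'>"
        f"<pre>{html.escape(key)}</pre>"
        "</body></html>\n"
    )
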