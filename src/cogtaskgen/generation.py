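"""Procedural generation of task content with answer keys.

Every generator is a pure function of (parameters, bank, seed): the same
inputs always produce the byte-identical document, and distinct seeds
produce distinct content.  Each generator has a matching oracle in
:func:`verify_document` that re-derives the answer key from the payload by
an independent route (grid scanning, recounting, sequence reconstruction,
breadth-first search, expression evaluation, bank recheck).
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .axes import AXES
from .banks import ContentBank
from .documents import TaskDocument
from .errors import (
    BankExhaustedError,
    GenerationFailureError,
    UnknownTaskError,
    ValidationError,
)
from .models import ModelRegistry, load_model_registry
from .params import Level, get_space

_default_bank: Optional[ContentBank] = None
_default_registry: Optional[ModelRegistry] = None


def default_bank() -> ContentBank:
    global _default_bank
    if _default_bank is None:
        _default_bank = ContentBank.default()
    return _default_bank


def _registry(registry: Optional[ModelRegistry]) -> ModelRegistry:
    global _default_registry
    if registry is not None:
        return registry
    if _default_registry is None:
        _default_registry = load_model_registry()
    return _default_registry


def _document(task_id, params, content, key, seed, registry) -> TaskDocument:
    reg = _registry(registry)
    profile = reg.profile(task_id, params).rounded().as_dict()
    return TaskDocument(
        task_id=task_id,
        params=dict(params),
        content=content,
        answer_key=key,
        profile=profile,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Word search
# ---------------------------------------------------------------------------

#: Carving directions: forward, down, up, and the top-left/bottom-right
#: diagonal (reversed horizontals are not used).
WORD_DIRECTIONS: Dict[str, Tuple[int, int]] = {
    "right": (0, 1),
    "down": (1, 0),
    "up": (-1, 0),
    "diag": (1, 1),
}

_PLACEMENT_BUDGET = 20000


def _word_candidates(word: str, side: int) -> List[Tuple[str, int, int]]:
    out = []
    n = len(word)
    for name, (dr, dc) in WORD_DIRECTIONS.items():
        for r in range(side):
            for c in range(side):
                r2, c2 = r + dr * (n - 1), c + dc * (n - 1)
                if 0 <= r2 < side and 0 <= c2 < side:
                    out.append((name, r, c))
    return out


def _try_place(words, idx, grid, side, rng, budget, placements) -> bool:
    if idx == len(words):
        return True
    word = words[idx]
    candidates = _word_candidates(word, side)
    rng.shuffle(candidates)
    for name, r, c in candidates:
        if budget[0] <= 0:
            return False
        budget[0] -= 1
        dr, dc = WORD_DIRECTIONS[name]
        cells = [(r + dr * i, c + dc * i) for i in range(len(word))]
        if any(grid.get(cell, word[i]) != word[i] for i, cell in enumerate(cells)):
            continue
        placed = [cell for cell in cells if cell not in grid]
        for i, cell in enumerate(cells):
            grid[cell] = word[i]
        if _try_place(words, idx + 1, grid, side, rng, budget, placements):
            placements.append(
                {"word": word, "row": r, "col": c, "direction": name}
            )
            return True
        for cell in placed:
            del grid[cell]
    return False


def generate_word_search(
    words_number: int,
    clue: str = "none",
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """A pool of random letters hiding ``words_number`` words.

    Words run forward, down, up, or along the main diagonal and may overlap
    where letters agree.  Placement is randomized search with backtracking;
    the grid side is max(longest word, words_number + 4) and grows once
    before generation fails.  The clue mode controls whether the word list,
    picture identifiers, or nothing is printed on the sheet.
    """
    params = {"words": words_number, "clue": clue}
    get_space("word_search").validate(params)
    bank = bank or default_bank()
    rng = random.Random(seed)
    entries = rng.sample(bank.require_words(words_number), words_number)
    chosen = [e.word for e in entries]
    side = max(max(len(w) for w in chosen), words_number + 4)

    placed: List[Dict[str, object]] = []
    for attempt_side in (side, side + 2):
        placed = []
        grid: Dict[Tuple[int, int], str] = {}
        order = sorted(chosen, key=len, reverse=True)
        if _try_place(order, 0, grid, attempt_side, rng,
                      [_PLACEMENT_BUDGET], placed):
            side = attempt_side
            break
    else:
        raise GenerationFailureError(
            f"could not place {words_number} words on a {side + 2}x{side + 2} grid"
        )
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    rows = [
        "".join(grid.get((r, c)) or rng.choice(letters) for c in range(side))
        for r in range(side)
    ]
    placements = sorted(placed, key=lambda p: p["word"])
    clues: Optional[List[str]]
    if clue == "word":
        clues = sorted(chosen)
    elif clue == "picture":
        clues = sorted(e.picture for e in entries)
    else:
        clues = None
    content = {"size": side, "grid": rows, "clue_mode": clue, "clues": clues}
    key = {"placements": placements}
    return _document("word_search", params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Cancellation
# ---------------------------------------------------------------------------

STIMULUS_ALPHABETS: Dict[str, List[str]] = {
    "numbers": [str(i) for i in range(1, 21)],
    "letters": list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"),
    "symbols": list("*#@&%+?$!=~^"),
}


def _grid_shape(pool: int) -> Tuple[int, int]:
    best = (1, pool)
    for r in range(1, int(pool**0.5) + 1):
        if pool % r == 0:
            best = (r, pool // r)
    return best


def generate_cancellation(
    stimulus: str,
    targets: int,
    distractors: int,
    pool: int,
    arrangement: str = "grid",
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """Strike-out sheet: find all occurrences of the target stimuli.

    Each target type occurs a pre-drawn number of times, uniform in
    [0.1, 0.3] x pool size; the rest of the pool is filled with the
    distractor types.  Grid arrangement lays the pool on rows x cols with
    |rows - cols| minimal; random arrangement assigns non-overlapping 2-D
    canvas positions.
    """
    params = {
        "stimulus": stimulus, "targets": targets, "distractors": distractors,
        "pool": pool, "arrangement": arrangement,
    }
    get_space("cancellation").validate(params)
    alphabet = STIMULUS_ALPHABETS[stimulus]
    if targets + distractors > len(alphabet):
        raise ValidationError(
            f"{stimulus} alphabet holds {len(alphabet)} symbols; cannot draw "
            f"{targets} target and {distractors} distractor types"
        )
    rng = random.Random(seed)
    types = rng.sample(alphabet, targets + distractors)
    target_types, distractor_types = types[:targets], types[targets:]
    lo, hi = max(1, int(0.1 * pool)), int(0.3 * pool)
    counts = {t: rng.randint(lo, hi) for t in target_types}
    n_targets = sum(counts.values())
    if n_targets > pool:
        raise ValidationError("target occurrences exceed the pool size")
    stimuli = [t for t, n in counts.items() for _ in range(n)]
    stimuli += [rng.choice(distractor_types) for _ in range(pool - n_targets)]
    rng.shuffle(stimuli)

    content: Dict[str, object] = {
        "stimulus": stimulus,
        "arrangement": arrangement,
        "targets": sorted(target_types),
        "distractor_types": sorted(distractor_types),
        "pool_size": pool,
    }
    if arrangement == "grid":
        r, c = _grid_shape(pool)
        rows = [stimuli[i * c:(i + 1) * c] for i in range(r)]
        content["cells"] = rows
        positions = [
            [i, j] for i in range(r) for j in range(c)
            if rows[i][j] in counts
        ]
        key = {"positions": positions, "count": n_targets}
    else:
        canvas = 1
        while canvas * canvas < 2 * pool:
            canvas += 1
        spots = rng.sample(range(canvas * canvas), pool)
        items = [
            {"x": s % canvas, "y": s // canvas, "s": stim}
            for s, stim in zip(spots, stimuli)
        ]
        content["canvas"] = canvas
        content["items"] = items
        key = {
            "indices": [i for i, it in enumerate(items) if it["s"] in counts],
            "count": n_targets,
        }
    return _document("cancellation", params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Numeric sequences
# ---------------------------------------------------------------------------

#: Sequences per printed sheet. A single arithmetic sequence makes a thin
#: worksheet and (with small starting values) cannot vary enough to keep
#: repeated programs fresh, so each document carries several.
SEQUENCES_PER_SHEET = 6

#: Starting values are drawn from [0, START_MAX].
START_MAX = 20


def _one_sequence(step, direction, missing, position, rng):
    length = 6 + missing
    low = rng.randint(0, START_MAX)
    terms = [low + i * step for i in range(length)]
    if direction == "descending":
        terms.reverse()
    if position == "start":
        blank = range(0, missing)
    elif position == "end":
        blank = range(length - missing, length)
    else:
        s = (length - missing) // 2
        blank = range(s, s + missing)
    visible = [None if i in blank else t for i, t in enumerate(terms)]
    answers = [terms[i] for i in blank]
    return visible, answers


def generate_numeric_sequence(
    step: int,
    direction: str = "ascending",
    missing: int = 1,
    position: str = "middle",
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """Fill-in-the-blanks arithmetic sequences.

    Each sheet holds :data:`SEQUENCES_PER_SHEET` sequences of length
    6 + ``missing`` with contiguous blanks at the requested position; all
    terms are non-negative (a descending sequence starts at its highest
    term).  The key lists the blanked values per sequence.
    """
    params = {
        "step": step, "direction": direction,
        "missing": missing, "position": position,
    }
    get_space("numeric_sequences").validate(params)
    rng = random.Random(seed)
    sequences, answers = [], []
    for _ in range(SEQUENCES_PER_SHEET):
        visible, ans = _one_sequence(step, direction, missing, position, rng)
        sequences.append({"terms": visible})
        answers.append(ans)
    content = {"sequences": sequences}
    key = {"answers": answers}
    return _document("numeric_sequences", params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Mazes
# ---------------------------------------------------------------------------


def _carve_maze(size: int, rng) -> Tuple[set, Dict[Tuple[int, int], Tuple[int, int]]]:
    """Depth-first spanning tree over the size x size cell lattice.

    Returns the carved passage edges and the DFS parent map (rooted at the
    entrance), whose chains give the unique tree paths.
    """
    start = (0, 0)
    visited = {start}
    parents: Dict[Tuple[int, int], Tuple[int, int]] = {}
    passages = set()
    stack = [start]
    while stack:
        r, c = stack[-1]
        neighbors = [
            (r + dr, c + dc)
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0))
            if 0 <= r + dr < size and 0 <= c + dc < size
        ]
        rng.shuffle(neighbors)
        for nxt in neighbors:
            if nxt not in visited:
                visited.add(nxt)
                parents[nxt] = (r, c)
                passages.add(frozenset(((r, c), nxt)))
                stack.append(nxt)
                break
        else:
            stack.pop()
    return passages, parents


def _maze_ascii(size: int, passages: set) -> List[str]:
    side = 2 * size + 1
    grid = [["#"] * side for _ in range(side)]
    for r in range(size):
        for c in range(size):
            grid[2 * r + 1][2 * c + 1] = " "
    for edge in passages:
        (r1, c1), (r2, c2) = sorted(edge)
        grid[r1 + r2 + 1][c1 + c2 + 1] = " "
    grid[0][1] = " "              # entrance above the top-left cell
    grid[side - 1][side - 2] = " "  # exit below the bottom-right cell
    grid[1][1] = "S"
    grid[side - 2][side - 2] = "E"
    return ["".join(row) for row in grid]


def generate_maze(
    size: int,
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """A perfect maze (spanning tree of the cell lattice) with entrance at
    the top-left and exit at the bottom-right cell; the key is the unique
    solution path."""
    params = {"size": size}
    get_space("mazes").validate(params)
    rng = random.Random(seed)
    passages, parents = _carve_maze(size, rng)
    goal = (size - 1, size - 1)
    path = [goal]
    while path[-1] != (0, 0):
        path.append(parents[path[-1]])
    path.reverse()
    content = {
        "size": size,
        "passages": sorted(sorted(edge) for edge in passages),
        "ascii": _maze_ascii(size, passages),
    }
    key = {"path": [list(cell) for cell in path]}
    return _document("mazes", params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Problem resolution
# ---------------------------------------------------------------------------

_OPERAND_RANGES = {"ones": (1, 9), "tens": (10, 99)}
_ARITH_RETRIES = 500


def _draw_operands(ops: Sequence[str], lo: int, hi: int, rng) -> List[int]:
    """Operands keeping every left-to-right partial result non-negative."""
    for _ in range(_ARITH_RETRIES):
        operands = [rng.randint(lo, hi)]
        running = operands[0]
        ok = True
        for op in ops:
            b = rng.randint(lo, hi)
            running = running + b if op == "+" else running - b
            if running < 0:
                ok = False
                break
            operands.append(b)
        if ok:
            return operands
    raise GenerationFailureError("could not satisfy non-negative partial results")


def generate_arithmetic_problem(
    type: str,
    operations: int,
    digits: str = "ones",
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """An addition/subtraction problem, bare or wrapped in a daily-living
    text template; evaluation is left to right and every partial result is
    a non-negative integer."""
    params = {"type": type, "operations": operations, "digits": digits}
    get_space("problem_resolution").validate(params)
    bank = bank or default_bank()
    rng = random.Random(seed)
    lo, hi = _OPERAND_RANGES[digits]
    if type == "textual":
        template = rng.choice(bank.problems_with_ops(operations))
        ops = list(template.ops)
        operands = _draw_operands(ops, lo, hi, rng)
        content = {"type": type, "text": template.text.format(*operands)}
    else:
        ops = [rng.choice("+-") for _ in range(operations)]
        operands = _draw_operands(ops, lo, hi, rng)
        expr = str(operands[0])
        for op, b in zip(ops, operands[1:]):
            expr += f" {op} {b}"
        content = {"type": type, "expression": expr}
    result = operands[0]
    for op, b in zip(ops, operands[1:]):
        result = result + b if op == "+" else result - b
    key = {"result": result, "operands": operands, "operations": ops}
    return _document("problem_resolution", params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Bank-driven tasks
# ---------------------------------------------------------------------------


def _derangement(n: int, rng) -> List[int]:
    while True:
        p = list(range(n))
        rng.shuffle(p)
        if all(p[i] != i for i in range(n)):
            return p


def _non_identity_permutation(n: int, rng) -> List[int]:
    while True:
        p = list(range(n))
        rng.shuffle(p)
        if any(p[i] != i for i in range(n)):
            return p


def _gen_association(params, bank, rng):
    n = params["pairs"]
    if len(bank.associations) < n:
        raise BankExhaustedError(
            f"association bank holds {len(bank.associations)} pairs, need {n}"
        )
    pairs = rng.sample(bank.associations, n)
    perm = _derangement(n, rng)
    content = {
        "left": [p.left for p in pairs],
        "right": [pairs[perm[j]].right for j in range(n)],
    }
    key = {"pairs": {p.left: p.right for p in pairs}}
    return content, key


def _gen_categorization(params, bank, rng):
    n_cat, n_items = params["categories"], params["items"]
    eligible = [c for c, items in bank.categories.items() if len(items) >= n_items]
    if len(eligible) < n_cat:
        raise BankExhaustedError(
            f"category bank has {len(eligible)} sets with >= {n_items} items, "
            f"need {n_cat}"
        )
    chosen = rng.sample(sorted(eligible), n_cat)
    groups = {c: rng.sample(bank.categories[c], n_items) for c in chosen}
    pool = [item for items in groups.values() for item in items]
    rng.shuffle(pool)
    content = {"items": pool, "n_categories": n_cat}
    key = {"groups": {c: sorted(items) for c, items in groups.items()}}
    return content, key


def _gen_image_pairs(params, bank, rng):
    n = params["pairs"]
    if len(bank.associations) < n:
        raise BankExhaustedError(
            f"image-pair bank holds {len(bank.associations)} pairs, need {n}"
        )
    pairs = rng.sample(bank.associations, n)
    shown = [
        {"a": f"img:{p.left}", "a_alt": p.left, "b": f"img:{p.right}", "b_alt": p.right}
        for p in pairs
    ]
    recall = [p.left for p in pairs]
    rng.shuffle(recall)
    content = {
        "pairs": shown,
        "recall_order": recall,
        "instruction": (
            "Study the image pairs, put the sheet away, and complete the "
            "recall page after 30 minutes."
        ),
    }
    key = {"pairs": {p.left: p.right for p in pairs}}
    return content, key


def _gen_action_sequencing(params, bank, rng):
    n, goal_mode = params["actions"], params["goal"]
    eligible = [s for s in bank.actions if len(s.steps) >= n]
    if not eligible:
        raise BankExhaustedError(f"action bank has no sequence with >= {n} steps")
    seq = rng.choice(eligible)
    steps = list(seq.steps[:n])
    perm = _non_identity_permutation(n, rng)
    displayed = [steps[perm[i]] for i in range(n)]
    content = {
        "actions": displayed,
        "goal": seq.goal if goal_mode == "given" else None,
    }
    key = {"canonical": steps, "ranks": [perm[i] for i in range(n)],
           "goal": seq.goal}
    return content, key


def _gen_comprehension(params, bank, rng):
    n = params["descriptions"]
    scene = rng.choice(bank.scenes)
    k_correct = rng.randint(1, n - 1)
    facts = rng.sample(range(len(scene.facts)), n)
    descriptions = []
    correct_flags = []
    for j, fi in enumerate(facts):
        fact = scene.facts[fi]
        if j < k_correct:
            descriptions.append(fact.correct_text)
            correct_flags.append(True)
        else:
            descriptions.append(fact.render(rng.choice(fact.foils)))
            correct_flags.append(False)
    order = list(range(n))
    rng.shuffle(order)
    descriptions = [descriptions[i] for i in order]
    correct_flags = [correct_flags[i] for i in order]
    content = {
        "scene": scene.scene_id,
        "title": scene.title,
        "asset": scene.asset,
        "descriptions": descriptions,
    }
    key = {"correct_indices": [i for i, ok in enumerate(correct_flags) if ok]}
    return content, key


def _gen_memory_of_stories(params, bank, rng):
    mode, length, n_q = params["type"], params["size"], params["questions"]
    story = rng.choice(bank.stories_of(length))
    if len(story.questions) < n_q:
        raise BankExhaustedError(
            f"story {story.story_id} has {len(story.questions)} questions, "
            f"need {n_q}"
        )
    elements = story.instantiate(rng)
    qids = rng.sample(range(len(story.questions)), n_q)
    questions = [story.questions[i].question.format_map(elements) for i in qids]
    answers = [str(story.questions[i].answer.format_map(elements)) for i in qids]
    text = story.text.format_map(elements)
    content = {
        "story_id": story.story_id,
        "mode": mode,
        "elements": {k: v for k, v in elements.items()},
        "questions": questions,
        "question_ids": qids,
        "alt_text": text,
    }
    if mode == "pictorial":
        content["panels"] = [p.format_map(elements) for p in story.panels]
    else:
        content["text"] = text
    key = {"answers": answers}
    return content, key


_BANK_GENERATORS = {
    "association": _gen_association,
    "categorization": _gen_categorization,
    "image_pairs": _gen_image_pairs,
    "action_sequencing": _gen_action_sequencing,
    "comprehension_of_contexts": _gen_comprehension,
    "memory_of_stories": _gen_memory_of_stories,
}


def generate_bank_task(
    task_id: str,
    params: Mapping[str, Level],
    bank: Optional[ContentBank] = None,
    seed: int = 0,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """Generate one of the content-bank tasks (association, categorization,
    image pairs, action sequencing, comprehension of contexts, memory of
    stories)."""
    if task_id not in _BANK_GENERATORS:
        raise UnknownTaskError(f"{task_id!r} is not a bank-driven task")
    get_space(task_id).validate(params)
    bank = bank or default_bank()
    rng = random.Random(seed)
    content, key = _BANK_GENERATORS[task_id](dict(params), bank, rng)
    return _document(task_id, params, content, key, seed, registry)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def generate_task(
    task_id: str,
    params: Mapping[str, Level],
    seed: int = 0,
    bank: Optional[ContentBank] = None,
    registry: Optional[ModelRegistry] = None,
) -> TaskDocument:
    """Generate any of the 11 tasks from a full parameter assignment."""
    params = dict(params)
    if task_id == "word_search":
        return generate_word_search(
            params["words"], params["clue"], bank, seed, registry
        )
    if task_id == "problem_resolution":
        return generate_arithmetic_problem(
            params["type"], params["operations"], params["digits"],
            bank, seed, registry,
        )
    if task_id == "numeric_sequences":
        return generate_numeric_sequence(
            params["step"], params["direction"], params["missing"],
            params["position"], bank, seed, registry,
        )
    if task_id == "cancellation":
        return generate_cancellation(
            params["stimulus"], params["targets"], params["distractors"],
            params["pool"], params["arrangement"], bank, seed, registry,
        )
    if task_id == "mazes":
        return generate_maze(params["size"], bank, seed, registry)
    if task_id in _BANK_GENERATORS:
        return generate_bank_task(task_id, params, bank, seed, registry)
    raise UnknownTaskError(f"unknown task {task_id!r}")


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


@dataclass
class VerificationReport:
    task_id: str
    checks: List[Dict[str, object]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append({"name": name, "passed": bool(passed), "detail": detail})

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def failures(self) -> List[str]:
        return [f"{c['name']}: {c['detail']}" for c in self.checks if not c["passed"]]


def _verify_word_search(doc, report, bank):
    grid = doc.content["grid"]
    side = len(grid)
    ok_cells = True
    for p in doc.answer_key["placements"]:
        dr, dc = WORD_DIRECTIONS[p["direction"]]
        word = p["word"]
        try:
            spelled = "".join(
                grid[p["row"] + dr * i][p["col"] + dc * i] for i in range(len(word))
                if 0 <= p["row"] + dr * i < side and 0 <= p["col"] + dc * i < side
            )
        except IndexError:
            spelled = ""
        if spelled != word:
            ok_cells = False
    report.add("key_cells_spell_words", ok_cells)

    # independent scanner: every keyed word appears in some straight run
    lines = []
    lines += grid                                             # rows, L->R
    cols = ["".join(grid[r][c] for r in range(side)) for c in range(side)]
    lines += cols                                             # top->bottom
    lines += [c[::-1] for c in cols]                          # bottom->top
    for start in range(-side + 1, side):                      # TL->BR diagonals
        diag = "".join(
            grid[r][r - start]
            for r in range(side)
            if 0 <= r - start < side
        )
        lines.append(diag)
    found = {p["word"]: any(p["word"] in ln for ln in lines)
             for p in doc.answer_key["placements"]}
    report.add(
        "scanner_finds_all_words",
        all(found.values()),
        ", ".join(w for w, ok in found.items() if not ok),
    )
    report.add(
        "key_covers_requested_words",
        len(doc.answer_key["placements"]) == doc.params["words"],
    )
    clue_mode = doc.content["clue_mode"]
    clues = doc.content["clues"]
    if clue_mode == "none":
        report.add("no_clues_printed", clues is None)
    elif clue_mode == "word":
        report.add(
            "word_clues_match_key",
            clues == sorted(p["word"] for p in doc.answer_key["placements"]),
        )
    else:
        report.add("picture_clues_present",
                   isinstance(clues, list) and len(clues) == doc.params["words"])


def _verify_cancellation(doc, report, bank):
    targets = set(doc.content["targets"])
    if doc.content["arrangement"] == "grid":
        cells = doc.content["cells"]
        flat = [s for row in cells for s in row]
        keyed = {tuple(p) for p in doc.answer_key["positions"]}
        ok_pos = all(cells[r][c] in targets for r, c in keyed)
        recount = sum(1 for s in flat if s in targets)
        report.add("keyed_positions_hold_targets", ok_pos)
        report.add("recount_matches_key", recount == len(keyed)
                   and recount == doc.answer_key["count"])
        report.add("grid_holds_pool",
                   len(flat) == doc.content["pool_size"])
        r, c = len(cells), len(cells[0])
        best = _grid_shape(doc.content["pool_size"])
        report.add("grid_shape_balanced", abs(r - c) == abs(best[0] - best[1]))
    else:
        items = doc.content["items"]
        keyed = set(doc.answer_key["indices"])
        ok_pos = all(items[i]["s"] in targets for i in keyed)
        recount = sum(1 for it in items if it["s"] in targets)
        coords = {(it["x"], it["y"]) for it in items}
        report.add("keyed_positions_hold_targets", ok_pos)
        report.add("recount_matches_key", recount == len(keyed)
                   and recount == doc.answer_key["count"])
        report.add("positions_non_overlapping", len(coords) == len(items))


def _verify_numeric_sequences(doc, report, bank):
    step = doc.params["step"]
    descending = doc.params["direction"] == "descending"
    all_ok = True
    detail = ""
    for seq, answers in zip(doc.content["sequences"], doc.answer_key["answers"]):
        terms = seq["terms"]
        d = None
        for i in range(len(terms) - 1):
            if terms[i] is not None and terms[i + 1] is not None:
                d = terms[i + 1] - terms[i]
                anchor = i
                break
        if d is None or abs(d) != step or (d < 0) != descending:
            all_ok = False
            detail = "no consistent step found"
            continue
        rebuilt = [terms[anchor] + (i - anchor) * d for i in range(len(terms))]
        if any(t is not None and t != r for t, r in zip(terms, rebuilt)):
            all_ok = False
            detail = "visible terms break the arithmetic progression"
            continue
        if [rebuilt[i] for i, t in enumerate(terms) if t is None] != answers:
            all_ok = False
            detail = "reconstructed blanks disagree with the key"
        if any(r < 0 for r in rebuilt):
            all_ok = False
            detail = "negative term"
    report.add("sequence_reconstruction_matches_key", all_ok, detail)
    report.add(
        "sheet_holds_expected_sequences",
        len(doc.content["sequences"]) == SEQUENCES_PER_SHEET,
    )


def _verify_maze(doc, report, bank):
    size = doc.content["size"]
    edges = {frozenset(map(tuple, e)) for e in doc.content["passages"]}
    report.add("spanning_tree_edge_count", len(edges) == size * size - 1)
    adj: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start, goal = (0, 0), (size - 1, size - 1)
    prev = {start: None}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in adj.get(cur, ()):
            if nxt not in prev:
                prev[nxt] = cur
                queue.append(nxt)
    report.add("all_cells_reachable", len(prev) == size * size)
    if goal in prev:
        path = [goal]
        while path[-1] != start:
            path.append(prev[path[-1]])
        path.reverse()
        report.add(
            "bfs_path_equals_key",
            [list(c) for c in path] == doc.answer_key["path"],
        )
    else:
        report.add("bfs_path_equals_key", False, "exit unreachable")


def _verify_arithmetic(doc, report, bank):
    operands = doc.answer_key["operands"]
    ops = doc.answer_key["operations"]
    result = operands[0]
    ok_partial = result >= 0
    for op, b in zip(ops, operands[1:]):
        result = result + b if op == "+" else result - b
        ok_partial = ok_partial and result >= 0
    report.add("evaluator_matches_key", result == doc.answer_key["result"])
    report.add("partial_results_non_negative", ok_partial)
    if doc.content["type"] == "numeric":
        expr = doc.content["expression"]
        tokens = expr.split()
        rebuilt = [int(t) for t in tokens[0::2]]
        report.add("expression_matches_operands",
                   rebuilt == operands and tokens[1::2] == list(ops))
    else:
        text = doc.content["text"]
        report.add(
            "text_contains_operands",
            all(str(b) in text for b in operands),
        )
        report.add("no_bare_expression", "=" not in text)


def _verify_association(doc, report, bank):
    pairs = {p.left: p.right for p in bank.associations}
    key = doc.answer_key["pairs"]
    report.add("pairs_in_bank",
               all(pairs.get(lft) == rgt for lft, rgt in key.items()))
    left, right = doc.content["left"], doc.content["right"]
    report.add("columns_consistent",
               sorted(key) == sorted(left)
               and sorted(key.values()) == sorted(right))
    report.add(
        "right_column_deranged",
        all(key[lft] != rgt for lft, rgt in zip(left, right)),
    )


def _verify_categorization(doc, report, bank):
    groups = doc.answer_key["groups"]
    ok_membership = all(
        item in bank.categories.get(cat, ())
        for cat, items in groups.items()
        for item in items
    )
    report.add("grouping_matches_bank", ok_membership)
    keyed_items = sorted(i for items in groups.values() for i in items)
    report.add("key_partitions_payload",
               keyed_items == sorted(doc.content["items"]))
    sizes = {len(items) for items in groups.values()}
    report.add("groups_equally_sized", sizes == {doc.params["items"]})
    report.add("group_count_matches", len(groups) == doc.params["categories"])


def _verify_image_pairs(doc, report, bank):
    pairs = {p.left: p.right for p in bank.associations}
    key = doc.answer_key["pairs"]
    report.add("pairs_in_bank",
               all(pairs.get(a) == b for a, b in key.items()))
    shown = {p["a_alt"]: p["b_alt"] for p in doc.content["pairs"]}
    report.add("payload_matches_key", shown == key)
    report.add("recall_order_is_permutation",
               sorted(doc.content["recall_order"]) == sorted(key))


def _verify_action_sequencing(doc, report, bank):
    canonical = doc.answer_key["canonical"]
    ranks = doc.answer_key["ranks"]
    displayed = doc.content["actions"]
    seq = next((s for s in bank.actions if s.goal == doc.answer_key["goal"]), None)
    report.add("sequence_in_bank",
               seq is not None and list(seq.steps[:len(canonical)]) == canonical)
    restored = [None] * len(displayed)
    ok = len(ranks) == len(displayed)
    if ok:
        for i, rank in enumerate(ranks):
            restored[rank] = displayed[i]
        ok = restored == canonical
    report.add("permutation_restores_canonical_order", ok)
    report.add("shuffle_not_identity", displayed != canonical)
    if doc.params["goal"] == "given":
        report.add("goal_line_present", doc.content["goal"] == doc.answer_key["goal"])
    else:
        report.add("goal_line_hidden", doc.content["goal"] is None)


def _verify_comprehension(doc, report, bank):
    scene = bank.scene(doc.content["scene"])
    correct = set(scene.correct_renders())
    incorrect = set(scene.incorrect_renders())
    descs = doc.content["descriptions"]
    keyed = set(doc.answer_key["correct_indices"])
    report.add(
        "keyed_descriptions_correct",
        all(descs[i] in correct for i in keyed),
    )
    report.add(
        "unkeyed_descriptions_incorrect",
        all(descs[i] in incorrect for i in range(len(descs)) if i not in keyed),
    )
    report.add("mix_of_correct_and_incorrect",
               0 < len(keyed) < len(descs))


def _verify_memory_of_stories(doc, report, bank):
    story = bank.story(doc.content["story_id"])
    elements = doc.content["elements"]
    qids = doc.content["question_ids"]
    rebuilt = [
        str(story.questions[i].answer.format_map(elements)) for i in qids
    ]
    report.add("answers_derivable_from_elements",
               rebuilt == doc.answer_key["answers"])
    report.add("question_count_matches",
               len(qids) == doc.params["questions"])
    if doc.params["type"] == "pictorial":
        report.add("panels_present", bool(doc.content.get("panels")))
    else:
        report.add("text_present", bool(doc.content.get("text")))


_VERIFIERS = {
    "word_search": _verify_word_search,
    "cancellation": _verify_cancellation,
    "numeric_sequences": _verify_numeric_sequences,
    "mazes": _verify_maze,
    "problem_resolution": _verify_arithmetic,
    "association": _verify_association,
    "categorization": _verify_categorization,
    "image_pairs": _verify_image_pairs,
    "action_sequencing": _verify_action_sequencing,
    "comprehension_of_contexts": _verify_comprehension,
    "memory_of_stories": _verify_memory_of_stories,
}


def verify_document(
    doc: TaskDocument,
    bank: Optional[ContentBank] = None,
    registry: Optional[ModelRegistry] = None,
) -> VerificationReport:
    """Run the task-specific oracle over a document.

    Also re-derives the demand profile from the stored parameters and checks
    it against the document for every task type.
    """
    if doc.task_id not in _VERIFIERS:
        raise UnknownTaskError(f"unknown task {doc.task_id!r}")
    bank = bank or default_bank()
    reg = _registry(registry)
    report = VerificationReport(doc.task_id)
    expected = reg.profile(doc.task_id, doc.params).rounded().as_dict()
    report.add("profile_matches_models", dict(doc.profile) == expected)
    _VERIFIERS[doc.task_id](doc, report, bank)
    return report
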