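"""Procedural generators: oracles, determinism, non-repetition, mutation."""

import copy
import json
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtaskgen.documents import TaskDocument
from cogtaskgen.errors import (
    BankExhaustedError,
    UnknownTaskError,
    ValidationError,
)
from cogtaskgen.generation import (
    SEQUENCES_PER_SHEET,
    STIMULUS_ALPHABETS,
    WORD_DIRECTIONS,
    generate_arithmetic_problem,
    generate_bank_task,
    generate_cancellation,
    generate_maze,
    generate_numeric_sequence,
    generate_task,
    generate_word_search,
    verify_document,
)
from cogtaskgen.render import render_html, render_text

#: One representative configuration per task used by the broad sweeps.
REPRESENTATIVE = {
    "word_search": {"words": 8, "clue": "none"},
    "problem_resolution": {"type": "numeric", "operations": 3, "digits": "tens"},
    "numeric_sequences": {"step": 2, "direction": "ascending", "missing": 2,
                          "position": "middle"},
    "action_sequencing": {"actions": 8, "goal": "given"},
    "association": {"pairs": 6},
    "cancellation": {"stimulus": "letters", "targets": 2, "distractors": 5,
                     "pool": 100, "arrangement": "grid"},
    "categorization": {"categories": 3, "items": 5},
    "comprehension_of_contexts": {"descriptions": 3},
    "image_pairs": {"pairs": 6},
    "mazes": {"size": 9},
    "memory_of_stories": {"type": "textual", "size": "medium", "questions": 4},
}


class TestWordSearch:
    def test_key_cells_spell_each_word(self, bank):
        doc = generate_word_search(5, "word", bank=bank, seed=3)
        grid = doc.content["grid"]
        for p in doc.answer_key["placements"]:
            dr, dc = WORD_DIRECTIONS[p["direction"]]
            spelled = "".join(
                grid[p["row"] + dr * i][p["col"] + dc * i]
                for i in range(len(p["word"]))
            )
            assert spelled == p["word"]

    def test_scanner_oracle_over_many_seeds(self, bank):
        for seed in range(25):
            doc = generate_word_search(8, "none", bank=bank, seed=seed)
            assert verify_document(doc, bank=bank).passed

    def test_grid_side_rule(self, bank):
        doc = generate_word_search(4, "none", bank=bank, seed=1)
        longest = max(len(p["word"]) for p in doc.answer_key["placements"])
        assert doc.content["size"] >= max(longest, 8)

    def test_clue_modes(self, bank):
        none = generate_word_search(5, "none", bank=bank, seed=2)
        assert none.content["clues"] is None
        words = generate_word_search(5, "word", bank=bank, seed=2)
        assert sorted(words.content["clues"]) == sorted(
            p["word"] for p in words.answer_key["placements"]
        )
        pics = generate_word_search(5, "picture", bank=bank, seed=2)
        assert all(c.startswith("img:") for c in pics.content["clues"])

    def test_corrupted_key_cell_fails_verification(self, bank):
        doc = generate_word_search(5, "none", bank=bank, seed=4)
        broken = json.loads(doc.to_json())
        broken["answer_key"]["placements"][0]["row"] = (
            (broken["answer_key"]["placements"][0]["row"] + 1)
            % len(broken["content"]["grid"])
        )
        report = verify_document(TaskDocument.from_dict(broken), bank=bank)
        assert not report.passed


class TestCancellation:
    def test_keyed_count_matches_recount(self, bank):
        for seed in range(10):
            doc = generate_cancellation("numbers", 1, 4, 50, "grid",
                                        bank=bank, seed=seed)
            flat = [s for row in doc.content["cells"] for s in row]
            targets = set(doc.content["targets"])
            assert sum(s in targets for s in flat) == doc.answer_key["count"]
            assert len(doc.answer_key["positions"]) == doc.answer_key["count"]

    def test_target_share_of_pool(self, bank):
        doc = generate_cancellation("letters", 2, 6, 200, "grid",
                                    bank=bank, seed=5)
        # each of the 2 target types occurs in [0.1, 0.3] x pool
        assert 2 * 20 <= doc.answer_key["count"] <= 2 * 60

    def test_grid_shape_balanced(self, bank):
        doc = generate_cancellation("symbols", 1, 3, 150, "grid",
                                    bank=bank, seed=0)
        rows = doc.content["cells"]
        assert len(rows) * len(rows[0]) == 150
        assert abs(len(rows) - len(rows[0])) <= 5  # 10 x 15 is optimal for 150

    def test_random_arrangement_positions_unique(self, bank):
        doc = generate_cancellation("symbols", 2, 4, 75, "random",
                                    bank=bank, seed=9)
        coords = {(i["x"], i["y"]) for i in doc.content["items"]}
        assert len(coords) == 75
        assert verify_document(doc, bank=bank).passed

    def test_alphabet_exhaustion_rejected(self, bank, monkeypatch):
        # the default grids never exceed an alphabet; shrink one to check
        # the guard
        monkeypatch.setitem(STIMULUS_ALPHABETS, "symbols", list("*#@&"))
        with pytest.raises(ValidationError):
            generate_cancellation("symbols", 3, 4, 50, "grid",
                                  bank=bank, seed=0)


class TestNumericSequences:
    def test_known_sequence_key(self, bank):
        # an ascending step-3 sequence blanked in the middle always keys
        # the value start + 3 * blank_index
        doc = generate_numeric_sequence(3, "ascending", 1, "middle",
                                        bank=bank, seed=0)
        for seq, answer in zip(doc.content["sequences"],
                               doc.answer_key["answers"]):
            terms = seq["terms"]
            blank = terms.index(None)
            anchor = next(i for i, t in enumerate(terms) if t is not None)
            assert answer[0] == terms[anchor] + 3 * (blank - anchor)

    def test_descending_first_blank(self, bank):
        doc = generate_numeric_sequence(2, "descending", 1, "start",
                                        bank=bank, seed=1)
        for seq, answer in zip(doc.content["sequences"],
                               doc.answer_key["answers"]):
            assert seq["terms"][0] is None
            assert answer[0] == seq["terms"][1] + 2

    def test_reconstruction_oracle_over_grid(self, bank):
        rng = random.Random(0)
        for _ in range(10):
            doc = generate_numeric_sequence(
                rng.randint(1, 5),
                rng.choice(["ascending", "descending"]),
                rng.randint(1, 3),
                rng.choice(["start", "middle", "end"]),
                bank=bank, seed=rng.randint(0, 10_000),
            )
            assert verify_document(doc, bank=bank).passed

    def test_all_terms_non_negative(self, bank):
        for seed in range(20):
            doc = generate_numeric_sequence(5, "descending", 3, "end",
                                            bank=bank, seed=seed)
            for seq in doc.content["sequences"]:
                assert all(t is None or t >= 0 for t in seq["terms"])

    def test_sheet_size(self, bank):
        doc = generate_numeric_sequence(1, "ascending", 2, "end",
                                        bank=bank, seed=3)
        assert len(doc.content["sequences"]) == SEQUENCES_PER_SHEET
        for seq in doc.content["sequences"]:
            assert len(seq["terms"]) == 8  # 6 + missing


class TestMaze:
    @pytest.mark.parametrize("size", [5, 9, 15])
    def test_perfect_maze_properties(self, bank, size):
        doc = generate_maze(size, bank=bank, seed=11)
        assert len(doc.content["passages"]) == size * size - 1
        report = verify_document(doc, bank=bank)
        assert report.passed

    def test_extra_passage_breaks_uniqueness_invariant(self, bank):
        doc = generate_maze(5, bank=bank, seed=2)
        broken = json.loads(doc.to_json())
        edges = {tuple(map(tuple, e)) for e in broken["content"]["passages"]}
        for r in range(5):
            for c in range(4):
                e = ((r, c), (r, c + 1))
                if e not in edges and (e[1], e[0]) not in edges:
                    broken["content"]["passages"].append([list(e[0]), list(e[1])])
                    break
            else:
                continue
            break
        report = verify_document(TaskDocument.from_dict(broken), bank=bank)
        assert not report.passed  # edge count no longer size^2 - 1

    def test_same_seed_same_maze(self, bank):
        a = generate_maze(9, bank=bank, seed=5)
        b = generate_maze(9, bank=bank, seed=5)
        assert a.to_json() == b.to_json()


class TestArithmetic:
    def test_single_addition_key(self, bank):
        doc = generate_arithmetic_problem("numeric", 1, "ones", bank=bank, seed=0)
        a, op, b = doc.content["expression"].split()
        expected = int(a) + int(b) if op == "+" else int(a) - int(b)
        assert doc.answer_key["result"] == expected

    def test_evaluator_oracle_many_seeds(self, bank):
        for seed in range(20):
            doc = generate_arithmetic_problem("numeric", 3, "tens",
                                              bank=bank, seed=seed)
            assert verify_document(doc, bank=bank).passed
            assert doc.answer_key["result"] >= 0

    def test_textual_problem_substitutes_operands(self, bank):
        doc = generate_arithmetic_problem("textual", 2, "tens", bank=bank, seed=7)
        text = doc.content["text"]
        for operand in doc.answer_key["operands"]:
            assert str(operand) in text
        assert "{" not in text and "=" not in text

    def test_textual_arity_matches_operations(self, bank):
        for ops in (1, 2, 3, 4):
            doc = generate_arithmetic_problem("textual", ops, "ones",
                                              bank=bank, seed=ops)
            assert len(doc.answer_key["operations"]) == ops
            assert len(doc.answer_key["operands"]) == ops + 1


class TestBankTasks:
    def test_association_derangement(self, bank):
        doc = generate_bank_task("association", {"pairs": 4}, bank=bank, seed=2)
        key = doc.answer_key["pairs"]
        assert len(key) == 4
        for lft, rgt in zip(doc.content["left"], doc.content["right"]):
            assert key[lft] != rgt  # partner never displayed on its own row

    def test_categorization_partition(self, bank):
        doc = generate_bank_task("categorization",
                                 {"categories": 3, "items": 4},
                                 bank=bank, seed=3)
        assert len(doc.content["items"]) == 12
        keyed = sorted(i for items in doc.answer_key["groups"].values()
                       for i in items)
        assert keyed == sorted(doc.content["items"])
        assert verify_document(doc, bank=bank).passed

    def test_action_sequencing_permutation_restores_order(self, bank):
        doc = generate_bank_task("action_sequencing",
                                 {"actions": 6, "goal": "hidden"},
                                 bank=bank, seed=4)
        assert doc.content["goal"] is None
        restored = [None] * 6
        for i, rank in enumerate(doc.answer_key["ranks"]):
            restored[rank] = doc.content["actions"][i]
        assert restored == doc.answer_key["canonical"]
        assert doc.content["actions"] != doc.answer_key["canonical"]

    def test_action_sequencing_goal_given(self, bank):
        doc = generate_bank_task("action_sequencing",
                                 {"actions": 4, "goal": "given"},
                                 bank=bank, seed=5)
        assert doc.content["goal"] == doc.answer_key["goal"]

    def test_comprehension_mixes_correct_and_incorrect(self, bank):
        for seed in range(10):
            doc = generate_bank_task("comprehension_of_contexts",
                                     {"descriptions": 3}, bank=bank, seed=seed)
            keyed = doc.answer_key["correct_indices"]
            assert 0 < len(keyed) < 3
            assert verify_document(doc, bank=bank).passed

    def test_story_answers_derive_from_elements(self, bank):
        doc = generate_bank_task(
            "memory_of_stories",
            {"type": "textual", "size": "long", "questions": 6},
            bank=bank, seed=6,
        )
        story = bank.story(doc.content["story_id"])
        for qid, answer in zip(doc.content["question_ids"],
                               doc.answer_key["answers"]):
            rebuilt = story.questions[qid].answer.format_map(
                doc.content["elements"]
            )
            assert str(rebuilt) == answer

    def test_pictorial_story_uses_panels(self, bank):
        doc = generate_bank_task(
            "memory_of_stories",
            {"type": "pictorial", "size": "short", "questions": 3},
            bank=bank, seed=8,
        )
        assert doc.content["panels"]
        assert "text" not in doc.content

    def test_image_pairs_recall_order_permutes_lefts(self, bank):
        doc = generate_bank_task("image_pairs", {"pairs": 5}, bank=bank, seed=9)
        assert sorted(doc.content["recall_order"]) == sorted(
            doc.answer_key["pairs"]
        )

    def test_bank_exhaustion_names_the_bank(self, bank):
        from cogtaskgen.banks import ContentBank

        tiny = ContentBank(
            words=bank.words[:3], associations=bank.associations[:2],
            categories={"fruits": ["apple", "pear", "plum"]},
            actions=bank.actions[:1], scenes=bank.scenes,
            stories=bank.stories, problems=bank.problems,
        )
        with pytest.raises(BankExhaustedError):
            generate_bank_task("association", {"pairs": 5}, bank=tiny, seed=0)

    def test_unknown_bank_task_rejected(self, bank):
        with pytest.raises(UnknownTaskError):
            generate_bank_task("mazes", {"size": 5}, bank=bank, seed=0)


class TestDocumentContracts:
    @pytest.mark.parametrize("task_id", sorted(REPRESENTATIVE))
    def test_determinism_byte_identical(self, bank, task_id):
        params = REPRESENTATIVE[task_id]
        a = generate_task(task_id, params, seed=123, bank=bank)
        b = generate_task(task_id, params, seed=123, bank=bank)
        assert a.to_json() == b.to_json()

    @pytest.mark.parametrize("task_id", sorted(REPRESENTATIVE))
    def test_distinct_seeds_distinct_payloads(self, bank, task_id):
        params = REPRESENTATIVE[task_id]
        payloads = {
            json.dumps(generate_task(task_id, params, seed=s, bank=bank).content,
                       sort_keys=True)
            for s in range(30)
        }
        assert len(payloads) == 30

    def test_random_grid_points_verify(self, bank, registry):
        """Property sweep: random parameter grid points and seeds all
        produce self-consistent documents."""
        rng = random.Random(99)
        from cogtaskgen.params import TASK_IDS, get_space

        for task_id in TASK_IDS:
            grid = list(get_space(task_id).grid())
            for cfg in rng.sample(grid, min(3, len(grid))):
                if task_id == "cancellation":
                    alphabet = STIMULUS_ALPHABETS[cfg["stimulus"]]
                    if cfg["targets"] + cfg["distractors"] > len(alphabet):
                        continue
                doc = generate_task(task_id, cfg, seed=rng.randint(0, 9999),
                                    bank=bank, registry=registry)
                report = verify_document(doc, bank=bank, registry=registry)
                assert report.passed, (task_id, cfg, report.failures())

    def test_profile_stored_in_document_matches_models(self, bank, registry):
        doc = generate_task("mazes", {"size": 7}, seed=1, bank=bank,
                            registry=registry)
        expected = registry.profile("mazes", {"size": 7}).rounded().as_dict()
        assert doc.profile == expected

    def test_json_round_trip(self, bank):
        doc = generate_task("association", {"pairs": 5}, seed=3, bank=bank)
        again = TaskDocument.from_json(doc.to_json())
        assert again.to_json() == doc.to_json()

    @pytest.mark.parametrize("task_id", sorted(REPRESENTATIVE))
    def test_rendering_produces_sheet_and_key(self, bank, task_id):
        doc = generate_task(task_id, REPRESENTATIVE[task_id], seed=5, bank=bank)
        sheet, key = render_text(doc)
        assert sheet.strip() and key.strip()
        assert "answer key" in key
        html = render_html(doc)
        assert html.startswith("<!DOCTYPE html>")
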