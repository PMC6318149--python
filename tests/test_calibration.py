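"""Calibration statistics: alpha, OLS fitting, screening, model comparison,
and the synthetic rating panel."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtaskgen.calibration import (
    RatingRecord,
    compare_models,
    cronbach_alpha,
    fit_demand_model,
    fit_mean_model,
    ratings_to_matrix,
    screen_predictors,
    simulate_ratings,
    study_design,
)
from cogtaskgen.errors import (
    CollinearityError,
    EmptyDesignError,
    IncomparableModelsError,
    UndefinedAlphaError,
    ValidationError,
)
from cogtaskgen.models import DemandModel, ModelRegistry
from cogtaskgen.params import get_space


def _records(task_id, axis, rows):
    """rows: (rater, params, rating, order)"""
    return [
        RatingRecord(rater_id=r, task_id=task_id, params=p, axis=axis,
                     rating=v, presentation_order=o)
        for r, p, v, o in rows
    ]


class TestCronbachAlpha:
    def test_perfectly_covarying_items(self):
        # each rater gives one constant rating across items
        m = [[3, 3, 3], [5, 5, 5], [8, 8, 8], [2, 2, 2]]
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_two_uncorrelated_equal_variance_items(self):
        m = [[1, 1], [1, 2], [2, 1], [2, 2]]
        assert cronbach_alpha(m) == pytest.approx(0.0)

    def test_hand_computed_three_by_three(self):
        # item variances 1, 7/3, 4; variance of sums 61/3
        # alpha = (3/2) * (1 - (22/3)/(61/3)) = 117/122
        m = [[2, 4, 5], [3, 5, 7], [4, 7, 9]]
        assert cronbach_alpha(m) == pytest.approx(117 / 122)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedAlphaError):
            cronbach_alpha([[1], [2]])  # single item
        with pytest.raises(UndefinedAlphaError):
            cronbach_alpha([[3, 3], [3, 3]])  # no variance

    def test_listwise_deletion_of_missing_rows(self):
        m = [[2, 4, 5], [3, 5, 7], [4, 7, 9], [1, np.nan, 2]]
        assert cronbach_alpha(m) == pytest.approx(117 / 122)

    @given(
        scale=st.floats(min_value=0.1, max_value=10),
        shift=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        m = rng.uniform(1, 10, size=(6, 5))
        base = cronbach_alpha(m)
        assert cronbach_alpha(scale * m + shift) == pytest.approx(base)


class TestFitDemandModel:
    def test_zero_noise_recovers_generator_exactly(self, registry):
        design = [
            ("comprehension_of_contexts", {"descriptions": d}) for d in (2, 3)
        ]
        records = simulate_ratings(
            registry, design, n_raters=6, noise_sd=0.0, seed=1,
            axes=["executive_functions"],
        )
        fit = fit_demand_model(records, ["descriptions"])
        assert fit.model.intercept == pytest.approx(0.25, abs=1e-9)
        assert fit.model.coefficients["descriptions"] == pytest.approx(1.20, abs=1e-9)

    def test_noisy_estimates_within_three_se(self, registry):
        design = list(get_space("problem_resolution").grid())
        design = [("problem_resolution", cfg) for cfg in design]
        records = simulate_ratings(
            registry, design, n_raters=20, noise_sd=1.0, seed=11,
            axes=["language"],
        )
        fit = fit_demand_model(records, ["type"])
        assert abs(fit.model.intercept - 4.65) < 3 * fit.se["intercept"]
        assert abs(fit.model.coefficients["type"] - 1.10) < 3 * fit.se["type"]

    def test_constant_predictor_raises_collinearity(self):
        rows = [
            (f"r{i}", {"words": 4 + (i % 3), "clue": "none"}, 5 + 0.1 * i, i + 1)
            for i in range(8)
        ]
        with pytest.raises(CollinearityError) as err:
            fit_demand_model(_records("word_search", "memory", rows),
                             ["words", "clue"])
        assert "clue" in err.value.aliased

    def test_mixed_tasks_rejected(self, registry):
        design = [("association", {"pairs": 3}), ("mazes", {"size": 5})]
        records = simulate_ratings(registry, design, n_raters=3, seed=0,
                                   axes=["memory"])
        with pytest.raises(ValidationError):
            fit_demand_model(records, [])

    def test_information_criteria_identities(self, registry):
        design = [("association", {"pairs": p}) for p in range(3, 11)]
        records = simulate_ratings(registry, design, n_raters=8,
                                   noise_sd=0.8, seed=3, axes=["memory"])
        fit = fit_demand_model(records, ["pairs"])
        k = len(fit.model.coefficients) + 2
        assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(
            k * math.log(fit.n_obs) - 2 * fit.log_likelihood
        )

    def test_recovery_bias_shrinks_with_panel_size(self, registry):
        design = [("association", {"pairs": p}) for p in range(3, 11)]
        true = registry.get("association", "memory").coefficients["pairs"]

        def mae(n_raters):
            errs = []
            for rep in range(12):
                records = simulate_ratings(
                    registry, design, n_raters=n_raters, noise_sd=1.0,
                    seed=1000 * n_raters + rep, axes=["memory"],
                )
                fit = fit_demand_model(records, ["pairs"])
                errs.append(abs(fit.model.coefficients["pairs"] - true))
            return float(np.mean(errs))

        errors = [mae(n) for n in (5, 20, 100)]
        assert errors[2] < errors[0]


class TestScreening:
    def _noise_fit(self, registry, seed, n_raters=25):
        # true memory model depends on pairs only; "noise" uses a second
        # spurious predictor by fitting association ratings on an
        # unrelated simulated column is impossible within one task, so use
        # cancellation where language truly ignores `targets`.
        design = [("cancellation", cfg)
                  for cfg in get_space("cancellation").grid()]
        rng = np.random.default_rng(seed)
        design = [design[i] for i in rng.choice(len(design), 16, replace=False)]
        records = simulate_ratings(registry, design, n_raters=n_raters,
                                   noise_sd=1.0, seed=seed, axes=["language"])
        return fit_demand_model(records, ["stimulus", "distractors", "targets"])

    def test_significant_predictors_survive(self, registry):
        fit = self._noise_fit(registry, seed=5)
        screened = screen_predictors(fit, 0.05)
        assert set(screened.model.coefficients) <= {"stimulus", "distractors",
                                                    "targets"}
        assert {"stimulus", "distractors"} <= set(screened.model.coefficients)

    def test_pure_noise_predictor_dropped(self, registry):
        dropped = 0
        for rep in range(40):
            screened = screen_predictors(self._noise_fit(registry, seed=100 + rep))
            if "targets" not in screened.model.coefficients:
                dropped += 1
        # the no-effect predictor survives a 5% screen only by chance;
        # 36/40 is the two-sigma band around the expected 95% drop rate
        assert dropped >= 36

    def test_no_survivors_fall_back_to_grand_mean(self, registry):
        design = [("mazes", {"size": s}) for s in (5, 7, 9, 11)]
        rng = np.random.default_rng(0)
        records = [
            RatingRecord("r%d" % i, "mazes", dict(cfg), "memory",
                         float(np.clip(5 + rng.normal(0, 1), 1, 10)), j + 1)
            for i in range(10)
            for j, (_, cfg) in enumerate(design)
        ]
        fit = fit_demand_model(records, ["size"])
        screened = screen_predictors(fit, alpha_level=0.001)
        if screened.model.is_fallback:
            grand = np.mean([r.rating for r in records])
            assert screened.model.fallback_mean == pytest.approx(float(grand))

    def test_all_significant_leaves_model_unchanged(self, registry):
        design = [("association", {"pairs": p}) for p in range(3, 11)]
        records = simulate_ratings(registry, design, n_raters=20,
                                   noise_sd=0.3, seed=9, axes=["memory"])
        fit = fit_demand_model(records, ["pairs"])
        assert screen_predictors(fit) is fit


class TestCompareModels:
    def _fits(self, registry, seed, n_raters=25):
        design = [("problem_resolution", cfg)
                  for cfg in get_space("problem_resolution").grid()]
        records = simulate_ratings(registry, design, n_raters=n_raters,
                                   noise_sd=1.0, seed=seed, axes=["language"])
        true_fit = fit_demand_model(records, ["type"])
        bigger = fit_demand_model(records, ["type", "operations"])
        return records, true_fit, bigger

    def test_single_model_ranks_first(self, registry):
        _, fit, _ = self._fits(registry, seed=2)
        ranking = compare_models([fit])
        assert ranking.best is fit
        assert ranking.delta_aic == (0.0,)

    def test_true_model_beats_spurious_extra_predictor(self, registry):
        wins = 0
        for rep in range(15):
            _, true_fit, bigger = self._fits(registry, seed=300 + rep)
            ranking = compare_models([true_fit, bigger])
            if ranking.best.model.coefficients.keys() == {"type"}:
                wins += 1
        assert wins > 7  # majority of replicates

    def test_bic_penalizes_overfit_harder(self, registry):
        better_bic = 0
        for rep in range(15):
            _, true_fit, bigger = self._fits(registry, seed=600 + rep)
            if true_fit.bic < bigger.bic:
                better_bic += 1
        assert better_bic >= 12

    def test_fits_on_different_records_rejected(self, registry):
        r1, fit1, _ = self._fits(registry, seed=1)
        _, fit2, _ = self._fits(registry, seed=99)
        with pytest.raises(IncomparableModelsError):
            compare_models([fit1, fit2])

    def test_mean_fit_comparable_with_slope_fit(self, registry):
        records, fit, _ = self._fits(registry, seed=4)
        ranking = compare_models([fit, fit_mean_model(records)])
        assert ranking.best is fit  # type effect is strong at sd=1


class TestSimulateRatings:
    def test_zero_noise_returns_model_predictions(self, registry):
        design = [("mazes", {"size": s}) for s in (5, 9, 15)]
        records = simulate_ratings(registry, design, n_raters=3,
                                   noise_sd=0.0, rater_effect_sd=0.0, seed=0)
        from cogtaskgen.models import evaluate_demand

        for r in records:
            expected = evaluate_demand(registry.get(r.task_id, r.axis), r.params)
            assert r.rating == pytest.approx(expected)

    def test_same_seed_identical_records(self, registry):
        design = study_design(n_variants=20, seed=3)
        a = simulate_ratings(registry, design, n_raters=4, noise_sd=0.5, seed=42)
        b = simulate_ratings(registry, design, n_raters=4, noise_sd=0.5, seed=42)
        assert a == b
        c = simulate_ratings(registry, design, n_raters=4, noise_sd=0.5, seed=43)
        assert a != c

    def test_empty_design_rejected(self, registry):
        with pytest.raises(EmptyDesignError):
            simulate_ratings(registry, [], n_raters=3, seed=0)

    def test_consistent_panel_reaches_high_alpha(self, registry):
        design = study_design(n_variants=67, seed=1)
        records = simulate_ratings(
            registry, design, n_raters=20, noise_sd=0.3,
            rater_effect_sd=0.2, seed=8,
        )
        matrix = ratings_to_matrix(records).to_numpy()
        assert cronbach_alpha(matrix) >= 0.9

    def test_presentation_orders_are_per_rater_permutations(self, registry):
        design = study_design(n_variants=12, seed=0)
        records = simulate_ratings(registry, design, n_raters=3, seed=5,
                                   axes=["memory"])
        by_rater = {}
        for r in records:
            by_rater.setdefault(r.rater_id, set()).add(r.presentation_order)
        for orders in by_rater.values():
            assert orders == set(range(1, len(design) + 1))
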