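import itertools
import math

import numpy as np
import pytest

from edanx.features import FEATURE_NAMES
from edanx.model import (
    AnxietyRegression,
    ClassScheme,
    PolyModel,
    build_design_row,
    classify,
    confusion,
    exhaustive_search,
    fit,
    n_coefficients,
    n_combinations,
    predict,
    ssr,
    stratified_split,
)

# Table of reported-anxiety occurrences per level (0..10) in the motivating
# 7-subject cohort; the split rule must reproduce the printed 90/15 partition.
LEVEL_TOTALS = [41, 16, 12, 9, 7, 4, 4, 2, 5, 2, 3]
EXPECTED_NIK = [35, 14, 10, 8, 6, 3, 3, 2, 4, 2, 3]
EXPECTED_NVK = [6, 2, 2, 1, 1, 1, 1, 0, 1, 0, 0]


class TestCounting:
    @pytest.mark.parametrize("p, expected", [(17, 171), (1, 3), (7, 36), (2, 6)])
    def test_coefficient_count(self, p, expected):
        assert n_coefficients(p) == expected

    def test_invalid_subset_size(self):
        with pytest.raises(ValueError):
            n_coefficients(0)

    @pytest.mark.parametrize(
        "n, p, expected",
        [(32, 7, 3_365_856), (32, 1, 32), (5, 5, 1), (32, 2, 496)],
    )
    def test_combinations(self, n, p, expected):
        assert n_combinations(n, p) == expected

    def test_combinations_invalid(self):
        with pytest.raises(ValueError):
            n_combinations(5, 6)


class TestDesignRow:
    def test_single_feature(self):
        assert np.array_equal(build_design_row([2.0]), [4.0, 2.0, 1.0])

    def test_two_features_order(self):
        assert np.array_equal(build_design_row([1.0, 2.0]), [1, 2, 4, 1, 2, 1])

    def test_zero_vector(self):
        row = build_design_row(np.zeros(3))
        assert row[-1] == 1.0
        assert np.all(row[:-1] == 0.0)

    def test_length_matches_coefficient_count(self):
        for p in range(1, 8):
            assert build_design_row(np.ones(p)).size == n_coefficients(p)


class TestFitPredict:
    def _make_quadratic(self, rng, n, p, noise=0.0):
        X = rng.normal(size=(n, p))
        coef = rng.normal(size=n_coefficients(p))
        A = np.vstack([build_design_row(x) for x in X])
        y = A @ coef + rng.normal(0, noise, n)
        return X, y, coef

    def test_exact_recovery_noiseless(self, rng):
        X, y, coef = self._make_quadratic(rng, 20, 2)
        model = fit(X, y, ["a", "b"])
        assert np.allclose(model.coef, coef, atol=1e-6)
        assert ssr(model, X, y) <= 1e-10

    def test_constant_targets(self, rng):
        X = rng.normal(size=(30, 2))
        model = fit(X, np.full(30, 4.2), ["a", "b"])
        assert model.gamma == pytest.approx(4.2, abs=1e-8)
        assert np.allclose(model.coef[:-1], 0.0, atol=1e-7)

    def test_noisy_coefficient_rmse(self):
        rng = np.random.default_rng(77)
        X, y, coef = self._make_quadratic(rng, 500, 2, noise=0.1)
        model = fit(X, y, ["a", "b"])
        rmse = np.sqrt(np.mean((model.coef - coef) ** 2))
        assert rmse <= 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit(np.empty((0, 2)), np.empty(0), ["a", "b"])

    def test_predict_hand_model(self):
        model = PolyModel(feature_names=["x"], coef=np.array([1.0, 1.0, 1.0]))
        assert predict(model, [[2.0]])[0] == pytest.approx(7.0)
        assert predict(model, [[0.0]])[0] == pytest.approx(1.0)

    def test_predict_dimension_mismatch(self):
        model = PolyModel(feature_names=["x"], coef=np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            predict(model, [[1.0, 2.0]])

    def test_ssr_oracle(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = fit(X, y, ["a", "b"])
        naive = sum(
            (yi - float(build_design_row(xi) @ model.coef)) ** 2
            for xi, yi in zip(X, y)
        )
        assert ssr(model, X, y) == pytest.approx(naive, abs=1e-9)

    def test_json_round_trip(self, rng, tmp_path):
        X, y, _ = self._make_quadratic(rng, 30, 3)
        model = fit(X, y, ["f1", "f2", "f3"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PolyModel.from_json(path)
        assert back.feature_names == model.feature_names
        assert np.allclose(back.coef, model.coef)


class TestStratifiedSplit:
    def test_reproduces_printed_partition(self):
        ratings = [lvl for lvl, c in enumerate(LEVEL_TOTALS) for _ in range(c)]
        plan = stratified_split(ratings, seed=3)
        nik = [plan.per_level_counts[k][0] for k in range(11)]
        nvk = [plan.per_level_counts[k][1] for k in range(11)]
        assert nik == EXPECTED_NIK
        assert nvk == EXPECTED_NVK
        assert plan.n_identification == 90
        assert plan.n_validation == 15

    def test_partition_is_disjoint_and_complete(self):
        ratings = [lvl for lvl, c in enumerate(LEVEL_TOTALS) for _ in range(c)]
        plan = stratified_split(ratings, seed=0)
        ident = set(plan.identification_indices.tolist())
        valid = set(plan.validation_indices.tolist())
        assert ident.isdisjoint(valid)
        assert ident | valid == set(range(len(ratings)))

    def test_single_level(self):
        plan = stratified_split([4] * 7, seed=1)
        assert plan.per_level_counts[4] == (6, 1)

    def test_seed_controls_membership(self):
        ratings = [0] * 20 + [5] * 8
        a = stratified_split(ratings, seed=1)
        b = stratified_split(ratings, seed=2)
        c = stratified_split(ratings, seed=1)
        assert np.array_equal(a.identification_indices, c.identification_indices)
        assert not np.array_equal(a.identification_indices, b.identification_indices)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([])


def _naive_search(X, y, split, p, names):
    """Independent enumerator: explicit loops, no shared code path."""
    Xi = X[split.identification_indices]
    yi = y[split.identification_indices]
    best = None
    for subset in itertools.combinations(range(len(names)), p):
        A = []
        for row in Xi[:, subset]:
            terms = []
            for i in range(p):
                for j in range(i, p):
                    terms.append(row[i] * row[j])
            terms.extend(row)
            terms.append(1.0)
            A.append(terms)
        A = np.array(A)
        coefs, *_ = np.linalg.lstsq(A, yi, rcond=None)
        s = float(np.sum((yi - A @ coefs) ** 2))
        if best is None or s < best[0] - 1e-12:
            best = (s, subset)
    return best


class TestExhaustiveSearch:
    def _dataset(self, rng, n=60, n_feat=6):
        names = [f"f{i}" for i in range(n_feat)]
        X = rng.normal(size=(n, n_feat))
        return X, names

    def test_single_feature_recovery(self, rng):
        X, names = self._dataset(rng)
        y = 2.0 * X[:, 3] ** 2 - X[:, 3] + 0.5
        split = stratified_split(np.zeros(len(y), dtype=int), seed=0)
        result = exhaustive_search(X, y, split, 1, feature_names=names)
        assert result.best_subset == ("f3",)
        assert result.evaluated_count == 6

    def test_evaluated_count_full_pool(self, rng):
        X = rng.normal(size=(40, 32))
        y = rng.normal(size=40)
        split = stratified_split(np.zeros(40, dtype=int), seed=0)
        result = exhaustive_search(X, y, split, 2, feature_names=list(FEATURE_NAMES))
        assert result.evaluated_count == 496

    def test_agrees_with_naive_enumerator(self, rng):
        X, names = self._dataset(rng)
        y = X[:, 1] + 0.3 * X[:, 4] ** 2 + rng.normal(0, 0.3, X.shape[0])
        split = stratified_split(np.zeros(len(y), dtype=int), seed=5)
        for p in (1, 2, 3):
            mine = exhaustive_search(X, y, split, p, feature_names=names)
            s_naive, subset_naive = _naive_search(X, y, split, p, names)
            assert tuple(names[i] for i in subset_naive) == mine.best_subset
            assert mine.ssr_identification == pytest.approx(s_naive, abs=1e-9)

    def test_nesting_monotonicity(self, rng):
        X, names = self._dataset(rng, n=80)
        y = rng.normal(size=80)
        split = stratified_split(np.zeros(80, dtype=int), seed=0)
        best = [
            exhaustive_search(X, y, split, p, feature_names=names).ssr_identification
            for p in (1, 2, 3)
        ]
        assert best[0] >= best[1] - 1e-9
        assert best[1] >= best[2] - 1e-9

    def test_overparameterized_warns_not_fails(self, rng):
        X, names = self._dataset(rng, n=12, n_feat=6)
        y = rng.normal(size=12)
        split = stratified_split(np.zeros(12, dtype=int), seed=0)
        with pytest.warns(UserWarning, match="minimum-norm"):
            result = exhaustive_search(X, y, split, 4, feature_names=names)
        assert math.isfinite(result.ssr_identification)


class TestClassification:
    @pytest.mark.parametrize(
        "value, levels, expected",
        [
            (2.91, 3, "low"),  # estimate just under the low/mild threshold
            (7.12, 3, "high"),  # estimate just over the mild/high threshold
            (7.37, 3, "high"),
            (5.0, 2, "low"),  # closed upper bound of the low interval
            (5.0001, 2, "high"),
            (3.0, 3, "low"),
            (-1.2, 3, "low"),  # extreme intervals extend beyond [0, 10]
            (11.5, 2, "high"),
        ],
    )
    def test_thresholds(self, value, levels, expected):
        scheme = ClassScheme.from_level_count(levels)
        assert classify(value, scheme) == expected

    def test_every_estimate_maps_to_one_class(self, rng):
        scheme = ClassScheme.three_level()
        for v in rng.uniform(-5, 15, 200):
            assert classify(v, scheme) in scheme.labels

    def test_invalid_level_count(self):
        with pytest.raises(ValueError):
            ClassScheme.from_level_count(4)


class TestConfusion:
    def test_perfect_predictions(self):
        scheme = ClassScheme.two_level()
        rep = confusion(["low", "high", "low"], ["low", "high", "low"], scheme)
        assert np.array_equal(rep.matrix, np.eye(2))
        assert rep.overall_accuracy == 100.0

    def test_hand_counted_matrix(self):
        scheme = ClassScheme.two_level()
        rep = confusion(
            ["low", "low", "high", "high"], ["low", "high", "high", "high"], scheme
        )
        assert np.allclose(rep.matrix, [[0.5, 0.5], [0.0, 1.0]])
        assert rep.overall_accuracy == pytest.approx(75.0)

    def test_rows_sum_to_one(self, rng):
        scheme = ClassScheme.three_level()
        truths = [classify(v, scheme) for v in rng.uniform(0, 10, 100)]
        preds = [classify(v, scheme) for v in rng.uniform(0, 10, 100)]
        rep = confusion(truths, preds, scheme)
        sums = rep.matrix.sum(axis=1)
        for i, label in enumerate(scheme.labels):
            if label not in rep.empty_classes:
                assert sums[i] == pytest.approx(1.0, abs=1e-12)

    def test_empty_true_class_flagged(self):
        scheme = ClassScheme.three_level()
        rep = confusion(["low", "low"], ["low", "mild"], scheme)
        assert "high" in rep.empty_classes
        assert np.isnan(rep.matrix[2]).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["low"], ["low", "high"], ClassScheme.two_level())


class TestModelResultsInterface:
    def test_fit_results_and_summary(self, rng):
        X = rng.normal(size=(50, 2))
        y = 1.5 * X[:, 0] - 0.5 * X[:, 1] ** 2 + 3.0
        res = AnxietyRegression(X, y, ["HR_mav", "SCL_mar"]).fit()
        assert res.ssr <= 1e-9
        assert res.nobs == 50
        text = res.summary()
        assert "HR_mav" in text and "SCL_mar" in text
        assert np.allclose(res.fittedvalues, y)

    def test_from_dataframe_and_confusion(self, rng):
        import pandas as pd

        X = rng.normal(size=(40, 1))
        y = np.clip(5 + 2 * X[:, 0], 0, 10)
        frame = pd.DataFrame({"HR_mav": X[:, 0], "anx": y})
        res = AnxietyRegression.from_dataframe(frame, ["HR_mav"]).fit()
        rep = res.confusion(ClassScheme.two_level())
        assert rep.overall_accuracy >= 99.0
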