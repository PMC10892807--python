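"""AHP engine: eigenvector weights, consistency, synthesis, grading, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ornaval as ov
from ornaval.ahp import (
    CR_THRESHOLD,
    INDEX_TO_TRAIT,
    InconsistentMatrixError,
    JudgmentMatrix,
    consistency,
    default_hierarchy,
    default_matrices,
    eigen_weights,
    grade_traits,
    ri_lookup,
    synthesize_weights,
)


def char_poly_oracle_3x3(a: np.ndarray) -> tuple[float, np.ndarray]:
    """Independent 3x3 eigen solve: explicit characteristic polynomial roots
    plus an SVD null-space for the eigenvector (no power iteration)."""
    tr = np.trace(a)
    m2 = sum(
        a[i, i] * a[j, j] - a[i, j] * a[j, i]
        for i in range(3) for j in range(i + 1, 3)
    )
    det = np.linalg.det(a)
    roots = np.roots([-1.0, tr, -m2, det])
    lam = max(r.real for r in roots if abs(r.imag) < 1e-9)
    _, _, vt = np.linalg.svd(a - lam * np.eye(3))
    w = np.abs(vt[-1])
    return lam, w / w.sum()


def random_reciprocal(rng: np.random.Generator, n: int) -> JudgmentMatrix:
    scale = np.concatenate([1.0 / np.arange(9, 1, -1), np.arange(1, 10)])
    a = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = rng.choice(scale)
            a[j, i] = 1.0 / a[i, j]
    return JudgmentMatrix([f"i{k}" for k in range(n)], a)


class TestEigenWeights:
    def test_consistent_matrix_recovers_generating_weights(self):
        w = np.array([0.6, 0.3, 0.1])
        m = JudgmentMatrix(list("abc"), np.outer(w, 1.0 / w))
        assert eigen_weights(m) == pytest.approx(w, abs=1e-10)

    def test_all_ones_gives_equal_weights(self):
        m = JudgmentMatrix(list("abcde"), np.ones((5, 5)))
        assert eigen_weights(m) == pytest.approx(np.full(5, 0.2), abs=1e-12)

    def test_3x3_matches_characteristic_polynomial_oracle(self):
        a = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1]])
        m = JudgmentMatrix(list("abc"), a)
        lam_o, w_o = char_poly_oracle_3x3(a)
        assert eigen_weights(m) == pytest.approx(w_o, abs=1e-8)
        res = consistency(m)
        assert res.lambda_max == pytest.approx(lam_o, abs=1e-8)
        # frozen values from the oracle
        assert res.lambda_max == pytest.approx(3.0385110905581714, abs=1e-9)
        assert eigen_weights(m) == pytest.approx(
            [0.63698557, 0.25828499, 0.10472943], abs=1e-7
        )

    def test_non_reciprocal_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            JudgmentMatrix(list("ab"), [[1, 2], [2, 1]])

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            JudgmentMatrix(list("ab"), [[1, -2], [-0.5, 1]])

    def test_matches_dense_eigen_oracle_on_random_matrices(self):
        # independent oracle: numpy's dense eigendecomposition
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 10))
            m = random_reciprocal(rng, n)
            vals, vecs = np.linalg.eig(m.values)
            k = np.argmax(vals.real)
            w_oracle = np.abs(vecs[:, k].real)
            w_oracle /= w_oracle.sum()
            assert eigen_weights(m) == pytest.approx(w_oracle, abs=1e-8)


class TestConsistency:
    def test_consistent_matrix_cr_zero(self):
        w = np.array([0.5, 0.25, 0.15, 0.1])
        m = JudgmentMatrix(list("abcd"), np.outer(w, 1.0 / w))
        res = consistency(m)
        assert res.ci == pytest.approx(0.0, abs=1e-9)
        assert res.cr == pytest.approx(0.0, abs=1e-9)
        assert res.consistent

    def test_2x2_always_consistent(self):
        res = consistency(JudgmentMatrix(list("ab"), [[1, 7], [1 / 7, 1]]))
        assert res.cr == 0.0 and res.consistent

    def test_3x3_cr_matches_oracle(self):
        a = np.array([[1, 3, 5], [1 / 3, 1, 3], [1 / 5, 1 / 3, 1]])
        lam_o, _ = char_poly_oracle_3x3(a)
        res = consistency(JudgmentMatrix(list("abc"), a))
        assert res.ci == pytest.approx((lam_o - 3) / 2, abs=1e-9)
        assert res.cr == pytest.approx((lam_o - 3) / 2 / 0.52, abs=1e-8)
        assert res.consistent

    def test_lambda_max_at_least_n(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = random_reciprocal(rng, int(rng.integers(3, 8)))
            assert consistency(m).lambda_max >= m.n - 1e-9

    def test_perturbation_never_decreases_cr(self):
        w = np.array([0.5, 0.3, 0.2])
        base = np.outer(w, 1.0 / w)
        cr0 = consistency(JudgmentMatrix(list("abc"), base)).cr
        for factor in (1.5, 2.0, 3.0, 0.5, 0.25):
            a = base.copy()
            a[0, 1] *= factor
            a[1, 0] = 1.0 / a[0, 1]
            assert consistency(JudgmentMatrix(list("abc"), a)).cr >= cr0 - 1e-12

    def test_ri_lookup(self):
        assert ri_lookup(1) == 0.0
        assert ri_lookup(2) == 0.0
        assert ri_lookup(6) == 1.26
        with pytest.raises(ValueError):
            ri_lookup(40)


class TestSynthesis:
    def test_single_criterion_global_equals_index_weights(self):
        h = ov.Hierarchy(target="t", criteria={"c": ["x", "y", "z"]})
        crit = JudgmentMatrix(["c"], [[1.0]])
        idx = {"c": JudgmentMatrix(["x", "y", "z"],
                                   [[1, 2, 4], [1 / 2, 1, 2], [1 / 4, 1 / 2, 1]])}
        ws = synthesize_weights(h, crit, idx)
        assert ws.global_weights == pytest.approx(ws.index_weights["c"])

    def test_two_single_index_criteria_split_evenly(self):
        h = ov.Hierarchy(target="t", criteria={"c1": ["x"], "c2": ["y"]})
        crit = JudgmentMatrix(["c1", "c2"], [[1, 1], [1, 1]])
        ws = synthesize_weights(h, crit, {})
        assert ws.global_weights["x"] == pytest.approx(0.5)
        assert ws.global_weights["y"] == pytest.approx(0.5)

    def test_default_model_weights_sum_to_one_and_spot_check(self, default_weights):
        ws = default_weights
        assert sum(ws.global_weights.values()) == pytest.approx(1.0, abs=1e-9)
        for crit, iw in ws.index_weights.items():
            assert sum(iw.values()) == pytest.approx(1.0, abs=1e-9)
        # hand-computed product: global = within-criterion x criterion weight
        spot = ws.index_weights["overall_flower_effect"]["pedicel_length"] \
            * ws.criterion_weights["overall_flower_effect"]
        assert ws.global_weights["pedicel_length"] == pytest.approx(spot, abs=1e-12)

    def test_default_model_encodes_reported_importance_ordering(self, default_weights):
        g = default_weights.global_weights
        top4 = sorted(g, key=g.get, reverse=True)[:4]
        assert set(top4) == {
            "pedicel_length", "floral_color", "flower_longevity", "flowering_duration",
        }
        crit_w = default_weights.criterion_weights
        assert min(crit_w, key=crit_w.get) == "plant_morphology"

    def test_inconsistent_matrix_gate(self):
        h = ov.Hierarchy(target="t", criteria={"c": ["x", "y", "z"]})
        crit = JudgmentMatrix(["c"], [[1.0]])
        bad = JudgmentMatrix(["x", "y", "z"],
                             [[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]])
        idx = {"c": bad}
        assert not consistency(bad).consistent
        with pytest.raises(InconsistentMatrixError, match="CR"):
            synthesize_weights(h, crit, idx)
        ws = synthesize_weights(h, crit, idx, allow_inconsistent=True)
        assert sum(ws.global_weights.values()) == pytest.approx(1.0)


class TestGradingAndScoring:
    def _rubric(self, hib=True):
        return ov.GradingRubric(
            breakpoints={"plant_height": np.array([10.0, 20.0, 30.0, 40.0])},
            higher_is_better={"plant_height": hib},
        )

    def _table(self, heights):
        return ov.TraitTable(pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(len(heights))],
            "plot_id": "C1", "treatment": "control", "year": 2017,
            "plant_height": heights,
        }))

    def test_below_lowest_breakpoint_grades(self):
        t = self._table([5.0, 15.0, 25.0, 35.0, 45.0])
        g = grade_traits(t, self._rubric(True), ["plant_height"])
        assert g["plant_height"].tolist() == [1, 2, 3, 4, 5]
        g = grade_traits(t, self._rubric(False), ["plant_height"])
        assert g["plant_height"].tolist() == [5, 4, 3, 2, 1]

    def test_missing_value_gives_missing_grade(self):
        t = self._table([5.0, np.nan])
        g = grade_traits(t, self._rubric(), ["plant_height"])
        assert np.isnan(g["plant_height"].iloc[1])

    def test_missing_rubric_entry_raises(self):
        t = self._table([5.0])
        with pytest.raises(ValueError, match="rubric"):
            grade_traits(t, self._rubric(), ["pedicel_length"])

    def test_quintile_rubric_grades_nearly_uniform(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.gamma(9.0, 5.0, size=5000))
        rubric = ov.GradingRubric.from_quantiles(t, ["plant_height"])
        g = grade_traits(t, rubric, ["plant_height"])["plant_height"]
        for grade in (1, 2, 3, 4, 5):
            assert (g == grade).mean() == pytest.approx(0.2, abs=0.03)

    def test_quintile_rubric_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(4.0, 10.0, size=1000)
        t1, t2 = self._table(vals), self._table(vals * 37.5)
        g1 = grade_traits(t1, ov.GradingRubric.from_quantiles(t1, ["plant_height"]),
                          ["plant_height"])
        g2 = grade_traits(t2, ov.GradingRubric.from_quantiles(t2, ["plant_height"]),
                          ["plant_height"])
        assert g1["plant_height"].tolist() == g2["plant_height"].tolist()

    def _graded(self, grades: dict, weights: dict):
        df = pd.DataFrame({
            "plant_id": ["p1"], "plot_id": ["C1"],
            "treatment": ["control"], "year": [2017],
        })
        for k, v in grades.items():
            df[k] = [float(v)]
        ws = ov.WeightSet(criterion_weights={}, index_weights={}, global_weights=weights)
        return df, ws

    def test_all_grades_five_scores_five(self):
        df, ws = self._graded({"a": 5, "b": 5, "c": 5}, {"a": 0.7, "b": 0.2, "c": 0.1})
        st_ = ov.comprehensive_score(df, ws)
        assert st_.scores["score"].iloc[0] == pytest.approx(5.0)

    def test_uniform_weights_mean_grade(self):
        df, ws = self._graded({"a": 1, "b": 3, "c": 5}, {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        assert ov.comprehensive_score(df, ws).scores["score"].iloc[0] == pytest.approx(3.0)

    def test_hand_computed_weighted_sum(self):
        grades = {"a": 2, "b": 4, "c": 5, "d": 1}
        weights = {"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}
        df, ws = self._graded(grades, weights)
        expected = 0.4 * 2 + 0.3 * 4 + 0.2 * 5 + 0.1 * 1  # = 3.1
        assert ov.comprehensive_score(df, ws).scores["score"].iloc[0] == pytest.approx(expected)

    def test_missing_index_renormalizes(self):
        df, ws = self._graded({"a": 4, "b": np.nan}, {"a": 0.5, "b": 0.5})
        st_ = ov.comprehensive_score(df, ws)
        assert st_.scores["score"].iloc[0] == pytest.approx(4.0)
        assert bool(st_.scores["renormalized"].iloc[0])

    def test_scores_bounded_and_monotone(self, default_table, default_weights):
        h = default_hierarchy()
        rubric = ov.GradingRubric.from_quantiles(default_table, h.indices)
        graded = grade_traits(default_table, rubric, h.indices)
        st_ = ov.comprehensive_score(graded, default_weights)
        assert st_.scores["score"].between(1.0, 5.0).all()
        # bumping one plant's grade can only raise its score
        bumped = graded.copy()
        col = "pedicel_length"
        i = bumped[col].first_valid_index()
        bumped.loc[i, col] = min(bumped.loc[i, col] + 1, 5)
        if bumped.loc[i, col] > graded.loc[i, col]:
            s2 = ov.comprehensive_score(bumped, default_weights)
            assert s2.scores["score"].iloc[i] > st_.scores["score"].iloc[i]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=0.05, max_value=20.0), min_size=3, max_size=7))
def test_consistent_matrices_from_any_weights_have_cr_zero(ws):
    w = np.asarray(ws)
    w = w / w.sum()
    m = JudgmentMatrix([f"i{k}" for k in range(len(w))], np.outer(w, 1.0 / w))
    res = consistency(m)
    assert res.cr == pytest.approx(0.0, abs=1e-8)
    assert eigen_weights(m) == pytest.approx(w, abs=1e-8)
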