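"""Domain types and the masked ratio objective."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coca import (
    ExpressionMatrix,
    InputError,
    KnowledgeMask,
    objective_j,
    participation,
    preprocess,
)
from conftest import brute_force_objective


class TestExpressionMatrix:
    def test_dataframe_round_trip(self, rng):
        x = ExpressionMatrix(rng.standard_normal((3, 4)), list("abc"), list("wxyz"))
        back = ExpressionMatrix.from_dataframe(x.to_dataframe())
        np.testing.assert_array_equal(back.values, x.values)
        assert back.gene_ids.tolist() == ["a", "b", "c"]

    def test_rejects_duplicates_and_nan(self):
        with pytest.raises(InputError, match="duplicate gene"):
            ExpressionMatrix(np.ones((2, 2)), ["a", "a"], ["s1", "s2"])
        bad = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(InputError, match="non-finite"):
            ExpressionMatrix(bad, ["a", "b"], ["s1", "s2"])

    def test_minimum_size(self):
        with pytest.raises(InputError, match="at least 2"):
            ExpressionMatrix(np.ones((1, 3)), ["a"], ["s1", "s2", "s3"])

    def test_gene_indices_reports_missing(self, rng):
        x = ExpressionMatrix(rng.standard_normal((3, 2)), list("abc"), ["s1", "s2"])
        assert x.gene_indices(["c", "a"]).tolist() == [2, 0]
        with pytest.raises(InputError, match="zzz"):
            x.gene_indices(["a", "zzz"])


class TestKnowledgeMask:
    def test_disjointness_enforced(self):
        with pytest.raises(InputError, match="both positive and negative"):
            KnowledgeMask([1, 1, 0], [1, 0, 1])

    def test_needs_two_per_side(self):
        with pytest.raises(InputError, match="positive"):
            KnowledgeMask([1, 0, 0, 0], [0, 1, 1, 0])

    def test_from_gene_sets_default_background(self):
        mask = KnowledgeMask.from_gene_sets(list("abcd"), ["a", "b"])
        assert mask.positive.tolist() == [1, 1, 0, 0]
        assert mask.negative.tolist() == [0, 0, 1, 1]

    def test_gene_in_neither_mask_allowed(self):
        mask = KnowledgeMask.from_gene_sets(list("abcde"), ["a", "b"], ["c", "d"])
        assert mask.positive[4] == 0 and mask.negative[4] == 0


class TestParticipation:
    @pytest.mark.parametrize(
        "values,w,expected",
        [
            (np.eye(2), [1.0, 0.0], [1.0, 0.0]),
            (np.zeros((3, 2)), [0.3, -0.7], [0.0, 0.0, 0.0]),
            (
                np.array([[1.0, 2.0], [3.0, 4.0]]),
                np.array([1.0, 1.0]) / np.sqrt(2),
                [3 / np.sqrt(2), 7 / np.sqrt(2)],
            ),
        ],
    )
    def test_examples(self, values, w, expected):
        np.testing.assert_allclose(participation(values, np.asarray(w)), expected)

    def test_dimension_mismatch_names_both_lengths(self):
        with pytest.raises(InputError, match="3.*2|2.*3"):
            participation(np.ones((4, 3)), np.ones(2))

    def test_linearity(self, rng):
        x = rng.standard_normal((10, 6))
        u, v = rng.standard_normal(6), rng.standard_normal(6)
        lhs = participation(x, 2.5 * u - 1.5 * v)
        rhs = 2.5 * participation(x, u) - 1.5 * participation(x, v)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestObjective:
    def test_symmetric_case_is_one(self):
        # |x_j . w| equal for all four genes, two positive vs two negative
        x = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]])
        mask = KnowledgeMask([1, 1, 0, 0], [0, 0, 1, 1])
        assert objective_j(x, mask, np.array([1.0, 0.0])) == pytest.approx(1.0, abs=1e-9)

    def test_null_numerator_is_zero(self):
        x = np.array([[0.0, 1], [0, -2], [1, 0], [2, 0]])
        mask = KnowledgeMask([1, 1, 0, 0], [0, 0, 1, 1])
        assert objective_j(x, mask, np.array([1.0, 0.0])) == 0.0

    def test_hand_computed_ratio(self):
        x = np.array([[1.0, 0], [0, 1], [1, 1], [2, 0]])
        mask = KnowledgeMask([1, 1, 0, 0], [0, 0, 1, 1])
        w = np.array([1.0, 0.0])
        assert objective_j(x, mask, w) == pytest.approx(1 / 3, rel=1e-9)
        assert objective_j(x, mask, w) == pytest.approx(
            brute_force_objective(x, mask, w), rel=1e-12
        )

    def test_zero_direction_rejected(self, small_matrix):
        x, mask = small_matrix
        with pytest.raises(InputError, match="nonzero"):
            objective_j(x, mask, np.zeros(5))

    def test_p_validated(self, small_matrix):
        x, mask = small_matrix
        with pytest.raises(InputError, match="p must be"):
            objective_j(x, mask, np.ones(5), p=3)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_brute_force_on_random_instances(self, rng, p):
        for _ in range(20):
            values = rng.standard_normal((20, 5))
            y = np.zeros(20)
            y[rng.choice(20, 6, replace=False)] = 1
            mask = KnowledgeMask(y, 1 - y)
            w = rng.standard_normal(5)
            assert objective_j(values, mask, w, p=p) == pytest.approx(
                brute_force_objective(values, mask, w, p=p), rel=1e-10
            )

    @given(seed=st.integers(0, 10_000), alpha=st.floats(-1e4, 1e4).filter(lambda a: abs(a) > 1e-6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance(self, seed, alpha):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal((12, 4))
        y = np.zeros(12)
        y[:4] = 1
        mask = KnowledgeMask(y, 1 - y)
        w = rng.standard_normal(4)
        j1 = objective_j(values, mask, w)
        j2 = objective_j(values, mask, alpha * w)
        assert j2 == pytest.approx(j1, rel=1e-10)

    def test_zero_projection_gene_changes_nothing(self, rng):
        values = rng.standard_normal((10, 3))
        w = rng.standard_normal(3)
        extra = np.zeros((1, 3))  # x_j . w = 0 for any w? use row orthogonal to w
        extra[0] = np.cross(w, rng.standard_normal(3))
        assert abs(extra[0] @ w) < 1e-12
        y = np.zeros(10)
        y[:4] = 1
        base = objective_j(values, KnowledgeMask(y, 1 - y), w)
        aug = np.vstack([values, extra])
        as_neg = objective_j(
            aug, KnowledgeMask(np.append(y, 0), np.append(1 - y, 1)), w
        )
        as_pos = objective_j(
            aug, KnowledgeMask(np.append(y, 1), np.append(1 - y, 0)), w
        )
        assert as_neg == pytest.approx(base, rel=1e-9)
        assert as_pos == pytest.approx(base, rel=1e-9)


class TestPreprocess:
    def test_centering_removes_row_means(self, rng):
        x = rng.standard_normal((6, 5)) + 3.0
        out = preprocess(x, center=True)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_scaling_gives_unit_variance_and_handles_constants(self, rng):
        x = rng.standard_normal((5, 6))
        x[2] = 7.0  # constant row
        out = preprocess(x, center=True, scale=True)
        sd = out.std(axis=1, ddof=1)
        np.testing.assert_allclose(np.delete(sd, 2), 1.0, rtol=1e-12)
        np.testing.assert_array_equal(out[2], 0.0)

    def test_disabled_is_identity(self, rng):
        x = rng.standard_normal((4, 4))
        np.testing.assert_array_equal(preprocess(x, center=False), x)
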