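"""Attribution math: hand-computed oracles, pseudoinverse recovery, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from qcai.adapter import CROSS_ATTENTION, LayerTopology, run_with_capture, TargetSpec
from qcai.core import (
    TokenImportance,
    aggregate_layers,
    attention_importance_map,
    combine_importance,
    explain,
    intrinsic_token_importance,
    key_attention_importance,
    normalize_scores,
    project_to_query_space,
    query_projection_importance,
)
from qcai.fixtures import ToyModelConfig, make_toy_model

from conftest import make_record, random_inputs


class TestAttentionImportanceMap:
    def test_hand_computed_square_map(self):
        # ReLU(grad*A) = [[0.5, 0], [1, 0]]; + I = [[1.5, 0], [1, 1]]
        rec = make_record([[0.5, 0.5], [0.5, 0.5]], [[1.0, -1.0], [2.0, 0.0]])
        imap = attention_importance_map(rec)
        np.testing.assert_allclose(imap.values, [[1.5, 0.0], [1.0, 1.0]])
        assert imap.includes_identity

    def test_zero_gradient_square_gives_identity(self):
        a = np.full((3, 3), 1 / 3)
        imap = attention_importance_map(make_record(a, np.zeros((3, 3))))
        np.testing.assert_array_equal(imap.values, np.eye(3))

    def test_zero_gradient_rectangular_gives_zeros(self):
        a = np.full((3, 5), 1 / 5)
        imap = attention_importance_map(make_record(a, np.zeros((3, 5))))
        np.testing.assert_array_equal(imap.values, np.zeros((3, 5)))
        assert not imap.includes_identity

    def test_identical_heads_equal_single_head(self):
        rng = np.random.default_rng(0)
        a1 = rng.dirichlet(np.ones(4), size=3)
        g1 = rng.normal(size=(3, 4))
        single = attention_importance_map(make_record(a1, g1)).values
        stacked = attention_importance_map(
            make_record(np.stack([a1] * 3), np.stack([g1] * 3))
        ).values
        np.testing.assert_allclose(stacked, single)

    def test_shape_mismatch_raises(self):
        rec = make_record(np.full((2, 2), 0.5), np.zeros((2, 2)))
        rec.grad_attention = np.zeros((1, 2, 3))
        with pytest.raises(ValueError):
            attention_importance_map(rec)


class TestIntrinsicTokenImportance:
    def test_hand_computed(self):
        act = np.array([[1.0, 2.0], [3.0, -4.0]])
        grad = np.array([[1.0, 1.0], [-1.0, 2.0]])
        np.testing.assert_array_equal(
            intrinsic_token_importance(act, grad), [2.0, 0.0]
        )

    def test_zero_gradient(self):
        act = np.random.default_rng(1).normal(size=(4, 3))
        np.testing.assert_array_equal(
            intrinsic_token_importance(act, np.zeros_like(act)), np.zeros(4)
        )

    def test_unit_gradient_gives_max_relu_activation(self):
        act = np.array([[-1.0, 2.0, 0.5], [3.0, -4.0, 1.0]])
        np.testing.assert_array_equal(
            intrinsic_token_importance(act, np.ones_like(act)), [2.0, 3.0]
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            intrinsic_token_importance(np.zeros((2, 3)), np.zeros((3, 2)))


class TestQueryProjection:
    def test_identity_keys_pass_through(self):
        rec = make_record(np.full((2, 2), 0.5), np.zeros((2, 2)))
        imap = attention_importance_map(rec)
        imap.values = np.array([[1.0, 0.0], [0.0, 2.0]])
        np.testing.assert_allclose(
            query_projection_importance(imap, np.eye(2)), [1.0, 2.0]
        )

    def test_exact_recovery_full_column_rank(self):
        """S = X K^T with K of full column rank is inverted exactly."""
        rng = np.random.default_rng(42)
        x = rng.normal(size=(4, 3))
        k = rng.normal(size=(5, 3))
        assert np.linalg.matrix_rank(k) == 3
        recovered = project_to_query_space(x @ k.T, k)
        assert np.abs(recovered - x).max() <= 1e-8

    def test_zero_map_gives_zero_scores(self):
        rec = make_record(np.full((3, 5), 0.2), np.zeros((3, 5)))
        imap = attention_importance_map(rec)
        k = np.random.default_rng(2).normal(size=(5, 4))
        np.testing.assert_array_equal(
            query_projection_importance(imap, k), np.zeros(3)
        )

    def test_rank_deficient_keys_do_not_raise(self):
        imap = attention_importance_map(
            make_record(np.full((2, 3), 1 / 3), np.abs(np.ones((2, 3))))
        )
        k = np.zeros((3, 4))  # rank 0
        scores = query_projection_importance(imap, k)
        assert scores.shape == (2,)
        assert np.all(scores >= 0)


class TestKeyAttentionImportance:
    def test_hand_computed_column_max(self):
        # choose grad so that ReLU(grad*A) = [[0.5, 0], [1, 1]]
        a = np.array([[0.5, 0.5], [0.5, 0.5]])
        g = np.array([[1.0, -1.0], [2.0, 2.0]])
        np.testing.assert_allclose(
            key_attention_importance(make_record(a, g)), [1.0, 1.0]
        )

    def test_zero_gradient(self):
        a = np.full((3, 4), 0.25)
        np.testing.assert_array_equal(
            key_attention_importance(make_record(a, np.zeros((3, 4)))), np.zeros(4)
        )

    def test_single_query_row_returns_the_row(self):
        a = np.array([[0.2, 0.7, 0.1]])
        np.testing.assert_allclose(
            key_attention_importance(make_record(a, np.ones((1, 3)))),
            [0.2, 0.7, 0.1],
        )


class TestCombineImportance:
    def test_definition(self):
        np.testing.assert_array_equal(
            combine_importance([1.0, 0.0], [0.0, 2.0]), [1.0, 2.0]
        )

    def test_idempotent_and_identity(self):
        a = np.array([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(combine_importance(a, a), a)
        np.testing.assert_array_equal(combine_importance(np.zeros(3), a), a)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_importance(np.ones(2), np.ones(3))

    @given(
        arrays(float, 6, elements=st.floats(0, 100)),
        arrays(float, 6, elements=st.floats(0, 100)),
    )
    def test_dominance(self, a, b):
        c = combine_importance(a, b)
        assert np.all(c >= a) and np.all(c >= b)


def _ti(name, scores):
    return TokenImportance(name, np.asarray(scores, float))


def _cross_topo(layer_id, q, k):
    return LayerTopology(layer_id, CROSS_ATTENTION, q, k)


class TestAggregateLayers:
    def test_single_layer_passthrough(self):
        per_layer = {0: (_ti("pep", [1.0, 2.0]), _ti("cdr3a", [0.5, 0.0, 3.0]))}
        out = aggregate_layers(per_layer, [_cross_topo(0, "pep", "cdr3a")])
        np.testing.assert_array_equal(out["pep"].scores, [1.0, 2.0])
        np.testing.assert_array_equal(out["cdr3a"].scores, [0.5, 0.0, 3.0])

    def test_converging_key_branches_merge_by_max(self):
        per_layer = {
            0: (_ti("pep", [1.0, 1.0]), _ti("cdr3a", [1.0, 0.0, 2.0])),
            1: (_ti("pep", [1.0, 1.0]), _ti("cdr3a", [0.0, 3.0, 1.0])),
        }
        topo = [_cross_topo(0, "pep", "cdr3a"), _cross_topo(1, "pep", "cdr3a")]
        out = aggregate_layers(per_layer, topo)
        np.testing.assert_array_equal(out["cdr3a"].scores, [1.0, 3.0, 2.0])

    def test_two_block_chain_matches_hand_unrolled_oracle(self):
        """Product down the decoder chain, max across converging branches."""
        rng = np.random.default_rng(5)
        q0, q1, q2 = (rng.uniform(0, 2, size=4) for _ in range(3))
        ka0, ka2 = rng.uniform(0, 2, size=3), rng.uniform(0, 2, size=3)
        kb1 = rng.uniform(0, 2, size=5)
        per_layer = {
            0: (_ti("pep", q0), _ti("cdr3a", ka0)),
            1: (_ti("pep", q1), _ti("cdr3b", kb1)),
            2: (_ti("pep", q2), _ti("cdr3a", ka2)),
        }
        topo = [
            _cross_topo(0, "pep", "cdr3a"),
            _cross_topo(1, "pep", "cdr3b"),
            _cross_topo(2, "pep", "cdr3a"),
        ]
        out = aggregate_layers(per_layer, topo)
        # independent hand-unrolled application of the two rules
        np.testing.assert_allclose(out["pep"].scores, q0 * q1 * q2)
        np.testing.assert_allclose(out["cdr3a"].scores, np.maximum(ka0, ka2))
        np.testing.assert_allclose(out["cdr3b"].scores, kb1)

    def test_length_mismatch_names_layers(self):
        per_layer = {
            0: (_ti("pep", [1.0, 1.0]), _ti("cdr3a", [1.0])),
            1: (_ti("pep", [1.0, 1.0]), _ti("cdr3a", [1.0, 2.0])),
        }
        topo = [_cross_topo(0, "pep", "cdr3a"), _cross_topo(1, "pep", "cdr3a")]
        with pytest.raises(ValueError, match="cdr3a"):
            aggregate_layers(per_layer, topo)


class TestExplain:
    def test_deterministic(self, toy_run):
        a = explain(toy_run)
        b = explain(toy_run)
        for name in a:
            assert np.array_equal(a[name].scores, b[name].scores)

    def test_planted_key_token_wins(self, class_target):
        model = make_toy_model(
            ToyModelConfig(seed=11, planted_key_seq="pep", planted_positions=(4,))
        )
        rng = np.random.default_rng(11)
        run = run_with_capture(model, random_inputs(rng), class_target)
        scores = explain(run)["pep"].scores
        assert int(np.argmax(scores)) == 4
        top2 = np.sort(scores)[-2:]
        assert top2[1] > top2[0]  # strictly maximal

    def test_no_cross_attention_is_informative_error(self, toy_run):
        run = toy_run
        run.records = run.self_attention_records()
        with pytest.raises(ValueError, match="baseline"):
            explain(run)

    def test_all_zero_gradients_give_all_zero_scores(self):
        a = np.full((1, 2, 3), 1 / 3)
        rec = make_record(a[0], np.zeros((2, 3)),
                          query_act=np.ones((2, 4)), key_act=np.ones((3, 4)))
        from qcai.adapter import CaptureRun, TokenMap
        run = CaptureRun(
            records=[rec], loss_value=0.0, target_spec=TargetSpec(),
            token_maps={"pep": TokenMap(list("ACD")), "cdr3b": TokenMap(list("GH"))},
        )
        out = explain(run)
        for imp in out.values():
            assert np.all(imp.scores == 0.0)

    def test_scores_nonnegative_everywhere(self, toy_run):
        for imp in explain(toy_run).values():
            assert np.all(imp.scores >= 0.0)


class TestNormalization:
    def test_minmax_to_unit_interval(self):
        s = normalize_scores(np.array([2.0, 4.0, 3.0]))
        np.testing.assert_allclose(s, [0.0, 1.0, 0.5])

    def test_constant_vector_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_scores(np.ones(4)), np.zeros(4))

    @given(arrays(float, 5, elements=st.floats(0, 1e6)))
    @settings(max_examples=50)
    def test_ranking_preserved(self, s):
        n = normalize_scores(s)
        assert np.array_equal(np.argsort(s, kind="stable"),
                              np.argsort(n, kind="stable"))
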