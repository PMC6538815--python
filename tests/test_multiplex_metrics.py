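import numpy as np
import pytest
from hypothesis import given, strategies as st

from brainmux import (
    METRIC_NAMES,
    MultiplexReference,
    assemble_feature_matrix,
    conditional_by_degree,
    inverse_participation,
    multi_inverse_participation,
    multistrength,
    strengths,
)
from brainmux.multiplex_metrics import Multiplex
from brainmux.network_construction import DegreeVector, Layer

from conftest import layer_from_weights


def triangle_layer():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[0, 2] = w[2, 0] = 0.25
    w[1, 2] = w[2, 1] = 1.0
    return layer_from_weights(w)


def scaled(layer, factor):
    return layer_from_weights(layer.weights * factor, grid_ref=layer.grid_ref)


class TestStrength:
    def test_empty_graph(self):
        assert np.all(strengths(layer_from_weights(np.zeros((4, 4)))) == 0.0)

    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(5)
        np.testing.assert_allclose(strengths(layer_from_weights(w)), 4.0)

    def test_hand_summation(self):
        np.testing.assert_allclose(strengths(triangle_layer()), [0.75, 1.5, 1.25])


class TestInverseParticipation:
    def test_single_connection_concentration(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.3
        Y = inverse_participation(layer_from_weights(w))
        assert Y[0] == pytest.approx(1.0)

    def test_uniform_limit(self):
        n = 7
        w = 0.5 * (1.0 - np.eye(n))
        Y = inverse_participation(layer_from_weights(w))
        np.testing.assert_allclose(Y, 1.0 / (n - 1))

    def test_hand_evaluation(self):
        w = np.zeros((4, 4))
        for j, v in zip((1, 2, 3), (0.5, 0.25, 0.25)):
            w[0, j] = w[j, 0] = v
        Y = inverse_participation(layer_from_weights(w))
        assert Y[0] == pytest.approx(0.375)

    def test_isolated_node_zero_with_warning(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        with pytest.warns(UserWarning, match="isolated"):
            Y = inverse_participation(layer_from_weights(w))
        assert Y[2] == 0.0

    def test_bounds_on_random_layer(self):
        rng = np.random.default_rng(0)
        w = np.triu(rng.uniform(size=(10, 10)), 1)
        layer = layer_from_weights(w + w.T)
        Y = inverse_participation(layer)
        s = strengths(layer)
        assert np.all(Y[s > 0] >= 1.0 / 9 - 1e-12)
        assert np.all(Y[s > 0] <= 1.0 + 1e-12)
        # participation shares normalize
        shares = layer.weights[s > 0] / s[s > 0, None]
        np.testing.assert_allclose(shares.sum(axis=1), 1.0)


class TestMultiplexMetrics:
    def test_homogeneous_multiplex_unit_multistrength(self):
        lay = triangle_layer()
        ref = MultiplexReference.from_layers([lay, lay, lay])
        np.testing.assert_allclose(multistrength(lay, ref), 1.0)

    def test_proportionality(self):
        lay = triangle_layer()
        ref = MultiplexReference.from_layers([lay, lay])
        np.testing.assert_allclose(multistrength(scaled(lay, 2.0), ref), 2.0)

    def test_hand_multistrength(self):
        # 2-layer reference with node strengths (1, 3); evaluated layer s = 1
        lay1 = layer_from_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))  # s = (1, 1)
        lay2 = layer_from_weights(np.array([[0.0, 3.0], [3.0, 0.0]]))  # s = (3, 3)
        ref = MultiplexReference.from_layers([lay1, lay2])  # o = (4, 4), A = 2
        np.testing.assert_allclose(multistrength(lay1, ref), 1.0 * 2 / 4)

    def test_sole_contributor_multi_inverse(self):
        lay = triangle_layer()
        ref = MultiplexReference.from_layers([lay])
        np.testing.assert_allclose(multi_inverse_participation(lay, ref), 1.0)

    def test_equal_shares_multi_inverse(self):
        lay = triangle_layer()
        A = 5
        ref = MultiplexReference.from_layers([lay] * A)
        np.testing.assert_allclose(multi_inverse_participation(lay, ref), 1.0 / A**2)

    def test_hand_multi_inverse(self):
        lay = layer_from_weights(np.array([[0.0, 1.0], [1.0, 0.0]]))  # s = 1
        ref = MultiplexReference(overlapping_strength=np.array([4.0, 4.0]), layer_count=2)
        np.testing.assert_allclose(multi_inverse_participation(lay, ref), 0.0625)

    def test_node_count_mismatch_error(self):
        ref = MultiplexReference(overlapping_strength=np.ones(5), layer_count=1)
        with pytest.raises(ValueError, match="nodes"):
            multistrength(triangle_layer(), ref)


class TestConditionalByDegree:
    def test_single_class_is_global_mean(self):
        vals = np.array([1.0, 4.0, 7.0])
        deg = DegreeVector(degrees=np.array([2, 2, 2]), tau=0.5)
        np.testing.assert_allclose(conditional_by_degree(vals, deg), 4.0)

    def test_singleton_class_is_own_value(self):
        vals = np.array([1.0, 4.0, 7.0])
        deg = DegreeVector(degrees=np.array([1, 2, 3]), tau=0.5)
        np.testing.assert_allclose(conditional_by_degree(vals, deg), vals)

    def test_hand_grouping(self):
        vals = np.array([1.0, 2.0, 6.0])
        deg = DegreeVector(degrees=np.array([2, 2, 3]), tau=0.5)
        np.testing.assert_allclose(conditional_by_degree(vals, deg), [1.5, 1.5, 6.0])

    @given(st.integers(0, 2**31 - 1))
    def test_class_means_preserved(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=12)
        k = rng.integers(0, 4, size=12)
        out = conditional_by_degree(vals, DegreeVector(degrees=k, tau=0.0))
        for c in np.unique(k):
            assert out[k == c].mean() == pytest.approx(vals[k == c].mean())


class TestFeatureMatrix:
    def test_minimal_matrix_shape(self):
        lay = triangle_layer()
        fm = assemble_feature_matrix(Multiplex(layers=[lay]), tau=0.0)
        assert fm.X.shape == (1, 24)
        assert len(fm.columns) == 24
        assert fm.columns[0].startswith("strength")

    def test_metric_major_ordering(self):
        lay = triangle_layer()
        fm = assemble_feature_matrix(Multiplex(layers=[lay]), tau=0.0)
        for b, metric in enumerate(METRIC_NAMES):
            assert fm.columns[b * 3] == f"{metric}_0000"

    def test_subject_permutation_permutes_rows(self):
        rng = np.random.default_rng(1)
        layers = []
        for i in range(5):
            w = np.triu(rng.uniform(size=(4, 4)), 1)
            layers.append(
                layer_from_weights(w + w.T, subject_id=f"s{i}", age=float(20 + i))
            )
        fm = assemble_feature_matrix(Multiplex(layers=layers), tau=0.3)
        perm = [3, 0, 4, 1, 2]
        fm_p = assemble_feature_matrix(
            Multiplex(layers=[layers[i] for i in perm]), tau=0.3
        )
        np.testing.assert_allclose(fm_p.X, fm.X[perm])
        np.testing.assert_allclose(fm_p.y, fm.y[perm])

    def test_reproducibility_bit_identical(self, small_multiplex):
        fm1 = assemble_feature_matrix(small_multiplex)
        fm2 = assemble_feature_matrix(small_multiplex)
        assert np.array_equal(fm1.X, fm2.X)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        w = np.triu(rng.uniform(size=(6, 6)), 1)
        w = w + w.T
        perm = rng.permutation(6)
        lay = layer_from_weights(w)
        lay_p = layer_from_weights(w[np.ix_(perm, perm)])
        fm = assemble_feature_matrix(Multiplex(layers=[lay]), tau=0.4)
        fm_p = assemble_feature_matrix(Multiplex(layers=[lay_p]), tau=0.4)
        for b in range(8):
            np.testing.assert_allclose(
                fm_p.X[0, b * 6 : (b + 1) * 6],
                fm.X[0, b * 6 : (b + 1) * 6][perm],
                atol=1e-12,
            )
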