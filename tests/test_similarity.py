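"""Phenotype-network container, normalization, calibration and combination."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenoprio as pp
from phenoprio.exceptions import AlignmentError, DegenerateInputError

from conftest import random_phenonet


def net_from(matrix, symmetric=False, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [f"D{i}" for i in range(matrix.shape[0])]
    return pp.PhenotypeNet(ids, matrix, symmetric=symmetric)


class TestPhenotypeNet:
    def test_rejects_non_square_and_duplicate_ids(self):
        with pytest.raises(ValueError):
            pp.PhenotypeNet(["a", "b"], np.zeros((2, 3)))
        with pytest.raises(ValueError):
            pp.PhenotypeNet(["a", "a"], np.zeros((2, 2)))

    def test_value_range_and_lookup(self):
        net = net_from([[0.5, 0.1], [0.2, 0.9]])
        assert net.value_range == (0.1, 0.9)
        assert net.index("D1") == 1
        assert "D0" in net and "X" not in net
        with pytest.raises(KeyError):
            net.index("X")


class TestSymmetrize:
    def test_averages_directed_scores(self):
        net = net_from([[1.0, 0.2], [0.4, 1.0]])
        out = pp.symmetrize(net)
        assert out.symmetric
        assert out.scores[0, 1] == out.scores[1, 0] == pytest.approx(0.3)

    def test_matches_entrywise_loop_oracle(self, rng):
        M = rng.uniform(0, 3, size=(3, 3))
        out = pp.symmetrize(net_from(M)).scores
        for i in range(3):
            for j in range(3):
                assert out[i, j] == pytest.approx((M[i, j] + M[j, i]) / 2)

    def test_idempotent_and_identity_on_symmetric(self, rng):
        net = random_phenonet(rng, symmetric=True)
        once = pp.symmetrize(net)
        assert np.array_equal(once.scores, net.scores)
        assert np.array_equal(pp.symmetrize(once).scores, once.scores)


class TestNormalize:
    # Hand case: S(A,B)=2 with self-similarities S(A,A)=4, S(B,B)=3.
    HAND = np.array([[4.0, 2.0], [2.0, 3.0]])

    @pytest.mark.parametrize(
        "method,expected_ab",
        [
            ("lin", 2 * 2 / (4 + 3)),
            ("sqrt", 2 / math.sqrt(12)),
            ("tanimoto", 2 / (4 + 3 - 2)),
        ],
    )
    def test_hand_values(self, method, expected_ab):
        out = pp.normalize(net_from(self.HAND, symmetric=True), method)
        assert out.scores[0, 1] == pytest.approx(expected_ab)

    def test_tanimoto_diagonal_is_one(self):
        out = pp.normalize(net_from(self.HAND, symmetric=True), "tanimoto")
        assert np.allclose(np.diag(out.scores), 1.0)

    def test_maxmin_endpoints(self, rng):
        net = random_phenonet(rng)
        out = pp.normalize(net, "maxmin").scores
        assert out.min() == 0.0 and out.max() == 1.0
        # extremes are taken over the whole matrix, diagonal included
        i, j = np.unravel_index(np.argmax(net.scores), net.scores.shape)
        assert out[i, j] == 1.0

    def test_maxmin_constant_matrix_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pp.normalize(net_from(np.full((3, 3), 0.7)), "maxmin")

    @pytest.mark.parametrize("method", ["lin", "sqrt", "tanimoto"])
    def test_zero_self_similarity_yields_zero(self, method):
        # a disease with no phenotype evidence contributes nothing
        S = np.array([[0.0, 0.0], [0.0, 3.0]])
        out = pp.normalize(net_from(S, symmetric=True), method).scores
        assert out[0, 0] == 0.0 and out[0, 1] == 0.0 and out[1, 0] == 0.0

    def test_values_above_one_are_clipped_with_warning(self, caplog):
        S = np.array([[1.0, 5.0], [5.0, 1.0]])  # cross > self: noisy input
        with caplog.at_level("WARNING"):
            out = pp.normalize(net_from(S, symmetric=True), "lin")
        assert out.scores.max() <= 1.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pp.normalize(net_from(self.HAND), "zscore")

    @pytest.mark.parametrize("method", ["lin", "sqrt", "maxmin", "tanimoto"])
    @given(seed=st.integers(0, 50))
    def test_output_range_in_unit_interval(self, method, seed):
        net = random_phenonet(np.random.default_rng(seed), n=6)
        out = pp.normalize(net, method).scores
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_symmetrize_then_tanimoto_is_exactly_symmetric(self, rng):
        asym = net_from(rng.uniform(0.5, 4, size=(6, 6)))
        out = pp.normalize(pp.symmetrize(asym), "tanimoto")
        assert np.array_equal(out.scores, out.scores.T)


class TestLogistic:
    def test_value_at_zero_forced_by_offset(self):
        assert pp.logistic(0.0, c=-15.0) == pytest.approx(1e-4)

    def test_half_at_minus_d_over_c(self):
        c = -13.0
        assert pp.logistic(-pp.LOGISTIC_D / c, c) == pytest.approx(0.5)

    def test_strictly_increasing_for_negative_c(self):
        x = np.linspace(0, 1, 1000)
        y = pp.logistic(x, c=-17.0)
        # pointwise re-evaluation oracle
        oracle = np.array([1 / (1 + math.exp(-17.0 * xi + math.log(9999))) for xi in x])
        assert np.allclose(y, oracle)
        assert np.all(np.diff(y) > 0)

    def test_maps_unit_interval_into_open_unit_interval(self, rng):
        net = random_phenonet(rng, symmetric=True)
        unit = pp.normalize(net, "tanimoto")
        out = pp.logistic_transform(unit, -12.0)
        assert out.symmetric
        assert np.all(out.scores > 0) and np.all(out.scores < 1)


class TestCombine:
    def test_endpoints_are_bit_identical(self, rng):
        a = random_phenonet(rng, symmetric=True)
        b = pp.PhenotypeNet(a.disease_ids, rng.uniform(0, 1, a.scores.shape))
        assert np.array_equal(pp.combine(a, b, 1.0).scores, a.scores)
        assert np.array_equal(pp.combine(a, b, 0.0).scores, b.scores)

    def test_half_is_entrywise_arithmetic_average(self, rng):
        a = random_phenonet(rng)
        b = pp.PhenotypeNet(a.disease_ids, rng.uniform(0, 1, a.scores.shape))
        out = pp.combine(a, b, 0.5).scores
        assert np.allclose(out, (a.scores + b.scores) / 2)

    def test_matches_entrywise_loop_oracle(self, rng):
        A = rng.uniform(0, 1, (4, 4))
        B = rng.uniform(0, 1, (4, 4))
        ids = list("wxyz")
        out = pp.combine(net_from(A, ids=ids), net_from(B, ids=ids), 0.3).scores
        for i in range(4):
            for j in range(4):
                assert out[i, j] == pytest.approx(0.3 * A[i, j] + 0.7 * B[i, j])

    @given(p=st.floats(0, 1), i=st.integers(0, 3), j=st.integers(0, 3))
    def test_linear_in_p_at_every_entry(self, p, i, j):
        rng = np.random.default_rng(99)
        A, B = rng.uniform(0, 1, (4, 4)), rng.uniform(0, 1, (4, 4))
        ids = list("abcd")
        out = pp.combine(net_from(A, ids=ids), net_from(B, ids=ids), p).scores
        assert out[i, j] == pytest.approx(p * A[i, j] + (1 - p) * B[i, j])

    def test_mismatched_disease_sets_rejected(self, rng):
        a = random_phenonet(rng)
        b = pp.PhenotypeNet([f"X{i}" for i in range(5)], rng.uniform(0, 1, (5, 5)))
        with pytest.raises(AlignmentError):
            pp.combine(a, b, 0.5)

    def test_proportion_out_of_range_rejected(self, rng):
        a = random_phenonet(rng)
        with pytest.raises(ValueError):
            pp.combine(a, a, 1.5)


class TestRelativeNetworkMean:
    def test_self_reference_is_exactly_one(self, rng):
        net = random_phenonet(rng)
        assert pp.relative_network_mean(net, net) == 1.0

    def test_doubled_network_gives_two(self, rng):
        ref = random_phenonet(rng)
        net = pp.PhenotypeNet(ref.disease_ids, 2.0 * ref.scores)
        assert pp.relative_network_mean(net, ref) == pytest.approx(2.0)

    def test_three_disease_hand_case(self):
        # rowsums 2,4,6 against 1,2,2 -> mean(2, 2, 3) = 7/3
        ids = ["a", "b", "c"]
        net = pp.PhenotypeNet(ids, np.array([[2, 0, 0], [0, 4, 0], [0, 0, 6.0]]))
        ref = pp.PhenotypeNet(ids, np.array([[1, 0, 0], [0, 2, 0], [0, 0, 2.0]]))
        assert pp.relative_network_mean(net, ref) == pytest.approx(7 / 3)

    def test_zero_reference_row_sum_names_disease(self, rng):
        net = random_phenonet(rng, n=3)
        ref = pp.PhenotypeNet(net.disease_ids, np.zeros((3, 3)))
        with pytest.raises(DegenerateInputError, match="D0"):
            pp.relative_network_mean(net, ref)


class TestIntersect:
    def test_set_intersection_of_ids(self):
        a = net_from(np.eye(3), ids=["1", "2", "3"])
        b = net_from(np.eye(3), ids=["2", "3", "4"])
        ra, rb = pp.intersect_networks(a, b)
        assert ra.disease_ids == rb.disease_ids == ["2", "3"]

    def test_identical_sets_unchanged_up_to_order(self, rng):
        net = random_phenonet(rng, n=4)
        ra, rb = pp.intersect_networks(net, net)
        assert ra.disease_ids == sorted(net.disease_ids)
        assert np.array_equal(ra.scores, rb.scores)

    def test_submatrix_matches_direct_indexing_oracle(self, rng):
        A = rng.uniform(0, 1, (5, 5))
        B = rng.uniform(0, 1, (5, 5))
        a = net_from(A, ids=["d1", "d2", "d3", "d4", "d5"])
        b = net_from(B, ids=["d3", "d4", "d5", "d6", "d7"])
        ra, rb = pp.intersect_networks(a, b)
        for x, dx in enumerate(ra.disease_ids):
            for y, dy in enumerate(ra.disease_ids):
                assert ra.scores[x, y] == A[a.index(dx), a.index(dy)]
                assert rb.scores[x, y] == B[b.index(dx), b.index(dy)]

    def test_empty_intersection_rejected(self, rng):
        a = random_phenonet(rng, n=3)
        b = net_from(np.eye(3), ids=["x", "y", "z"])
        with pytest.raises(AlignmentError):
            pp.intersect_networks(a, b)


class TestFormSelection:
    def test_symmetric_form_requires_symmetric_network(self, rng):
        asym = random_phenonet(rng, symmetric=False)
        with pytest.raises(ValueError):
            pp.query_similarities(asym, asym.disease_ids[0], pp.Form.SYMMETRIC)

    def test_row_col_require_asymmetric_network(self, rng):
        sym = random_phenonet(rng, symmetric=True)
        with pytest.raises(ValueError):
            pp.query_similarities(sym, sym.disease_ids[0], pp.Form.ROW)

    def test_row_and_col_read_opposite_directions(self):
        S = np.array([[1.0, 0.2, 0.8], [0.5, 1.0, 0.1], [0.3, 0.6, 1.0]])
        net = pp.PhenotypeNet(["a", "b", "c"], S, symmetric=False)
        assert np.array_equal(pp.query_similarities(net, "b", pp.Form.ROW), S[1, :])
        assert np.array_equal(pp.query_similarities(net, "b", pp.Form.COL), S[:, 1])
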