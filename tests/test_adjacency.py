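"""Functional adjacency matrices, norms, permutations and nilpotency."""

import itertools

import numpy as np
import pytest

from bnstab import (boolean_power, compute_adjacency, is_acyclic,
                    is_strictly_triangular, iterate_adjacency,
                    nilpotency_index, parse_network, permute_by_col_norm,
                    permute_by_row_norm, vector_stats)
from bnstab.adjacency import AdjacencyMatrix
from bnstab.fixtures import GeneratorConfig, random_network
from bnstab.network import FixedAssignment as FA

EX1_MATRIX = [
    "00100011",
    "00001101",
    "00000001",
    "01000010",
    "01010000",
    "00100001",
    "01000001",
    "11010010",
]


def bits(rows):
    return np.array([[int(c) for c in r] for r in rows], dtype=bool)


class TestComputeAdjacency:
    def test_benchmark_8node_matrix(self, ex1):
        A = compute_adjacency(ex1)
        assert (A.matrix == bits(EX1_MATRIX)).all()

    def test_vacuous_dependence_is_zero(self):
        net = parse_network("a, b | !b\nb, a")
        A = compute_adjacency(net)
        assert A[0, 1] == 0  # tautology: no functional dependence

    def test_controlled_4node_matrix(self, ex2):
        A = compute_adjacency(ex2, [FA("x3", 1)])
        assert (A.matrix == bits(["0110", "0001", "0000", "0010"])).all()

    def test_binding_also_zeroes_fixed_columns(self, ex2):
        A = compute_adjacency(ex2, [FA("x3", 1)], bind=True)
        assert not A.matrix[:, 2].any()
        assert not A.matrix[2, :].any()


class TestVectorStats:
    def test_row_norms_after_row_permutation(self, ex1):
        P = permute_by_row_norm(compute_adjacency(ex1))
        assert vector_stats(P).row_norms == (1, 2, 2, 2, 2, 3, 3, 4)

    def test_col_norms_after_col_permutation(self, ex1):
        P = permute_by_col_norm(compute_adjacency(ex1))
        assert vector_stats(P).col_norms == (1, 1, 1, 2, 2, 3, 4, 5)

    def test_zero_matrix_stats(self):
        A = AdjacencyMatrix(np.zeros((3, 3), dtype=bool), ("a", "b", "c"))
        st = vector_stats(A)
        assert st.row_norms == st.col_norms == st.d_rows == st.d_cols == (0, 0, 0)

    def test_partial_column_sum_for_last_node(self, ex1):
        # x8 has the largest row norm, so it lands last and its partial
        # column sum equals its full out-degree.
        P = permute_by_row_norm(compute_adjacency(ex1))
        assert P.labels[-1] == "x8"
        assert vector_stats(P).d_cols[-1] == 5


class TestPermutation:
    def test_stable_sort_keeps_tied_order(self):
        net = parse_network("a, b\nb, a\nc, a")
        A = compute_adjacency(net)
        assert permute_by_row_norm(A).labels == ("a", "b", "c")

    def test_permutation_preserves_entry_multiset_and_cycles(self, ex1):
        A = compute_adjacency(ex1)
        for P in (permute_by_row_norm(A), permute_by_col_norm(A)):
            assert P.matrix.sum() == A.matrix.sum()
            assert is_acyclic(P) == is_acyclic(A)

    def test_permutation_record_recovers_original(self, ex1):
        A = compute_adjacency(ex1)
        P = permute_by_row_norm(A)
        inv = np.argsort(P.perm)
        assert (P.matrix[np.ix_(inv, inv)] == A.matrix).all()


class TestBooleanPower:
    def test_controlled_matrix_fourth_power_vanishes(self, ex2):
        A = compute_adjacency(ex2, [FA("x3", 1)])
        assert not boolean_power(A, 4).matrix.any()
        assert boolean_power(A, 3).matrix.any()

    def test_power_one_is_identity_operation(self, ex1):
        A = compute_adjacency(ex1)
        assert (boolean_power(A, 1).matrix == A.matrix).all()

    def test_permutation_matrix_never_vanishes(self):
        m = np.eye(4, dtype=bool)[[1, 2, 3, 0]]
        A = AdjacencyMatrix(m, ("a", "b", "c", "d"))
        for k in (1, 2, 5, 8):
            assert boolean_power(A, k).matrix.any()


class TestNilpotency:
    def test_controlled_4node_index_is_four(self, ex2):
        A = compute_adjacency(ex2, [FA("x3", 1)])
        assert nilpotency_index(A) == 4

    def test_zero_matrix_index_one(self):
        A = AdjacencyMatrix(np.zeros((5, 5), dtype=bool), tuple("abcde"))
        assert nilpotency_index(A) == 1

    def test_self_loop_not_nilpotent(self):
        m = np.zeros((3, 3), dtype=bool)
        m[0, 0] = True
        assert nilpotency_index(AdjacencyMatrix(m, ("a", "b", "c"))) is None


class TestTriangularAndAcyclic:
    def test_raw_benchmark_matrix_not_triangular(self, ex1):
        A = compute_adjacency(ex1)
        assert not is_strictly_triangular(A, "lower")
        assert not is_strictly_triangular(A, "upper")

    def test_zero_matrix_triangular_both_sides(self):
        A = AdjacencyMatrix(np.zeros((4, 4), dtype=bool), tuple("abcd"))
        assert is_strictly_triangular(A, "lower")
        assert is_strictly_triangular(A, "upper")

    def test_zeroing_hub_rows_makes_benchmark_acyclic(self, ex1):
        A = compute_adjacency(ex1)
        for nm in ("x8", "x2"):
            k = A.labels.index(nm)
            A.matrix[k, :] = False
            A.matrix[:, k] = False
        assert is_acyclic(A)

    def test_self_loop_is_cyclic(self):
        m = np.zeros((2, 2), dtype=bool)
        m[1, 1] = True
        assert not is_acyclic(AdjacencyMatrix(m, ("a", "b")))

    def test_constructed_dag_is_acyclic(self):
        rng = np.random.default_rng(3)
        m = np.tril(rng.random((6, 6)) < 0.5, k=-1)
        assert is_acyclic(AdjacencyMatrix(m, tuple("abcdef")))


class TestIterateAdjacency:
    def test_third_iterate_of_controlled_network_vanishes(self, ex2):
        A = iterate_adjacency(ex2, [FA("x3", 1)], k=3)
        assert not A.matrix.any()

    def test_first_iterate_equals_definition(self, ex1):
        A1 = iterate_adjacency(ex1, k=1)
        assert (A1.matrix == compute_adjacency(ex1).matrix).all()

    def test_smallest_vanishing_iterate_with_hub_control(self, ex1):
        # brute-force composition: find smallest k with A(F^k) = 0
        ks = [k for k in range(1, 9)
              if not iterate_adjacency(ex1, [FA("x8", 1)], k=k).matrix.any()]
        assert ks, "controlled network should have a vanishing iterate"
        k0 = ks[0]
        assert iterate_adjacency(ex1, [FA("x8", 1)], k=k0 - 1).matrix.any()
        # dominance bound places it at or below the Boolean-power index
        A = compute_adjacency(ex1, [FA("x8", 1)])
        kA = nilpotency_index(A)
        assert kA is None or k0 <= kA

    @pytest.mark.parametrize("seed", range(8))
    def test_elementwise_dominance_bound(self, seed):
        net = random_network(GeneratorConfig(n=6, s=3, seed=seed))
        A = compute_adjacency(net)
        for k in range(1, 6):
            lhs = iterate_adjacency(net, k=k).matrix
            rhs = boolean_power(A, k).matrix
            assert not (lhs & ~rhs).any()


class TestThreeWayEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_nilpotent_iff_acyclic_iff_permutable_to_triangular(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        m = rng.random((n, n)) < 0.3
        A = AdjacencyMatrix(m, tuple(f"n{i}" for i in range(n)))
        nil = nilpotency_index(A) is not None
        acy = is_acyclic(A)
        tri = any(
            not np.triu(m[np.ix_(p, p)], k=0).any()
            for p in map(list, itertools.permutations(range(n)))
        )
        assert nil == acy == tri
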