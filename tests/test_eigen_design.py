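import itertools
from fractions import Fraction

import numpy as np
import pytest

import qdyad as q

from conftest import CANONICAL_ORDER, DYAD_OPTIMA, DYAD_TABLE

F = Fraction


def brute_force_min_sum(table, grid):
    """Exhaustive integer-grid oracle for the min-sum separation problem."""
    m = len(table)
    best = None
    argmins = set()
    for lam in itertools.product(grid, repeat=m):
        if any(
            abs(lam[i] - lam[k]) < table[i][k]
            for i in range(m)
            for k in range(i + 1, m)
        ):
            continue
        total = sum(lam)
        if best is None or total < best:
            best = total
            argmins = set()
        if total == best:
            argmins.add(lam)
    return best, argmins


def grid_embedding_oracle(pattern, max_value=18, max_xy=6):
    """Exhaustive oracle: does any integer (λ, x, y) with 0 < x < y realize
    every pairwise gap exactly as the mapped pattern value?

    Gap differences are shift-invariant, so the search fixes min(λ) = 0.
    """
    m = len(pattern.labels)
    grids = np.meshgrid(*([np.arange(max_value + 1)] * m), indexing="ij")
    lam = np.stack([g.ravel() for g in grids], axis=1)
    lam = lam[lam.min(axis=1) == 0]
    pairs = list(itertools.combinations(range(m), 2))
    gaps = np.stack([np.abs(lam[:, i] - lam[:, k]) for i, k in pairs], axis=1)
    for x in range(1, max_xy + 1):
        for y in range(x + 1, max_xy + 1):
            target = np.array(
                [x if pattern.assignment[p] == "a" else y for p in pairs]
            )
            if np.any(np.all(gaps == target, axis=1)):
                return True
    return False


class TestSolveMinSum:
    def test_dyad_has_exactly_eight_optimal_solutions(self, dyad_problem):
        objective, solutions = q.solve_min_sum(dyad_problem)
        assert objective == 12
        assert {tuple(int(v) for v in s.values) for s in solutions} == DYAD_OPTIMA

    def test_agrees_with_brute_force_integer_grid(self, dyad_problem):
        objective, solutions = q.solve_min_sum(dyad_problem)
        oracle_best, oracle_set = brute_force_min_sum(DYAD_TABLE, range(11))
        assert objective == oracle_best
        assert {tuple(int(v) for v in s.values) for s in solutions} == oracle_set

    def test_every_solution_satisfies_the_constraints(self, dyad_problem):
        _, solutions = q.solve_min_sum(dyad_problem)
        for s in solutions:
            assert s.satisfies(dyad_problem)

    def test_two_label_problem(self):
        prob = q.SeparationProblem(["x", "y"], [[0, F(3)], [F(3), 0]])
        objective, solutions = q.solve_min_sum(prob)
        assert objective == 3
        assert {s.values for s in solutions} == {(F(0), F(3)), (F(3), F(0))}

    def test_optimum_invariant_under_relabeling(self, dyad_problem):
        perm = [2, 0, 3, 1]
        table = [
            [dyad_problem.separations[perm[i]][perm[k]] for k in range(4)]
            for i in range(4)
        ]
        prob = q.SeparationProblem([dyad_problem.labels[i] for i in perm], table)
        objective, solutions = q.solve_min_sum(prob)
        assert objective == 12 and len(solutions) == 8

    def test_solution_set_closed_under_the_table_symmetries(self, dyad_problem):
        # exchanging (0,0)<->(1,1), or (0,1)<->(1,0), permutes the optima
        _, solutions = q.solve_min_sum(dyad_problem)
        tuples = {tuple(s.values) for s in solutions}
        swapped_ends = {(t[3], t[1], t[2], t[0]) for t in tuples}
        swapped_mid = {(t[0], t[2], t[1], t[3]) for t in tuples}
        assert swapped_ends == tuples
        assert swapped_mid == tuples

    def test_negative_separations_rejected(self):
        with pytest.raises(ValueError):
            q.SeparationProblem(["x", "y"], [[0, -1], [-1, 0]])


class TestCanonicalSolution:
    def test_selects_2_0_4_6(self, dyad_problem):
        _, solutions = q.solve_min_sum(dyad_problem)
        canon = q.canonical_solution(solutions, CANONICAL_ORDER)
        assert tuple(int(v) for v in canon.values) == (2, 0, 4, 6)

    def test_canonical_gap_exceeds_its_requirement(self, dyad_problem):
        # the (0,1)-(1,1) gap is 6 although the Q-shape distance asks only 2
        _, solutions = q.solve_min_sum(dyad_problem)
        canon = q.canonical_solution(solutions, CANONICAL_ORDER)
        assert canon.gap("(0,1)", "(1,1)") == 6 > 2


class TestMonotoneEmbedding:
    def test_dyad_pattern_infeasible_for_randomized_values(
        self, dyad, dyad_states, dyad_labels
    ):
        table = q.distance_table(dyad, dyad_states)
        pattern = q.pattern_from_table(table, dyad_labels)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            a = F(rng.integers(1, 50).item(), rng.integers(1, 20).item())
            b = a + F(rng.integers(1, 50).item(), rng.integers(1, 20).item())
            report = q.check_monotone_embedding(pattern.with_values(a, b))
            assert not report.feasible
            assert report.contradictions

    def test_dyad_infeasibility_confirmed_by_grid_oracle(
        self, dyad, dyad_states, dyad_labels
    ):
        table = q.distance_table(dyad, dyad_states)
        pattern = q.pattern_from_table(table, dyad_labels)
        assert grid_embedding_oracle(pattern) is False

    def test_additive_chain_is_feasible(self):
        pattern = q.SeparationPattern(
            ["1", "2", "3"], 1, 2,
            {(0, 1): "a", (1, 2): "a", (0, 2): "b"},
        )
        report = q.check_monotone_embedding(pattern)
        assert report.feasible
        w = report.witness
        lam = w["eigenvalues"]
        assert abs(lam["3"] - lam["1"]) == w["y"]
        assert 0 < w["x"] < w["y"]

    @pytest.mark.parametrize("labels", [3, 4])
    def test_agrees_with_grid_oracle_on_random_patterns(self, labels):
        rng = np.random.default_rng(7 + labels)
        pairs = list(itertools.combinations(range(labels), 2))
        for _ in range(25):
            kinds = rng.choice(["a", "b"], size=len(pairs))
            if len(set(kinds)) < 2:
                continue
            pattern = q.SeparationPattern(
                [str(i) for i in range(labels)], 1, 2, dict(zip(pairs, kinds))
            )
            got = q.check_monotone_embedding(pattern).feasible
            assert got == grid_embedding_oracle(pattern)

    def test_too_few_labels_rejected(self):
        pattern = q.SeparationPattern(["1", "2"], 1, 2, {(0, 1): "a"})
        with pytest.raises(ValueError):
            q.check_monotone_embedding(pattern)


class TestAffineDimension:
    def test_single_and_pair(self, dyad_qshapes):
        assert q.affine_dimension(dyad_qshapes[:1]) == 0
        assert q.affine_dimension(dyad_qshapes[:2]) == 1

    def test_dyad_dimension_matches_exact_rank_oracle(self, dyad_qshapes):
        import sympy

        coords = sympy.Matrix(
            [[x for x in Q.flatten()] for Q in dyad_qshapes]
        )
        centered = coords[1:, :] - sympy.Matrix.vstack(*[coords[0, :]] * 3)
        exact_rank = centered.rank()
        computed = q.affine_dimension(dyad_qshapes)
        assert computed == exact_rank
        # the parallelogram identity caps the dimension below the full
        # simplex dimension of four points
        assert computed == 2 < 3


class TestMultiOperatorSet:
    def test_squared_gaps_reproduce_qshape_distances(self, dyad_qshapes, dyad_labels):
        ops = q.build_multi_operator_set(dyad_qshapes, dyad_labels)
        # brute-force: squared Euclidean distance = (1/4) * differing entries
        for i, k in itertools.combinations(range(4), 2):
            differing = sum(
                1
                for ra, rb in zip(dyad_qshapes[i].rows, dyad_qshapes[k].rows)
                for a, b in zip(ra, rb)
                if a != b
            )
            assert ops.squared_gap(i, k) == pytest.approx(differing / 4)

    def test_identical_qshapes_give_zero_gap(self, dyad_qshapes, dyad_labels):
        ops = q.build_multi_operator_set(
            [dyad_qshapes[0]] * 4, dyad_labels
        )
        assert np.allclose(ops.gap_matrix(), 0.0)

    def test_reduced_basis_is_an_isometry(self, dyad_qshapes, dyad_labels):
        full = q.build_multi_operator_set(dyad_qshapes, dyad_labels)
        reduced = q.build_multi_operator_set(dyad_qshapes, dyad_labels, reduced=True)
        assert reduced.num_operators == q.affine_dimension(dyad_qshapes)
        assert np.allclose(full.gap_matrix(), reduced.gap_matrix())

    def test_mismatched_counts_rejected(self, dyad_qshapes):
        with pytest.raises(ValueError):
            q.build_multi_operator_set(dyad_qshapes, ["only", "two"])


class TestOperatorCounts:
    @pytest.mark.parametrize(
        "n,d,quantum,expected",
        [(2, 2, False, 27), (3, 3, False, 385), (2, 2, True, 99)],
    )
    def test_printed_counts(self, n, d, quantum, expected):
        assert q.count_operators(n, d, quantum=quantum) == expected

    def test_formula_structure(self):
        for n in range(1, 4):
            for d in (2, 3):
                assert q.count_operators(n, d) == (2**n - 1) * (2 * d**n + 1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            q.count_operators(0, 2)
        with pytest.raises(ValueError):
            q.count_operators(2, 1)
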