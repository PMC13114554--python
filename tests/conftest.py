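from fractions import Fraction

import pytest

import qdyad as q

F = Fraction
H = F(1, 2)

#: the four dyad Q-shape matrices in lexicographic state order, frozen from
#: the noised-complement forward/backward construction
DYAD_QSHAPES = {
    (0, 0): [[H, 0, H, 0], [H, 0, H, 0], [H, H, 0, 0], [H, H, 0, 0]],
    (0, 1): [[H, 0, H, 0], [H, 0, H, 0], [0, 0, H, H], [0, 0, H, H]],
    (1, 0): [[0, H, 0, H], [0, H, 0, H], [H, H, 0, 0], [H, H, 0, 0]],
    (1, 1): [[0, H, 0, H], [0, H, 0, H], [0, 0, H, H], [0, 0, H, H]],
}

#: pairwise row-sum distances with the unit base distance
DYAD_TABLE = [
    [0, 2, 2, 4],
    [2, 0, 4, 2],
    [2, 4, 0, 2],
    [4, 2, 2, 0],
]

#: the eight optimal eigenvalue assignments (λ00, λ01, λ10, λ11)
DYAD_OPTIMA = {
    (0, 2, 6, 4),
    (0, 6, 2, 4),
    (2, 0, 4, 6),
    (6, 0, 4, 2),
    (6, 4, 0, 2),
    (2, 4, 0, 6),
    (4, 2, 6, 0),
    (4, 6, 2, 0),
}

#: canonical state order in which the canonical solution increases
CANONICAL_ORDER = ["(0,1)", "(0,0)", "(1,0)", "(1,1)"]


@pytest.fixture(scope="session")
def dyad():
    return q.build_swap_dyad()


@pytest.fixture(scope="session")
def monad():
    return q.build_not_monad()


@pytest.fixture(scope="session")
def dyad_states(dyad):
    return dyad.all_states()


@pytest.fixture(scope="session")
def dyad_labels(dyad, dyad_states):
    return [dyad.state_label(s) for s in dyad_states]


@pytest.fixture(scope="session")
def dyad_qshapes(dyad, dyad_states):
    return [q.compute_qshape(dyad, s) for s in dyad_states]


@pytest.fixture(scope="session")
def dyad_problem(dyad, dyad_states, dyad_labels):
    table = q.distance_table(dyad, dyad_states)
    return q.SeparationProblem.from_table(dyad_labels, table)


@pytest.fixture(scope="session")
def canonical_operator(dyad_problem):
    _, solutions = q.solve_min_sum(dyad_problem)
    canon = q.canonical_solution(solutions, CANONICAL_ORDER)
    return q.CollapseOperatorSet.from_eigensolution(canon)
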