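"""Seeded random network fixtures for property tests and exploration."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .network import NetworkSpec, TransitionModel

__all__ = ["generate_fixture"]

_MAX_STATE_BITS = 12  # state space capped at 4096


def generate_fixture(kind: str, n: int, d: int, seed: int) -> NetworkSpec:
    """Random network with a deterministic-permutation or row-stochastic TPM.

    Reproducible from ``seed``; the joint state space is capped at 4096
    states.  Stochastic rows are drawn Dirichlet-flat and stored as exact
    rationals on a 10^6 grid so TransitionModel invariants hold exactly.
    """
    if n * math.log2(d) > _MAX_STATE_BITS:
        raise ValueError("state space too large: need n*log2(d) <= 12")
    size = d**n
    rng = np.random.default_rng(seed)
    if kind == "permutation":
        perm = rng.permutation(size)
        rows = [
            [Fraction(1) if k == perm[i] else Fraction(0) for k in range(size)]
            for i in range(size)
        ]
    elif kind == "stochastic":
        rows = []
        for _ in range(size):
            raw = rng.dirichlet(np.ones(size))
            grid = [int(round(x * 10**6)) for x in raw]
            grid[-1] = 10**6 - sum(grid[:-1])
            if grid[-1] < 0:  # pragma: no cover - rounding pathology
                grid[-1] = 0
                excess = sum(grid) - 10**6
                grid[int(np.argmax(grid))] -= excess
            rows.append([Fraction(g, 10**6) for g in grid])
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    labels = tuple(chr(ord("A") + i) for i in range(n))
    return NetworkSpec(
        n, d, labels, TransitionModel(rows), name=f"{kind}-n{n}d{d}-seed{seed}"
    )
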