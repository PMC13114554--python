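"""Statevector model of Schrödinger's dyad.

Prepares product states of the two channels (|0⟩, |1⟩, |±⟩ or explicit
amplitude pairs), applies the SWAP gate as a fixed unitary on the
computational basis (lexicographic order (0,0), (0,1), (1,0), (1,1)), and
iterates the feedback loop, optionally interleaving a stretch of collapse
evolution between gate applications.  Preparing |0,+⟩ and applying SWAP
yields |+,0⟩ = (|0,0⟩ + |1,0⟩)/√2 — a superposition of two dyad states
whose associated qualitative (Q-shape) states differ.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .dynamics import CollapseModel, DensityOp, evolve_master

__all__ = ["prepare_product", "apply_swap", "feedback_run", "TOKENS"]

_SQ2 = 1.0 / math.sqrt(2.0)

TOKENS: dict[str, tuple[complex, complex]] = {
    "0": (1.0, 0.0),
    "1": (0.0, 1.0),
    "+": (_SQ2, _SQ2),
    "-": (_SQ2, -_SQ2),
}


def prepare_product(tokens: Sequence) -> np.ndarray:
    """Tensor product of single-qubit states, normalized.

    Each token is one of "0", "1", "+", "-" or an explicit amplitude pair.
    """
    if not tokens:
        raise ValueError("need at least one qubit token")
    state = np.array([1.0 + 0.0j])
    for tok in tokens:
        if isinstance(tok, str):
            if tok not in TOKENS:
                raise ValueError(f"unknown token {tok!r}; use 0, 1, + or -")
            amp = np.array(TOKENS[tok], dtype=complex)
        else:
            amp = np.asarray(tok, dtype=complex)
            if amp.shape != (2,):
                raise ValueError("explicit amplitudes must be a pair")
            norm = np.linalg.norm(amp)
            if norm < 1e-12:
                raise ValueError("zero amplitude pair")
            amp = amp / norm
        state = np.kron(state, amp)
    return state / np.linalg.norm(state)


def apply_swap(psi: np.ndarray) -> np.ndarray:
    """Exchange the two channels: the amplitude of (a, b) moves to (b, a)."""
    psi = np.asarray(psi, dtype=complex)
    if psi.shape != (4,):
        raise ValueError("SWAP acts on a two-qubit state (4 amplitudes)")
    return psi[[0, 2, 1, 3]]


_SWAP_MATRIX = np.eye(4)[[0, 2, 1, 3]]


def feedback_run(
    psi0: np.ndarray,
    steps: int,
    model: CollapseModel | None = None,
    dt_per_step: float = 1.0,
) -> list[DensityOp]:
    """Iterate the SWAP feedback loop, with optional collapse between gates.

    Returns the density operator after the initial state and after each of
    ``steps`` rounds, where one round is: apply SWAP, then (if a collapse
    model is given) evolve the master equation for ``dt_per_step``.
    Without collapse the sequence is pure with period two.
    """
    if steps < 0:
        raise ValueError("steps must be non-negative")
    psi0 = np.asarray(psi0, dtype=complex)
    if abs(np.linalg.norm(psi0) - 1.0) > 1e-9:
        raise ValueError("initial state must be normalized")
    if model is not None and model.dim != 4:
        raise ValueError("collapse model must act on the 4-dimensional dyad")
    rho = DensityOp.from_pure(psi0)
    out = [rho]
    for _ in range(steps):
        mat = _SWAP_MATRIX @ rho.matrix @ _SWAP_MATRIX.T
        rho = DensityOp(mat, check=False)
        if model is not None and dt_per_step > 0:
            rho = evolve_master(model, rho, dt_per_step)
        out.append(rho)
    return out
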