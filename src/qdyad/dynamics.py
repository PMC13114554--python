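"""Collapse dynamics: Lindblad master equation and its stochastic unraveling.

The model couples the system to M commuting collapse operators, all
diagonal in the collapse basis, with a single global rate ω:

    dρ/dt = −i[H₀, ρ] − (ω/2) Σ_m [A_m, [A_m, ρ]].

Because the operators are diagonal, the double commutator acts entrywise:
the (i, k) coherence obeys dρ_ik/dt = −(ω/2)‖a⃗_i − a⃗_k‖² ρ_ik when
H₀ = 0, so populations are frozen and each off-diagonal element decays
exponentially with a rate set by the squared Euclidean gap between the
eigenvalue vectors — i.e. by the squared qualitative distance when the
operator set is built from Q-shape coordinates.

The stochastic pure-state dynamics is the quantum-state-diffusion
unraveling

    dψ = [−iH₀ dt − (ω/2) Σ_m (A_m − ⟨A_m⟩)² dt + √ω Σ_m (A_m − ⟨A_m⟩) dW_m] ψ,

integrated with Euler–Maruyama and per-step renormalization; its noise
average reproduces the master equation and individual trajectories collapse
onto collapse-basis eigenspaces with Born-rule frequencies.  (The √ω noise
coefficient is the one whose Itô expansion yields the ω/2 double-commutator
rate above for every ω.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eigen_design import CollapseOperatorSet

__all__ = [
    "CollapseModel",
    "DensityOp",
    "Trajectory",
    "lindblad_rhs",
    "evolve_master",
    "simulate_sde",
    "simulate_ensemble",
    "fit_decay_rate",
]

_HERM_TOL = 1e-9


@dataclass
class CollapseModel:
    """Diagonal commuting collapse operators with rate ω and optional H₀."""

    operators: CollapseOperatorSet
    omega: float = 1.0
    hamiltonian: np.ndarray | None = None

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("collapse rate omega must be positive")
        if self.hamiltonian is not None:
            H = np.asarray(self.hamiltonian, dtype=complex)
            if H.shape != (self.dim, self.dim):
                raise ValueError("Hamiltonian shape must match the collapse basis")
            if np.max(np.abs(H - H.conj().T)) > _HERM_TOL:
                raise ValueError("Hamiltonian must be Hermitian")
            self.hamiltonian = H

    @property
    def dim(self) -> int:
        return self.operators.vectors.shape[0]

    def gap_matrix(self) -> np.ndarray:
        """G[i, k] = ‖a⃗_i − a⃗_k‖², the squared eigenvalue-vector gaps."""
        return self.operators.gap_matrix()

    def max_gap2(self) -> float:
        return float(np.max(self.gap_matrix()))


class DensityOp:
    """Trace-1 positive Hermitian matrix with validation on construction."""

    def __init__(self, matrix, check: bool = True):
        rho = np.asarray(matrix, dtype=complex)
        if check:
            if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
                raise ValueError("density operator must be a square matrix")
            if np.max(np.abs(rho - rho.conj().T)) > 1e-9:
                raise ValueError("density operator must be Hermitian")
            if abs(np.trace(rho).real - 1.0) > 1e-9:
                raise ValueError(f"trace is {np.trace(rho).real}, not 1")
            if np.linalg.eigvalsh(rho).min() < -1e-9:
                raise ValueError("density operator must be positive semidefinite")
        self.matrix = rho

    @classmethod
    def from_pure(cls, psi) -> "DensityOp":
        psi = np.asarray(psi, dtype=complex)
        psi = psi / np.linalg.norm(psi)
        return cls(np.outer(psi, psi.conj()), check=False)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def purity(self) -> float:
        return float(np.trace(self.matrix @ self.matrix).real)

    def coherence(self, i: int, k: int) -> complex:
        return complex(self.matrix[i, k])

    def populations(self) -> np.ndarray:
        return np.real(np.diag(self.matrix))


def _double_commutator_sum(model: CollapseModel, rho: np.ndarray) -> np.ndarray:
    # diagonal operators act entrywise: Σ_m [A_m,[A_m,ρ]]_ik = ρ_ik ‖a_i − a_k‖²
    return model.gap_matrix() * rho


def lindblad_rhs(model: CollapseModel, rho: DensityOp | np.ndarray) -> np.ndarray:
    """Right-hand side −i[H₀, ρ] − (ω/2) Σ_m [A_m, [A_m, ρ]]."""
    mat = rho.matrix if isinstance(rho, DensityOp) else np.asarray(rho, dtype=complex)
    if mat.shape != (model.dim, model.dim):
        raise ValueError("density-operator shape does not match the model")
    out = -0.5 * model.omega * _double_commutator_sum(model, mat)
    if model.hamiltonian is not None:
        H = model.hamiltonian
        out = out - 1j * (H @ mat - mat @ H)
    return out


def evolve_master(model: CollapseModel, rho0: DensityOp, t: float) -> DensityOp:
    """Noise-averaged state at time t.

    With H₀ = 0 the equation is solved in closed form,
    ρ_ik(t) = ρ_ik(0)·exp(−(ω/2)‖a⃗_i − a⃗_k‖² t); otherwise an adaptive
    Runge–Kutta integration of the full master equation is used.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if model.hamiltonian is None:
        decay = np.exp(-0.5 * model.omega * model.gap_matrix() * t)
        return DensityOp(rho0.matrix * decay, check=False)
    from scipy.integrate import solve_ivp

    n = model.dim

    def rhs(_t, y):
        rho = y.reshape(n, n).astype(complex)
        return lindblad_rhs(model, rho).ravel()

    sol = solve_ivp(
        rhs,
        (0.0, t),
        rho0.matrix.ravel().astype(complex),
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    rho = sol.y[:, -1].reshape(n, n)
    rho = 0.5 * (rho + rho.conj().T)  # kill integrator round-off
    return DensityOp(rho, check=False)


@dataclass
class Trajectory:
    """One stochastic pure-state run on a fixed time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), dim), normalized rows
    seed: int
    dt: float
    noise: np.ndarray = field(default=None)  # realized dW, shape (steps, M)

    def outcome(self) -> int:
        """Index of the dominant collapse-basis state at the final time."""
        return int(np.argmax(np.abs(self.states[-1]) ** 2))


def _default_dt(model: CollapseModel) -> float:
    # keep the per-step contraction ω·max-gap²·dt small
    g = model.max_gap2()
    return 0.01 / (model.omega * g) if g > 0 else 0.01


def _em_step(model: CollapseModel, psi: np.ndarray, dt: float, dw: np.ndarray):
    """Vectorized Euler–Maruyama step for a batch of normalized states.

    ``psi`` has shape (batch, dim); ``dw`` has shape (batch, M).
    """
    a = model.operators.vectors  # (dim, M)
    w = model.omega
    prob = np.abs(psi) ** 2  # (batch, dim)
    means = prob @ a  # ⟨A_m⟩ per trajectory, (batch, M)
    centered = a[None, :, :] - means[:, None, :]  # (batch, dim, M)
    drift = -0.5 * w * np.sum(centered**2, axis=2) * dt  # (batch, dim)
    diffusion = np.sqrt(w) * np.einsum("bim,bm->bi", centered, dw)
    if model.hamiltonian is not None:
        hpsi = psi @ model.hamiltonian.T
    else:
        hpsi = 0.0
    new = psi + (-1j * dt) * hpsi + (drift + diffusion) * psi
    norms = np.linalg.norm(new, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise FloatingPointError("state norm collapsed to zero; reduce dt")
    return new / norms


def simulate_sde(
    model: CollapseModel,
    psi0,
    t: float,
    dt: float | None = None,
    seed: int = 0,
) -> Trajectory:
    """Integrate one stochastic trajectory, reproducible from ``seed``."""
    psi0 = np.asarray(psi0, dtype=complex)
    if abs(np.linalg.norm(psi0) - 1.0) > 1e-6:
        raise ValueError("initial state must be normalized")
    if dt is None:
        dt = _default_dt(model)
    if model.omega * model.max_gap2() * dt > 0.1:
        raise ValueError("dt too large for the model's fastest decay rate")
    steps = max(1, int(round(t / dt)))
    rng = np.random.default_rng(seed)
    M = model.operators.num_operators
    times = np.linspace(0.0, steps * dt, steps + 1)
    states = np.empty((steps + 1, psi0.size), dtype=complex)
    states[0] = psi0 / np.linalg.norm(psi0)
    noise = rng.normal(0.0, np.sqrt(dt), size=(steps, 1, M))
    psi = states[0][None, :]
    for s in range(steps):
        psi = _em_step(model, psi, dt, noise[s])
        states[s + 1] = psi[0]
    return Trajectory(times=times, states=states, seed=seed, dt=dt, noise=noise[:, 0, :])


def simulate_ensemble(
    model: CollapseModel,
    psi0,
    t: float,
    ntraj: int,
    dt: float | None = None,
    seed: int = 0,
    checkpoints: int = 5,
):
    """Integrate many trajectories at once; returns ensemble diagnostics.

    Returns a dict with the checkpoint times, the ensemble-averaged density
    operators at those times, the per-trajectory final outcomes, and the
    outcome histogram over collapse-basis states.  One master seed spawns
    the whole batch of Wiener increments (independent noise per operator).
    """
    psi0 = np.asarray(psi0, dtype=complex)
    psi0 = psi0 / np.linalg.norm(psi0)
    if dt is None:
        dt = _default_dt(model)
    steps = max(1, int(round(t / dt)))
    check_idx = np.unique(
        np.round(np.linspace(0, steps, checkpoints + 1)).astype(int)
    )
    rng = np.random.default_rng(seed)
    M = model.operators.num_operators
    dim = psi0.size
    psi = np.tile(psi0, (ntraj, 1))
    avg_rhos = {}
    if 0 in check_idx:
        avg_rhos[0] = np.einsum("bi,bk->ik", psi, psi.conj()) / ntraj
    for s in range(steps):
        dw = rng.normal(0.0, np.sqrt(dt), size=(ntraj, M))
        psi = _em_step(model, psi, dt, dw)
        if (s + 1) in check_idx:
            avg_rhos[s + 1] = np.einsum("bi,bk->ik", psi, psi.conj()) / ntraj
    outcomes = np.argmax(np.abs(psi) ** 2, axis=1)
    hist = np.bincount(outcomes, minlength=dim)
    return {
        "times": check_idx * dt,
        "avg_rho": [avg_rhos[i] for i in check_idx],
        "outcomes": outcomes,
        "histogram": hist,
        "seed": seed,
        "dt": dt,
        "ntraj": ntraj,
    }


def fit_decay_rate(times, rhos, pair: tuple[int, int]) -> float:
    """Least-squares slope of −log|ρ_ik(t)| for an H₀ = 0 evolution.

    Returns the fitted exponential decay rate of the (i, k) coherence;
    contract: equals (ω/2)‖a⃗_i − a⃗_k‖² for master-equation input.
    """
    i, k = pair
    mags = np.array(
        [abs(r.matrix[i, k] if isinstance(r, DensityOp) else r[i, k]) for r in rhos]
    )
    if mags[0] < 1e-12:
        raise ValueError("initial coherence vanishes; nothing to fit")
    if np.allclose(mags, mags[0]):
        return 0.0
    keep = mags > 1e-300
    t = np.asarray(times, dtype=float)[keep]
    y = np.log(mags[keep])
    slope = np.polyfit(t, y, 1)[0]
    return float(-slope)
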