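"""Overdamped Brownian dynamics with periodic boundaries.

The equation of motion is position-only Langevin dynamics: velocity is
slaved to force, dr/dt = -grad(U)/xi + f(t)/xi, with Gaussian white noise
whose variance is fixed by fluctuation–dissipation,
<f_i(t) f_j(t')> = 2 xi kBT delta_ij delta(t-t') I.  Euler–Maruyama
discretization: each step displaces a bead by (dt/xi) F + sqrt(2 kBT dt/xi) eta.
Hydrodynamic interactions between beads are neglected; the bead diffusion
coefficient is D = kBT/xi (Einstein relation, MSD = 6 D t).

State positions are stored *unwrapped*; the minimum-image convention is
applied to every pair interaction, so observables like MSD come for free
and re-wrapping is only done on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kernels
from .forcefield import BrokenBondError, FENEParams, PairTable, _as_bond_codes


@dataclass(frozen=True)
class BDParams:
    """Integration protocol in reduced units (tau = sqrt(m sigma^2/epsilon)).

    Defaults: kBT=1, dt=1e-4 tau, xi=0.5.  The bead mass never enters —
    overdamped dynamics carries no inertia; tau is bookkeeping only.
    """

    dt: float = 1e-4
    xi: float = 0.5
    kBT: float = 1.0
    n_steps: int = 100_000
    seed: int = 0
    save_every: int = 10_000
    skin: float = 0.5
    exclude_bonded_lj: bool = False
    trap_k: float = 0.0  # isotropic harmonic tether about the origin (0 = off)
    # stability guard: clamp of the per-step force displacement (sigma);
    # ~5x the typical displacement at the default dt, so it fires only in
    # the rare LJ-core squeezes that would otherwise snap a bond
    max_force_disp: float = 0.1

    def __post_init__(self):
        if self.dt <= 0 or self.xi <= 0 or self.kBT <= 0:
            raise ValueError("dt, xi, kBT must all be positive")
        if self.n_steps < 0 or self.save_every < 1:
            raise ValueError("n_steps >= 0 and save_every >= 1 required")


@dataclass
class SimulationState:
    """Positions + species + bonds + box of a running system.

    chain_id maps each bead to its molecule so analysis can group beads by
    chain.  positions are unwrapped; .wrapped_positions() folds them into
    the primary box.
    """

    positions: np.ndarray
    species: np.ndarray
    box: np.ndarray
    bonds: np.ndarray
    chain_id: np.ndarray | None = None
    step: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, float)
        self.species = np.ascontiguousarray(self.species, np.int8)
        self.box = np.asarray(self.box, float).reshape(3)
        self.bonds = np.ascontiguousarray(self.bonds, np.int64).reshape(-1, 2)
        if self.chain_id is None:
            self.chain_id = np.zeros(len(self.positions), np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrapped_positions(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.positions.copy(), self.species.copy(), self.box.copy(),
            self.bonds.copy(), self.chain_id.copy(), self.step,
        )


@dataclass
class Trajectory:
    """Frames saved by run(): unwrapped positions at a fixed step stride."""

    frames: list[np.ndarray]
    steps: list[int]
    species: np.ndarray
    box: np.ndarray
    bonds: np.ndarray
    chain_id: np.ndarray
    dt: float = 1e-4

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.steps, float) * self.dt


_NOISE_CHUNK = 512  # steps of pre-generated Gaussian noise per kernel call


def step(
    state: SimulationState,
    bd: BDParams,
    table: PairTable | None = None,
    fene: FENEParams = FENEParams(),
    n_steps: int = 1,
    rng: np.random.Generator | None = None,
    with_noise: bool = True,
    force_cap: float = np.inf,
) -> SimulationState:
    """Advance the state by n_steps Euler–Maruyama steps (in place).

    The noise stream comes from the supplied numpy Generator; when none is
    given a fresh one is derived from (bd.seed, state.step), making any
    (state, params) pair reproducible in isolation.
    """
    if table is None:
        table = PairTable.default()
    eps_t, sig_t, rc2_t, shift_t = table._tables()
    if rng is None:
        rng = np.random.default_rng((bd.seed, state.step))
    amp = np.sqrt(2.0 * bd.kBT * bd.dt / bd.xi)
    codes = _as_bond_codes(state.bonds, state.n_beads)
    n = state.n_beads
    done = 0
    while done < n_steps:
        chunk = min(_NOISE_CHUNK, n_steps - done)
        if with_noise:
            noise = amp * rng.standard_normal((chunk, n, 3))
        else:
            noise = np.zeros((chunk, n, 3))
        status, at, bad, _ = kernels.integrate(
            state.positions, state.species, state.box, state.bonds, codes,
            bd.exclude_bonded_lj, eps_t, sig_t, rc2_t, shift_t,
            fene.kappa, fene.R0, bd.dt, bd.xi, noise, bd.skin, bd.trap_k,
            force_cap, bd.max_force_disp,
        )
        if status == kernels.BOND_BROKEN:
            i, j = state.bonds[bad]
            raise BrokenBondError(
                f"integration unstable, reduce dt: bond ({i}, {j}) reached R0 "
                f"at step {state.step + done + at}"
            )
        done += chunk
    state.step += n_steps
    return state


def run(
    state: SimulationState,
    bd: BDParams,
    table: PairTable | None = None,
    fene: FENEParams = FENEParams(),
    callback=None,
) -> tuple[Trajectory, SimulationState]:
    """Propagate bd.n_steps steps, saving a frame every bd.save_every steps.

    The initial frame is always saved.  Bit-for-bit reproducible for a given
    (seed, single thread).  callback(state, frame_index) is invoked at each
    saved frame.
    """
    traj = Trajectory(
        frames=[state.positions.copy()], steps=[state.step],
        species=state.species.copy(), box=state.box.copy(),
        bonds=state.bonds.copy(), chain_id=state.chain_id.copy(), dt=bd.dt,
    )
    if callback is not None:
        callback(state, 0)
    done = 0
    rng = np.random.default_rng(bd.seed)
    while done < bd.n_steps:
        chunk = min(bd.save_every, bd.n_steps - done)
        step(state, bd, table, fene, n_steps=chunk, rng=rng)
        done += chunk
        traj.frames.append(state.positions.copy())
        traj.steps.append(state.step)
        if callback is not None:
            callback(state, len(traj) - 1)
    return traj, state


def replica_params(bd: BDParams, replica: int) -> BDParams:
    """Independent-replica protocol: same physics, decorrelated seed stream."""
    return replace(bd, seed=(bd.seed + 7_919 * (replica + 1)) % 2_147_483_647)
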