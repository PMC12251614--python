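"""Bonded (FENE) and non-bonded (truncated-shifted Lennard-Jones) interactions.

Reduced units throughout: lengths in sigma, energies in epsilon, kBT = 1 by
default.  Solvent is implicit — solvent quality lives entirely in the pair
cutoffs: hydrophobic A–A pairs keep the attractive well (rc = 2.5 sigma, poor
solvent) while A–B and B–B pairs are cut at the LJ minimum 2^(1/6) sigma
(purely repulsive, good solvent, the WCA limit).  Each pair potential is
shifted so it is exactly zero at its cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels

SPECIES = {"A": 0, "B": 1}
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class BrokenBondError(RuntimeError):
    """A FENE bond reached its maximum extension R0."""


class OverlapError(RuntimeError):
    """Two beads closer than the hard floor (1e-6 sigma)."""


@dataclass(frozen=True)
class FENEParams:
    """Finitely extensible nonlinear elastic bond: U = -kappa R0^2/2 ln(1-(r/R0)^2).

    kappa=30, R0=1.5 is the Kremer–Grest parameterization; together with the
    repulsive LJ core it prevents chain crossing and puts the equilibrium
    bond length near 0.97 sigma.
    """

    kappa: float = 30.0
    R0: float = 1.5

    def __post_init__(self):
        if self.kappa <= 0 or self.R0 <= 0:
            raise ValueError("FENE parameters kappa and R0 must be positive")


def _species_index(s) -> int:
    if isinstance(s, str):
        return SPECIES[s]
    return int(s)


@dataclass
class PairTable:
    """Per-species-pair LJ parameters with species-dependent cutoffs.

    Defaults encode the implicit-solvent rules: epsilon = sigma = 1 for all
    pairs, rc(A,A) = 2.5 sigma, rc(A,B) = rc(B,B) = 2^(1/6) sigma, and each
    pair shifted so U(rc) = 0.
    """

    epsilon: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    sigma: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    rc: np.ndarray = field(
        default_factory=lambda: np.array(
            [[2.5, WCA_CUTOFF], [WCA_CUTOFF, WCA_CUTOFF]]
        )
    )

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, float)
        self.sigma = np.asarray(self.sigma, float)
        self.rc = np.asarray(self.rc, float)
        for name, a in (("epsilon", self.epsilon), ("sigma", self.sigma), ("rc", self.rc)):
            if a.shape != (2, 2):
                raise ValueError(f"{name} must be a 2x2 species-pair table")
            if not np.allclose(a, a.T):
                raise ValueError(f"{name} must be symmetric in the species pair")

    @classmethod
    def default(cls) -> "PairTable":
        return cls()

    @property
    def shift(self) -> np.ndarray:
        """Energy offset per pair: minus the unshifted LJ value at rc."""
        sr6 = (self.sigma / self.rc) ** 6
        return -4.0 * self.epsilon * (sr6 * sr6 - sr6)

    @property
    def max_cutoff(self) -> float:
        return float(self.rc.max())

    def _tables(self):
        return self.epsilon, self.sigma, self.rc**2, self.shift


def fene_energy(r, p: FENEParams = FENEParams()):
    """FENE bond energy at extension r; diverges as r -> R0, error at r >= R0."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= p.R0):
        raise BrokenBondError(f"bond length {float(np.max(r)):.4f} >= R0={p.R0}")
    return -0.5 * p.kappa * p.R0**2 * np.log(1.0 - (r / p.R0) ** 2)


def fene_force(r, p: FENEParams = FENEParams()):
    """Magnitude of the restoring force -dU/dr (positive = pulls inward)."""
    r = np.asarray(r, float)
    if np.any(r >= p.R0):
        raise BrokenBondError(f"bond length {float(np.max(r)):.4f} >= R0={p.R0}")
    return -p.kappa * r / (1.0 - (r / p.R0) ** 2)


def lj_energy(r, pair, table: PairTable | None = None):
    """Truncated-and-shifted LJ energy for a species pair; 0 beyond rc."""
    if table is None:
        table = PairTable.default()
    i = _species_index(pair[0])
    j = _species_index(pair[1])
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    eps = table.epsilon[i, j]
    sig = table.sigma[i, j]
    rc = table.rc[i, j]
    sr6 = (sig / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6) + table.shift[i, j]
    return np.where(r < rc, u, 0.0)


def _as_bond_codes(bonds: np.ndarray, n: int) -> np.ndarray:
    if len(bonds) == 0:
        return np.empty(0, np.int64)
    lo = np.minimum(bonds[:, 0], bonds[:, 1]).astype(np.int64)
    hi = np.maximum(bonds[:, 0], bonds[:, 1]).astype(np.int64)
    return np.sort(lo * n + hi)


def total_energy_forces(
    positions: np.ndarray,
    species: np.ndarray,
    box: np.ndarray,
    bonds: np.ndarray,
    table: PairTable | None = None,
    fene: FENEParams = FENEParams(),
    exclude_bonded_lj: bool = False,
    trap_k: float = 0.0,
    brute_force: bool = False,
):
    """Total potential energy and per-bead forces of a configuration.

    Forces are minus the gradient of the total FENE + shifted-LJ (+ optional
    isotropic harmonic trap about the origin) potential, with the
    minimum-image convention applied to every pair.  By the Kremer–Grest
    convention directly bonded beads also feel the pair LJ term; set
    exclude_bonded_lj=True to drop it.
    """
    positions = np.ascontiguousarray(positions, float)
    species = np.ascontiguousarray(species, np.int8)
    box = np.asarray(box, float)
    bonds = np.ascontiguousarray(bonds, np.int64).reshape(-1, 2)
    if table is None:
        table = PairTable.default()
    eps_t, sig_t, rc2_t, shift_t = table._tables()
    n = positions.shape[0]
    if brute_force:
        pi, pj = kernels.brute_pair_list(positions, species, box, rc2_t)
    else:
        pi, pj = kernels.cell_pair_list(positions, species, box, rc2_t)
    # canonical pair order so cell-list and brute-force paths accumulate
    # in the same sequence (bitwise-identical energies and forces)
    order = np.lexsort((pj, pi))
    pi = np.ascontiguousarray(pi[order])
    pj = np.ascontiguousarray(pj[order])
    forces = np.empty_like(positions)
    energy, status, bad = kernels.compute_forces(
        positions, species, box, pi, pj, bonds,
        _as_bond_codes(bonds, n), exclude_bonded_lj,
        eps_t, sig_t, rc2_t, shift_t, fene.kappa, fene.R0, trap_k, forces,
    )
    if status == kernels.OVERLAP:
        raise OverlapError(f"beads {pi[bad]} and {pj[bad]} overlap (r < 1e-6)")
    if status == kernels.BOND_BROKEN:
        i, j = bonds[bad]
        raise BrokenBondError(f"bond ({i}, {j}) at or beyond R0={fene.R0}")
    return energy, forces


def total_force(positions, species, box, bonds, table=None, fene=FENEParams(),
                **kw) -> np.ndarray:
    """Per-bead force vectors (see total_energy_forces)."""
    return total_energy_forces(positions, species, box, bonds, table, fene, **kw)[1]
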