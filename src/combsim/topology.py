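"""Molecular graph of one Ax-comb-(By)n chain.

The molecule is a hydrophobic linear backbone of x A beads carrying n
hydrophilic side chains of y B beads each, grafted at n distinct backbone
positions chosen uniformly at random (n <= x).  Every bond — backbone,
side chain and graft — is a FENE bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CombTopology:
    x: int
    y: int
    n: int
    graft_sites: tuple[int, ...]
    bonds: np.ndarray = field(repr=False)  # (n_bonds, 2) int64
    species: np.ndarray = field(repr=False)  # (n_beads,) int8, 0=A, 1=B

    @property
    def n_beads(self) -> int:
        return self.x + self.n * self.y

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def backbone_indices(self) -> np.ndarray:
        return np.arange(self.x)

    @property
    def label(self) -> str:
        return f"A{self.x}(B{self.y}){self.n}"


def make_topology(x: int, y: int, n: int, seed: int | None = None) -> CombTopology:
    """Build an Ax-comb-(By)n topology with random graft sites.

    Beads 0..x-1 are the backbone (species A); side chain j contributes y
    B beads appended in order, bonded linearly and grafted to backbone bead
    graft_sites[j].  Deterministic given the seed.
    """
    if x < 1:
        raise ValueError("backbone length x must be >= 1")
    if y < 0 or n < 0:
        raise ValueError("side-chain length y and graft number n must be >= 0")
    if n > x:
        raise ValueError(f"grafting number n={n} exceeds backbone length x={x}")
    if y == 0 and n > 0:
        n = 0  # zero-length side chains carry no beads

    rng = np.random.default_rng(seed)
    sites = tuple(sorted(rng.choice(x, size=n, replace=False).tolist())) if n else ()

    bonds = [(i, i + 1) for i in range(x - 1)]
    species = [0] * x
    nxt = x
    for s in sites:
        prev = s
        for _ in range(y):
            bonds.append((prev, nxt))
            species.append(1)
            prev = nxt
            nxt += 1
    bond_arr = (
        np.asarray(bonds, np.int64).reshape(-1, 2)
        if bonds
        else np.empty((0, 2), np.int64)
    )
    return CombTopology(
        x=x, y=y, n=n, graft_sites=sites,
        bonds=bond_arr, species=np.asarray(species, np.int8),
    )


def replicate(top: CombTopology, n_chains: int):
    """Concatenate n_chains copies of a topology into system-level arrays.

    Returns (species, bonds, chain_id); bead indices of chain c are offset
    by c * top.n_beads.
    """
    nb = top.n_beads
    species = np.tile(top.species, n_chains)
    chain_id = np.repeat(np.arange(n_chains), nb)
    if top.n_bonds:
        offsets = (np.arange(n_chains) * nb)[:, None, None]
        bonds = (top.bonds[None, :, :] + offsets).reshape(-1, 2)
    else:
        bonds = np.empty((0, 2), np.int64)
    return species, bonds, chain_id
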