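"""Pack comb chains into a periodic box and build constructed geometries.

The number of chains at a target bead volume fraction phi follows the
bead-volume convention: each bead occupies a sphere of diameter sigma,
v_bead = pi sigma^3 / 6, so n_chains = floor(phi V / (v_bead beads_per_chain)).
This convention is isolated in chains_at_volume_fraction() so alternatives
are a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .bd import BDParams, SimulationState, step
from .forcefield import FENEParams, PairTable
from .topology import CombTopology, replicate

V_BEAD = np.pi / 6.0  # sigma^3, sphere of diameter sigma
BOND_LENGTH = 0.97  # equilibrium Kremer-Grest bond length, sigma
MIN_SEPARATION = 0.8  # packing post-condition, sigma


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class PackingSpec:
    box: tuple[float, float, float] = (20.0, 20.0, 20.0)
    phi: float = 0.15
    placement_seed: int = 0

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


def chains_at_volume_fraction(spec: PackingSpec, beads_per_chain: int) -> int:
    """floor(phi V / (v_bead * beads_per_chain)) with v_bead = pi/6 sigma^3."""
    return int(np.floor(spec.phi * spec.volume / (V_BEAD * beads_per_chain)))


def _grow_chain(top: CombTopology, rng: np.random.Generator) -> np.ndarray:
    """One chain as a bond-length random walk avoiding intra-chain overlap."""
    nb = top.n_beads
    pos = np.zeros((nb, 3))
    placed = np.zeros(nb, bool)
    placed[0] = True
    # walk the bond list; bonds are ordered so each bond has one placed end
    for attempt_chain in range(200):
        ok = True
        placed[:] = False
        placed[0] = True
        for i, j in top.bonds:
            anchor, new = (i, j) if placed[i] else (j, i)
            for attempt in range(60):
                v = rng.normal(size=3)
                v *= BOND_LENGTH / np.linalg.norm(v)
                cand = pos[anchor] + v
                d = np.linalg.norm(pos[placed] - cand, axis=1)
                if d.min() > 0.85:
                    pos[new] = cand
                    placed[new] = True
                    break
            else:
                ok = False
                break
        if ok:
            return pos - pos.mean(axis=0)
    raise PackingError(f"could not grow a self-avoiding conformation for {top.label}")


def pack_box(
    top: CombTopology,
    spec: PackingSpec = PackingSpec(),
    n_chains: int | None = None,
    table: PairTable | None = None,
    fene: FENEParams = FENEParams(),
    pushoff_steps: int = 3000,
) -> SimulationState:
    """Random dispersion of chains at the target volume fraction.

    Chains are grown as self-avoiding random walks, dropped at random
    positions/orientations, then relaxed by a short zero-temperature
    capped-force push-off so no pair is closer than 0.8 sigma.
    """
    if n_chains is None:
        if spec.phi <= 0:
            raise PackingError("volume fraction phi must be positive")
        n_chains = chains_at_volume_fraction(spec, top.n_beads)
    if n_chains < 1:
        raise PackingError("no chains fit: phi too small for this box/molecule")

    rng = np.random.default_rng(spec.placement_seed)
    box = np.asarray(spec.box, float)
    species, bonds, chain_id = replicate(top, n_chains)
    coords = np.empty((n_chains * top.n_beads, 3))
    for c in range(n_chains):
        chain = _grow_chain(top, rng)
        # random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        chain = chain @ q.T
        chain += rng.uniform(0, 1, 3) * box
        coords[c * top.n_beads : (c + 1) * top.n_beads] = chain

    state = SimulationState(coords, species, box, bonds, chain_id)
    _push_off(state, table, fene, pushoff_steps)
    return state


def _push_off(state, table, fene, n_steps, anneal=False):
    """Zero-noise capped-force descent until the 0.8 sigma floor holds.

    A tiny jitter first breaks exact coincidences (which would otherwise
    carry no repulsive force); with anneal=True a short small-time-step
    thermal stage follows, which relaxes the residual strains of densely
    constructed initial geometries.
    """
    rng = np.random.default_rng(12345)
    state.positions += 0.01 * rng.normal(size=state.positions.shape)
    bd = BDParams(dt=1e-4, xi=0.5, kBT=1.0, seed=0)
    ok = False
    for cap in (20.0, 100.0, 500.0):
        step(state, bd, table, fene, n_steps=n_steps, with_noise=False,
             force_cap=cap)
        if kernels.min_pair_distance(state.positions, state.box) >= MIN_SEPARATION:
            ok = True
            break
    if not ok:
        d = kernels.min_pair_distance(state.positions, state.box)
        if d < MIN_SEPARATION:
            raise PackingError(
                f"push-off failed: minimum pair distance {d:.3f} < "
                f"{MIN_SEPARATION} sigma (phi too high?)"
            )
    if anneal:
        for dt_a, n_a in ((1e-5, 10_000), (2e-5, 20_000), (5e-5, 20_000)):
            gentle = BDParams(dt=dt_a, xi=0.5, kBT=1.0, seed=1,
                              max_force_disp=0.05)
            step(state, gentle, table, fene, n_steps=n_a)


# ---------------------------------------------------------------------------
# Constructed geometries (classifier fixtures and seeded initial conditions)
# ---------------------------------------------------------------------------

def _fib_sphere(n: int) -> np.ndarray:
    """n near-uniform directions (Fibonacci lattice on the unit sphere)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def hollow_sphere(n: int = 600, radius: float = 4.0, jitter: float = 0.05,
                  seed: int = 0) -> np.ndarray:
    """Closed shell of beads — a vesicle membrane stand-in."""
    rng = np.random.default_rng(seed)
    return radius * _fib_sphere(n) + jitter * rng.normal(size=(n, 3))


def spherical_cap(n: int = 600, radius: float = 4.0, opening_deg: float = 70.0,
                  jitter: float = 0.05, seed: int = 0) -> np.ndarray:
    """Open shell (bowl): sphere with a polar cap of half-angle opening_deg removed.

    Returns exactly n beads.
    """
    frac = max(1e-9, (1 + np.cos(np.radians(opening_deg))) / 2)
    m = int(n / frac)
    while True:
        pts = hollow_sphere(m, radius, jitter, seed)
        keep = pts[:, 2] < radius * np.cos(np.radians(opening_deg))
        if keep.sum() >= n:
            kept = pts[keep]
            # subsample evenly — a plain [:n] would shave the far pole off
            idx = np.linspace(0, len(kept) - 1, n).round().astype(int)
            return kept[idx]
        m = int(m * 1.3) + 8


def ring(n: int = 600, major_radius: float = 5.0, tube_radius: float = 1.0,
         seed: int = 0) -> np.ndarray:
    """Torus of beads — a toroidal micelle stand-in."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 2 * np.pi, n)
    v = rng.uniform(0, 2 * np.pi, n)
    rho = major_radius + tube_radius * np.cos(v)
    return np.column_stack([rho * np.cos(u), rho * np.sin(u), tube_radius * np.sin(v)])


def rod(n: int = 600, length: float = 12.0, tube_radius: float = 1.0,
        seed: int = 0) -> np.ndarray:
    """Straight capped tube — a cylindrical micelle stand-in."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-length / 2, length / 2, n)
    r = tube_radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def disk(n: int = 600, radius: float = 6.0, thickness: float = 1.0,
         seed: int = 0) -> np.ndarray:
    """Flat circular platelet — a sheet-like micelle stand-in."""
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-thickness / 2, thickness / 2, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def vesicle_fixture(n_out: int = 700, n_in: int = 250, radius: float = 4.0,
                    shell: float = 0.8, seed: int = 0):
    """(positions, species) of an idealized vesicle: A membrane, B linings.

    Hydrophilic B beads coat both membrane faces so the radial B density
    shows the two-peak signature; the interior within radius - shell is
    solvent cavity (empty).
    """
    rng = np.random.default_rng(seed)
    mem = radius * _fib_sphere(n_out) * (1 + 0.04 * rng.normal(size=(n_out, 1)))
    b_out = (radius + shell) * _fib_sphere(int(n_out * 0.6))
    b_in = (radius - shell) * _fib_sphere(n_in)
    pos = np.vstack([mem, b_out, b_in])
    species = np.concatenate(
        [np.zeros(len(mem), np.int8), np.ones(len(b_out) + len(b_in), np.int8)]
    )
    return pos, species


def sheet_fixture(n_a: int = 700, n_b: int = 670, radius: float = 6.0,
                  thickness: float = 1.0, coat: float = 0.8, seed: int = 0):
    """(positions, species) of an idealized amphiphile sheet.

    Hydrophobic A platelet with hydrophilic B beads coating both faces —
    the same bead budget as vesicle_fixture so timeline tests can morph
    between them frame by frame.
    """
    a = disk(n_a, radius, thickness, seed)
    rng = np.random.default_rng(seed + 1)
    nb2 = n_b // 2
    faces = []
    for sgn, m in ((1.0, nb2), (-1.0, n_b - nb2)):
        r = radius * np.sqrt(rng.uniform(0, 1, m))
        th = rng.uniform(0, 2 * np.pi, m)
        z = sgn * (thickness / 2 + coat) * np.ones(m)
        faces.append(np.column_stack([r * np.cos(th), r * np.sin(th), z]))
    pos = np.vstack([a] + faces)
    species = np.concatenate([np.zeros(n_a, np.int8), np.ones(n_b, np.int8)])
    return pos, species


def bowl_fixture(n_a: int = 700, n_b: int = 670, radius: float = 4.0,
                 opening_deg: float = 70.0, coat: float = 0.8, seed: int = 0):
    """(positions, species) of an idealized open-shell (bowl) micelle."""
    a = spherical_cap(n_a, radius, opening_deg, seed=seed)
    cut = np.cos(np.radians(opening_deg))
    nb2 = n_b // 2
    outer = spherical_cap(nb2, radius + coat, opening_deg, seed=seed + 1)
    inner = spherical_cap(n_b - nb2, radius - coat, opening_deg, seed=seed + 2)
    pos = np.vstack([a[:n_a], outer[:nb2], inner[: n_b - nb2]])
    n_a_real = len(a[:n_a])
    species = np.concatenate(
        [np.zeros(n_a_real, np.int8), np.ones(len(pos) - n_a_real, np.int8)]
    )
    del cut
    return pos, species


def sheet_initial_state(
    top: CombTopology,
    n_chains: int,
    box: tuple[float, float, float],
    thickness: float = 3.5,
    packing_fraction: float = 0.4,
    seed: int = 0,
) -> SimulationState:
    """Preformed flat aggregate (sheet-like micelle) for closure studies.

    Chains are random coils whose centres fill a thin disk at the box
    centre; a short push-off removes overlaps.  The amphiphiles then
    self-organize the disk into a membrane patch within a few 1e4 steps,
    after which rim tension drives the sheet -> bowl -> vesicle closure
    pathway without prescribing it.
    """
    rng = np.random.default_rng(seed)
    species, bonds, chain_id = replicate(top, n_chains)
    vol = n_chains * top.n_beads * V_BEAD / packing_fraction
    disk_r = np.sqrt(vol / (np.pi * thickness))
    boxv = np.asarray(box, float)
    if 2 * disk_r > min(boxv[0], boxv[1]) - 2.0:
        raise PackingError(
            f"sheet of radius {disk_r:.1f} does not fit the box {box}"
        )
    coords = np.empty((n_chains * top.n_beads, 3))
    for c in range(n_chains):
        chain = _grow_chain(top, rng)
        chain[:, 2] *= 0.5  # pre-flatten the coil toward the slab plane
        r = disk_r * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        centre = np.array([
            r * np.cos(th), r * np.sin(th),
            rng.uniform(-0.3, 0.3) * thickness / 2,
        ])
        coords[c * top.n_beads:(c + 1) * top.n_beads] = chain + centre
    coords += boxv / 2
    state = SimulationState(coords, species, boxv, bonds, chain_id)
    _push_off(state, None, FENEParams(), 4000, anneal=True)
    return state


def vesicle_initial_state(
    top: CombTopology,
    n_chains: int,
    box: tuple[float, float, float],
    thickness: float = 3.0,
    packing_fraction: float = 0.45,
    seed: int = 0,
) -> SimulationState:
    """Pre-assembled hollow shell of comb chains, for seeded relaxation runs.

    Backbone coils fill a spherical shell whose mid-radius is set by the
    bead budget (so different molecules at equal total bead count give
    equal-sized shells); each hydrophilic side-chain bead is re-placed
    radially toward the nearer membrane face, which shortcuts the slow
    B-bead migration so a brief BD relaxation yields an organized
    membrane (A core, B linings inside and out).
    """
    rng = np.random.default_rng(seed)
    species, bonds, chain_id = replicate(top, n_chains)
    vol = n_chains * top.n_beads * V_BEAD / packing_fraction
    radius = np.sqrt(vol / (4 * np.pi * thickness))
    boxv = np.asarray(box, float)
    if 2 * (radius + thickness / 2 + 2.0) > min(boxv):
        raise PackingError(
            f"shell of radius {radius:.1f} does not fit the box {box}"
        )
    coords = np.empty((n_chains * top.n_beads, 3))
    dirs = _fib_sphere(n_chains)
    for c in range(n_chains):
        chain = _grow_chain(top, rng)
        r_mid = radius + thickness * rng.uniform(-0.2, 0.2)
        chain = chain + r_mid * dirs[c]
        # point each side chain at the nearer solvent face
        nxt = top.x
        for s in top.graft_sites:
            base = chain[s]
            rb = np.linalg.norm(base)
            u = base / max(rb, 1e-9)
            sgn = 1.0 if rb >= radius else -1.0
            for k in range(top.y):
                chain[nxt] = base + sgn * (k + 1) * BOND_LENGTH * u
                nxt += 1
        coords[c * top.n_beads:(c + 1) * top.n_beads] = chain
    coords += boxv / 2.0
    state = SimulationState(coords, species, boxv, bonds, chain_id)
    _push_off(state, None, FENEParams(), 4000, anneal=True)
    return state
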