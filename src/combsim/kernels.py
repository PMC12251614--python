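"""Numba kernels: neighbour lists, pair forces and the Euler–Maruyama loop.

Everything here is plain-array plumbing.  Positions passed to these kernels
are *unwrapped*; the minimum-image convention is applied to every pair
distance, so coordinates may drift outside the primary box without harm.
All kernels are single-threaded and deterministic; Gaussian noise is
pre-generated by the caller (numpy Generator) so the stochastic stream is
independent of kernel internals.

The Verlet pair list is species-aware: each species pair is recorded only
within its own interaction cutoff plus skin (hydrophobic A-A pairs reach
2.5 sigma, everything else only the WCA core), which roughly halves the
pair count of a comb-copolymer system.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integrator / force kernel
OK = 0
BOND_BROKEN = 1
OVERLAP = 2


@njit(cache=True)
def wrap_positions(pos, box):
    """Coordinates folded into [0, box) per dimension (new array)."""
    n = pos.shape[0]
    out = np.empty_like(pos)
    for i in range(n):
        for k in range(3):
            out[i, k] = pos[i, k] - box[k] * np.floor(pos[i, k] / box[k])
            if out[i, k] >= box[k]:  # guard against round-up at the edge
                out[i, k] -= box[k]
    return out


@njit(cache=True, fastmath=True)
def brute_pair_list(pos, species, box, lc2_t):
    """All pairs with minimum-image distance^2 < lc2_t[si, sj], O(N^2)."""
    n = pos.shape[0]
    ibox = 1.0 / box
    cap = max(64, 8 * n)
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            d2 = 0.0
            for k in range(3):
                d = pos[i, k] - pos[j, k]
                d -= box[k] * np.rint(d * ibox[k])
                d2 += d * d
            if d2 < lc2_t[species[i], species[j]]:
                if m >= cap:
                    cap *= 2
                    qi = np.empty(cap, np.int64)
                    qj = np.empty(cap, np.int64)
                    qi[:m] = pi[:m]
                    qj[:m] = pj[:m]
                    pi = qi
                    pj = qj
                pi[m] = i
                pj[m] = j
                m += 1
    return pi[:m].copy(), pj[:m].copy()


@njit(cache=True, fastmath=True)
def cell_pair_list(pos, species, box, lc2_t):
    """Same contract as brute_pair_list via cell binning.

    Cells are sized near half the largest listed cutoff (reach-2
    neighbourhood, corner cells pruned by distance) which substantially
    reduces distance checks versus cutoff-sized cells.  Falls back to the
    brute path when the box is too small for an unambiguous half-shell
    iteration.
    """
    n = pos.shape[0]
    cutoff = np.sqrt(np.max(lc2_t))
    # prefer reach-2 (finer cells); drop to reach-1 or brute for small boxes
    reach = 2
    ncx = int(box[0] * reach / cutoff)
    ncy = int(box[1] * reach / cutoff)
    ncz = int(box[2] * reach / cutoff)
    if min(ncx, min(ncy, ncz)) < 2 * reach + 1:
        reach = 1
        ncx = int(box[0] / cutoff)
        ncy = int(box[1] / cutoff)
        ncz = int(box[2] / cutoff)
    if min(ncx, min(ncy, ncz)) < 2 * reach + 1 or n < 32:
        return brute_pair_list(pos, species, box, lc2_t)
    w = wrap_positions(pos, box)
    bx = box[0]
    by = box[1]
    bz = box[2]
    hx = 0.5 * bx
    hy = 0.5 * by
    hz = 0.5 * bz
    sx = bx / ncx
    sy = by / ncy
    sz = bz / ncz
    ncells = ncx * ncy * ncz
    cell_of = np.empty(n, np.int64)
    count = np.zeros(ncells + 1, np.int64)
    for i in range(n):
        cx = int(w[i, 0] / sx)
        cy = int(w[i, 1] / sy)
        cz = int(w[i, 2] / sz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count.copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # half-shell offsets within reach, pruned when the nearest corner of the
    # offset cell is already beyond the cutoff
    noffs = 0
    offs = np.empty(((2 * reach + 1) ** 3 // 2 + 1, 3), np.int64)
    c2 = cutoff * cutoff
    for ox in range(-reach, reach + 1):
        for oy in range(-reach, reach + 1):
            for oz in range(-reach, reach + 1):
                if oz < 0 or (oz == 0 and oy < 0) or (oz == 0 and oy == 0 and ox < 0):
                    continue
                dmx = max(abs(ox) - 1, 0) * sx
                dmy = max(abs(oy) - 1, 0) * sy
                dmz = max(abs(oz) - 1, 0) * sz
                if dmx * dmx + dmy * dmy + dmz * dmz > c2:
                    continue
                offs[noffs, 0] = ox
                offs[noffs, 1] = oy
                offs[noffs, 2] = oz
                noffs += 1

    cap = max(64, int(n * 30))
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    m = 0
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                if count[c + 1] == count[c]:
                    continue
                for dn in range(noffs):
                    nx = (cx + offs[dn, 0]) % ncx
                    ny = (cy + offs[dn, 1]) % ncy
                    nz = (cz + offs[dn, 2]) % ncz
                    cn = (nx * ncy + ny) * ncz + nz
                    for a in range(count[c], count[c + 1]):
                        i = order[a]
                        wx = w[i, 0]
                        wy = w[i, 1]
                        wz = w[i, 2]
                        si = species[i]
                        b0 = count[cn]
                        if cn == c:
                            b0 = a + 1
                        for b in range(b0, count[cn + 1]):
                            j = order[b]
                            dx = wx - w[j, 0]
                            dy = wy - w[j, 1]
                            dz = wz - w[j, 2]
                            if dx > hx:
                                dx -= bx
                            elif dx < -hx:
                                dx += bx
                            if dy > hy:
                                dy -= by
                            elif dy < -hy:
                                dy += by
                            if dz > hz:
                                dz -= bz
                            elif dz < -hz:
                                dz += bz
                            d2 = dx * dx + dy * dy + dz * dz
                            if d2 < lc2_t[si, species[j]]:
                                if m >= cap:
                                    cap *= 2
                                    qi = np.empty(cap, np.int64)
                                    qj = np.empty(cap, np.int64)
                                    qi[:m] = pi[:m]
                                    qj[:m] = pj[:m]
                                    pi = qi
                                    pj = qj
                                if i < j:
                                    pi[m] = i
                                    pj[m] = j
                                else:
                                    pi[m] = j
                                    pj[m] = i
                                m += 1
    return pi[:m].copy(), pj[:m].copy()


@njit(cache=True)
def pair_list_uniform(pos, box, cutoff):
    """Species-blind pair list at a single cutoff (analysis helper)."""
    species = np.zeros(pos.shape[0], np.int8)
    lc2 = np.full((2, 2), cutoff * cutoff)
    return cell_pair_list(pos, species, box, lc2)


@njit(cache=True)
def _bond_code(i, j, n):
    if i > j:
        i, j = j, i
    return i * n + j


@njit(cache=True)
def _in_sorted(codes, code):
    lo = 0
    hi = codes.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if codes[mid] < code:
            lo = mid + 1
        else:
            hi = mid
    return lo < codes.shape[0] and codes[lo] == code


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    species,
    box,
    pi,
    pj,
    bonds,
    bond_codes,
    exclude_bonded_lj,
    eps_t,
    sig_t,
    rc2_t,
    shift_t,
    kappa,
    r0,
    trap_k,
    forces,
):
    """Total force (written into *forces*) and potential energy.

    Returns (energy, status, bad_index).  status OVERLAP flags a pair below
    the 1e-6 sigma floor, BOND_BROKEN a FENE bond at or past R0; bad_index
    points into the pair/bond list so the caller can name the culprit.
    """
    n = pos.shape[0]
    nb = bonds.shape[0]
    for i in range(n):
        for k in range(3):
            forces[i, k] = 0.0
    energy = 0.0
    status = OK
    bad = -1
    bx = box[0]
    by = box[1]
    bz = box[2]
    ibx = 1.0 / bx
    iby = 1.0 / by
    ibz = 1.0 / bz

    for a in range(pi.shape[0]):
        i = pi[a]
        j = pj[a]
        si = species[i]
        sj = species[j]
        rc2 = rc2_t[si, sj]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= rc2:
            continue
        if exclude_bonded_lj and _in_sorted(bond_codes, _bond_code(i, j, n)):
            continue
        if d2 < 1e-12:
            status = OVERLAP
            bad = a
            continue
        eps = eps_t[si, sj]
        sig = sig_t[si, sj]
        s2 = sig * sig / d2
        s6 = s2 * s2 * s2
        s12 = s6 * s6
        energy += 4.0 * eps * (s12 - s6) + shift_t[si, sj]
        f = 24.0 * eps * (2.0 * s12 - s6) / d2
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    r02 = r0 * r0
    for b in range(nb):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= bx * np.rint(dx * ibx)
        dy -= by * np.rint(dy * iby)
        dz -= bz * np.rint(dz * ibz)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= r02:
            status = BOND_BROKEN
            bad = b
            continue
        energy += -0.5 * kappa * r02 * np.log(1.0 - d2 / r02)
        f = -kappa / (1.0 - d2 / r02)
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz

    if trap_k > 0.0:
        for i in range(n):
            for k in range(3):
                energy += 0.5 * trap_k * pos[i, k] * pos[i, k]
                forces[i, k] -= trap_k * pos[i, k]
    return energy, status, bad


@njit(cache=True, fastmath=True)
def integrate(
    pos,
    species,
    box,
    bonds,
    bond_codes,
    exclude_bonded_lj,
    eps_t,
    sig_t,
    rc2_t,
    shift_t,
    kappa,
    r0,
    dt,
    xi,
    noise,
    skin,
    trap_k,
    force_cap,
    max_force_disp,
):
    """Euler–Maruyama propagation over noise.shape[0] steps.

    Displacement per bead per step: (dt/xi) * F  +  noise[step, bead, :],
    where the caller has already scaled the Gaussian draws by
    sqrt(2 kBT dt / xi) (fluctuation-dissipation).  A zero-length noise
    array with explicit n_steps is not supported — deterministic descent
    passes an all-zero array.  The species-aware Verlet list (cutoff + skin)
    is rebuilt whenever any bead moved more than skin/2 since the last
    build.  force_cap (if finite) truncates the per-bead net force
    magnitude — used only for packing push-off.  max_force_disp clamps the
    *deterministic* displacement of a bead in one step; the explicit Euler
    scheme is only marginally stable against the steep LJ core, and rare
    many-body squeezes (order one event per 1e8 bead-steps at the default
    time step) otherwise launch an overshoot cascade that snaps a FENE
    bond.  The clamp is ~5 sigma above typical displacements, so it leaves
    equilibrium statistics untouched; clamp events are counted.

    Returns (status, step_of_failure, bad_index, n_clamped).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    lc2 = (np.sqrt(rc2_t) + skin) ** 2
    pi, pj = cell_pair_list(pos, species, box, lc2)
    ref = pos.copy()
    forces = np.empty((n, 3))
    mob = dt / xi
    half_skin2 = 0.25 * skin * skin
    ibox = 1.0 / box
    capped = np.isfinite(force_cap)
    fclamp = max_force_disp / mob  # clamp expressed in force units
    n_clamped = 0

    for s in range(n_steps):
        mx = 0.0
        for i in range(n):
            d2 = 0.0
            for k in range(3):
                d = pos[i, k] - ref[i, k]
                d2 += d * d
            if d2 > mx:
                mx = d2
        if mx > half_skin2:
            pi, pj = cell_pair_list(pos, species, box, lc2)
            ref = pos.copy()

        _, status, bad = compute_forces(
            pos, species, box, pi, pj, bonds, bond_codes, exclude_bonded_lj,
            eps_t, sig_t, rc2_t, shift_t, kappa, r0, trap_k, forces,
        )
        if status == BOND_BROKEN:
            return status, s, bad, n_clamped

        if capped:
            for i in range(n):
                fm = np.sqrt(
                    forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
                )
                if fm > force_cap:
                    sc = force_cap / fm
                    forces[i, 0] *= sc
                    forces[i, 1] *= sc
                    forces[i, 2] *= sc

        for i in range(n):
            fm2 = (
                forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
            )
            if fm2 > fclamp * fclamp:
                sc = fclamp / np.sqrt(fm2)
                forces[i, 0] *= sc
                forces[i, 1] *= sc
                forces[i, 2] *= sc
                n_clamped += 1
            pos[i, 0] += mob * forces[i, 0] + noise[s, i, 0]
            pos[i, 1] += mob * forces[i, 1] + noise[s, i, 1]
            pos[i, 2] += mob * forces[i, 2] + noise[s, i, 2]

    # bond sanity after the final move (mid-chunk breakage is caught by the
    # FENE term of compute_forces on the following step)
    r02 = r0 * r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d2 = 0.0
        for k in range(3):
            d = pos[i, k] - pos[j, k]
            d -= box[k] * np.rint(d * ibox[k])
            d2 += d * d
        if d2 >= r02:
            return BOND_BROKEN, n_steps - 1, b, n_clamped
    return OK, n_steps, -1, n_clamped


@njit(cache=True, fastmath=True)
def min_pair_distance(pos, box):
    n = pos.shape[0]
    best = 1e300
    ibox = 1.0 / box
    for i in range(n):
        for j in range(i + 1, n):
            d2 = 0.0
            for k in range(3):
                d = pos[i, k] - pos[j, k]
                d -= box[k] * np.rint(d * ibox[k])
                d2 += d * d
            if d2 < best:
                best = d2
    return np.sqrt(best)
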