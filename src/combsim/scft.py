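"""Self-consistent field theory for the comb copolymer / short-solvent blend.

Mean-field Gaussian-chain theory of an incompressible melt of AB comb
copolymers blended with short A-homopolymer solvent.  In reduced SCFT
units (lengths in a sqrt(N/6), contour in units of N segments) the chain
propagator obeys the modified diffusion equation

    dq/ds = lap(q) - omega(r) q ,      q(r, 0) = 1,

solved per block by symmetric operator splitting
exp(-w ds/2) . exp(ds lap) . exp(-w ds/2); the diffusion substep is exact
in Fourier space on periodic Cartesian grids and Crank-Nicolson on the
symmetry-reduced grids (planar slab, cylindrical/spherical radial,
axisymmetric r-z).  Because the discrete one-step operator is self-adjoint
in the cell-volume inner product, the single-chain partition function
Q = <q(s) qdag(S-s)> is independent of the contour split point to
round-off — a strong internal consistency check.

Free energy per chain volume (units of rho0 V kBT / N):

    F = -(phi/alpha) ln(Qc/phi) - ((1-phi)/gamma) ln(Qh/(1-phi))
        + < chiN phiA phiB - wA phiA - wB phiB - eta (1 - phiA - phiB) >

where alpha is the copolymer contour length in units of N (alpha = 1 for
the reference AB2 star), gamma the solvent length (0.2), and eta the
incompressibility pressure field.  The repeat unit A1-comb-(B1)1 maps to
an AB2 star with fA = 0.5; a general Ax-comb-(By)n maps 1 bead -> 0.5 N
segments, i.e. backbone 0.5x, side chains 0.5y, alpha = 0.5 (x + n y).
The solvent is short A homopolymer, so solvent density joins phiA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

A, B = 0, 1


# ---------------------------------------------------------------------------
# batched Thomas solver (precomputed factorization)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _thomas_factor(a, b, c):
    n = b.shape[0]
    cp = np.empty(n)
    den = np.empty(n)
    den[0] = b[0]
    cp[0] = c[0] / b[0]
    for i in range(1, n):
        den[i] = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / den[i]
    return cp, den


@njit(cache=True)
def _thomas_solve(a, cp, den, rhs, out):
    # rhs, out: (n, m) solved along axis 0 for every column
    n, m = rhs.shape
    for j in range(m):
        out[0, j] = rhs[0, j] / den[0]
    for i in range(1, n):
        for j in range(m):
            out[i, j] = (rhs[i, j] - a[i] * out[i - 1, j]) / den[i]
    for i in range(n - 2, -1, -1):
        for j in range(m):
            out[i, j] -= cp[i] * out[i + 1, j]
    return out


class _CNDiffusion:
    """Crank-Nicolson step for a tridiagonal Laplacian (finite volume)."""

    def __init__(self, lap_sub, lap_diag, lap_sup, ds):
        n = len(lap_diag)
        h = 0.5 * ds
        # M = I - h L, N = I + h L
        self.m_a = -h * lap_sub
        self.n_a = h * lap_sub
        self.n_b = 1.0 + h * lap_diag
        self.n_c = h * lap_sup
        m_b = 1.0 - h * lap_diag
        m_c = -h * lap_sup
        self.cp, self.den = _thomas_factor(self.m_a, m_b, m_c)
        self.n = n

    def apply(self, q):
        # q: (n, m); returns M^{-1} N q
        rhs = self.n_b[:, None] * q
        rhs[:-1] += self.n_c[:-1, None] * q[1:]
        rhs[1:] += self.n_a[1:, None] * q[:-1]
        out = np.empty_like(rhs)
        return _thomas_solve(self.m_a, self.cp, self.den, rhs, out)


def _fv_laplacian(faces_area, cell_vol, h):
    """Tridiagonal finite-volume Laplacian with zero-flux boundaries.

    faces_area: area of the n+1 faces; cell_vol: volume of the n cells.
    Self-adjoint in the cell-volume inner product.
    """
    n = len(cell_vol)
    sub = np.zeros(n)
    diag = np.zeros(n)
    sup = np.zeros(n)
    for i in range(n):
        a_lo = faces_area[i] if i > 0 else 0.0
        a_hi = faces_area[i + 1] if i < n - 1 else 0.0
        sub[i] = a_lo / (h * cell_vol[i])
        sup[i] = a_hi / (h * cell_vol[i])
        diag[i] = -(a_lo + a_hi) / (h * cell_vol[i])
    return sub, diag, sup


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

class Grid:
    """Interface: shape, weights (cell volumes), average(), stepper(ds)."""

    shape: tuple
    weights: np.ndarray

    def average(self, f):
        return float(np.sum(self.weights * f) / np.sum(self.weights))

    def stepper(self, ds):
        raise NotImplementedError


class _SymmetricSplitStepper:
    """exp(-w ds/2) diffuse(ds) exp(-w ds/2) with cached diffusion."""

    def __init__(self, diffuse, ds):
        self._diffuse = diffuse
        self.ds = ds

    def step(self, q, half_boltz):
        return self._diffuse(half_boltz * q) * half_boltz


class CartesianGrid(Grid):
    """Periodic Cartesian grid, exact spectral diffusion (any dimension)."""

    def __init__(self, lengths, shape):
        self.lengths = tuple(float(x) for x in np.atleast_1d(lengths))
        self.shape = tuple(int(s) for s in np.atleast_1d(shape))
        if len(self.lengths) != len(self.shape):
            raise ValueError("lengths and shape must have the same dimension")
        self.weights = np.full(self.shape, np.prod(
            [L / n for L, n in zip(self.lengths, self.shape)]
        ))
        k2 = np.zeros(self.shape)
        for ax, (L, n) in enumerate(zip(self.lengths, self.shape)):
            k = 2 * np.pi * np.fft.fftfreq(n, d=L / n)
            sh = [1] * len(self.shape)
            sh[ax] = n
            k2 = k2 + (k.reshape(sh)) ** 2
        self._k2 = k2

    @property
    def coords(self):
        axes = [
            (np.arange(n) + 0.5) * (L / n)
            for L, n in zip(self.lengths, self.shape)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def stepper(self, ds):
        decay = np.exp(-self._k2 * ds)

        def diffuse(q):
            return np.real(np.fft.ifftn(np.fft.fftn(q) * decay))

        return _SymmetricSplitStepper(diffuse, ds)


class PlanarGrid(Grid):
    """1D slab with zero-flux walls (lamellar / sheet geometry)."""

    def __init__(self, length, n):
        self.length = float(length)
        self.shape = (int(n),)
        h = self.length / n
        self.h = h
        self.r = (np.arange(n) + 0.5) * h
        self.weights = np.full(n, h)
        self._lap = _fv_laplacian(np.ones(n + 1), self.weights, h)

    @property
    def coords(self):
        return self.r

    def stepper(self, ds):
        cn = _CNDiffusion(*self._lap, ds)

        def diffuse(q):
            return cn.apply(q.reshape(-1, 1)).reshape(q.shape)

        return _SymmetricSplitStepper(diffuse, ds)


class RadialGrid(Grid):
    """1D radial grid, dim=3 spherical or dim=2 cylindrical, zero-flux."""

    def __init__(self, radius, n, dim=3):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 (cylindrical) or 3 (spherical)")
        self.radius = float(radius)
        self.dim = dim
        self.shape = (int(n),)
        h = self.radius / n
        self.h = h
        faces = np.arange(n + 1) * h
        self.r = (np.arange(n) + 0.5) * h
        if dim == 3:
            area = faces**2
            vol = (faces[1:] ** 3 - faces[:-1] ** 3) / 3.0
        else:
            area = faces.copy()
            vol = (faces[1:] ** 2 - faces[:-1] ** 2) / 2.0
        self.weights = vol
        self._lap = _fv_laplacian(area, vol, h)

    @property
    def coords(self):
        return self.r

    def stepper(self, ds):
        cn = _CNDiffusion(*self._lap, ds)

        def diffuse(q):
            return cn.apply(q.reshape(-1, 1)).reshape(q.shape)

        return _SymmetricSplitStepper(diffuse, ds)


class AxisymmetricGrid(Grid):
    """2D (r, z) grid with cylindrical radial Laplacian, zero-flux walls.

    Represents axially symmetric structures (toroid, bowl, finite
    cylinder); the azimuthal direction is integrated out.
    """

    def __init__(self, radius, height, nr, nz):
        self.radius = float(radius)
        self.height = float(height)
        self.shape = (int(nr), int(nz))
        hr = self.radius / nr
        hz = self.height / nz
        self.hr, self.hz = hr, hz
        faces = np.arange(nr + 1) * hr
        self.r = (np.arange(nr) + 0.5) * hr
        self.z = (np.arange(nz) + 0.5) * hz
        vol_r = (faces[1:] ** 2 - faces[:-1] ** 2) / 2.0
        self.weights = np.outer(vol_r, np.full(nz, hz))
        self._lap_r = _fv_laplacian(faces, vol_r, hr)
        self._lap_z = _fv_laplacian(np.ones(nz + 1), np.full(nz, hz), hz)

    @property
    def coords(self):
        return np.meshgrid(self.r, self.z, indexing="ij")

    def stepper(self, ds):
        # Strang within diffusion: r half, z full, r half -> self-adjoint
        cn_r = _CNDiffusion(*self._lap_r, 0.5 * ds)
        cn_z = _CNDiffusion(*self._lap_z, ds)

        def diffuse(q):
            q = cn_r.apply(q)
            q = cn_z.apply(np.ascontiguousarray(q.T)).T
            return cn_r.apply(np.ascontiguousarray(q))

        return _SymmetricSplitStepper(diffuse, ds)


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StarArchitecture:
    """Star of arms joined at one junction: [(species, length), ...].

    The reference blend model is the AB2 star with fA = 0.5:
    arms [(A, 0.5), (B, 0.25), (B, 0.25)], total length alpha = 1.
    """

    arms: tuple = ((A, 0.5), (B, 0.25), (B, 0.25))

    @property
    def alpha(self):
        return sum(l for _, l in self.arms)

    @property
    def f_a(self):
        return sum(l for sp, l in self.arms if sp == A) / self.alpha

    def describe(self):
        return "star:" + "+".join(
            f"{'AB'[sp]}{l:g}" for sp, l in self.arms
        )


@dataclass(frozen=True)
class CombArchitecture:
    """Ax-comb-(By)n at the bead -> 0.5 N segment mapping.

    Backbone contour 0.5x (species A) with n grafted B side chains of
    contour 0.5y each, evenly spaced along the backbone interior.
    """

    x: int = 8
    y: int = 1
    n: int = 2

    @property
    def backbone(self):
        return 0.5 * self.x

    @property
    def side(self):
        return 0.5 * self.y

    @property
    def alpha(self):
        return 0.5 * (self.x + self.n * self.y)

    @property
    def f_a(self):
        return self.backbone / self.alpha

    def graft_fractions(self):
        """Graft positions as fractions of the backbone contour."""
        return [(g + 1) / (self.n + 1) for g in range(self.n)]

    def describe(self):
        return f"comb:A{self.x}(B{self.y}){self.n}"


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SCFTParams:
    """chiN=15, solvent length gamma=0.2 and fA=0.5 follow the blend model;
    phi is the overall copolymer volume fraction (the BD-matching 0.15 is
    the default; the inverted solvent-minority preset uses 0.85)."""

    chiN: float = 15.0
    phi: float = 0.15
    gamma: float = 0.2
    ds: float = 0.0125
    architecture: StarArchitecture | CombArchitecture = StarArchitecture()
    mix: float = 0.1
    zeta: float = 10.0  # incompressibility penalty strength in the eta update
    tol: float = 1e-6
    incomp_tol: float = 1e-4
    max_iter: int = 20000
    mix_max: float = 0.5  # bold-driver cap for the adaptive mixing rate
    anderson_depth: int = 0  # >0 enables (experimental) Anderson acceleration
    anderson_start: int = 40  # simple-mixing iterations before acceleration
    anderson_beta: float = 0.5

    def __post_init__(self):
        if not (0 < self.phi < 1):
            raise ValueError("phi must lie in (0, 1)")
        if self.gamma <= 0 or self.ds <= 0 or self.chiN < 0:
            raise ValueError("gamma, ds must be positive; chiN >= 0")


@dataclass
class SCFTState:
    params: SCFTParams
    grid: Grid
    w: np.ndarray  # (2, *grid.shape) fields for A and B
    phi_a: np.ndarray
    phi_b: np.ndarray
    eta: np.ndarray
    q_c: float
    q_h: float
    free_energy: float
    residual: float
    incompressibility: float
    iterations: int
    converged: bool
    seed_name: str = ""
    history: list = field(default_factory=list)


class SCFTConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _nsteps(length, ds):
    n = int(round(length / ds))
    if n < 1 or abs(n * ds - length) > 1e-9:
        raise ValueError(
            f"contour step ds={ds} does not divide block length {length}"
        )
    return n


def _propagate_block(q0, nsteps, stepper, half_boltz, store=False):
    """Propagate q0 through nsteps contour steps; optionally keep all nodes."""
    qs = [q0] if store else None
    q = q0
    for _ in range(nsteps):
        q = stepper.step(q, half_boltz)
        if store:
            qs.append(q)
    return (q, qs) if store else (q, None)


def _simpson_weights(n_nodes):
    """Composite Simpson weights on n_nodes = odd count; falls back to
    trapezoid correction when the interval count is odd."""
    n = n_nodes - 1  # intervals
    w = np.zeros(n_nodes)
    if n == 0:
        return w
    if n % 2 == 0:
        w[0] = w[-1] = 1.0
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        w /= 3.0
    else:
        # Simpson on the first n-1 intervals + trapezoid on the last
        w[: n_nodes - 1] = _simpson_weights(n_nodes - 1) if n > 1 else 0
        w[-2] += 0.5
        w[-1] += 0.5
    return w


def solve_chains(grid: Grid, w: np.ndarray, params: SCFTParams):
    """Propagators, partition functions and unnormalized densities.

    Returns (q_c, q_h, rho_a, rho_b, rho_s) where rho are the contour
    integrals of q qdag per species for the copolymer and the solvent,
    normalized such that phiK = (phi/(alpha q_c)) rhoK etc.
    """
    ds = params.ds
    arch = params.architecture
    half = [np.exp(-0.5 * ds * w[A]), np.exp(-0.5 * ds * w[B])]
    stepper = grid.stepper(ds)
    one = np.ones(grid.shape)

    if isinstance(arch, StarArchitecture):
        arms = list(arch.arms)
        ns = [_nsteps(l, ds) for _, l in arms]
        fwd = []
        for (sp, _), n in zip(arms, ns):
            _, qs = _propagate_block(one, n, stepper, half[sp], store=True)
            fwd.append(qs)
        ends = [qs[-1] for qs in fwd]
        q_c = grid.average(np.prod(ends, axis=0))
        rho = [np.zeros(grid.shape), np.zeros(grid.shape)]
        for a, ((sp, _), n) in enumerate(zip(arms, ns)):
            # complement: product of the other arms' ends, walked outward
            comp0 = one
            for b_ in range(len(arms)):
                if b_ != a:
                    comp0 = comp0 * ends[b_]
            _, comp = _propagate_block(comp0, n, stepper, half[sp], store=True)
            sw = _simpson_weights(n + 1)
            acc = np.zeros(grid.shape)
            for k in range(n + 1):
                acc += sw[k] * fwd[a][k] * comp[n - k]
            rho[sp] += acc * ds
    elif isinstance(arch, CombArchitecture):
        n_bb = _nsteps(arch.backbone, ds)
        n_sc = _nsteps(arch.side, ds) if arch.n else 0
        graft_nodes = sorted(
            min(n_bb - 1, max(1, int(round(f * n_bb))))
            for f in arch.graft_fractions()
        )
        if len(set(graft_nodes)) != len(graft_nodes):
            raise ValueError("graft sites collide on the contour grid; refine ds")
        # side-arm propagator from its free end
        h_side = one
        side_fwd = None
        if arch.n and n_sc:
            h_side, side_fwd = _propagate_block(
                one, n_sc, stepper, half[B], store=True
            )
        gset = set(graft_nodes)
        # backbone propagators from both ends, multiplying in side arms
        def walk(include_graft_at_node):
            qs = [one]
            q = one
            for k in range(1, n_bb + 1):
                q = stepper.step(q, half[A])
                node = include_graft_at_node(k)
                if node in gset:
                    q = q * h_side
                qs.append(q)
            return qs
        qf = walk(lambda k: k)           # forward: nodes 0..n_bb
        qb = walk(lambda k: n_bb - k)    # backward walker at node n_bb - k
        q_c = grid.average(qf[-1])
        rho = [np.zeros(grid.shape), np.zeros(grid.shape)]
        sw = _simpson_weights(n_bb + 1)
        acc = np.zeros(grid.shape)
        for k in range(n_bb + 1):
            wgt = qf[k] * qb[n_bb - k]
            if k in gset:
                # both walkers already include this graft's side arm; strip one
                wgt = wgt / np.maximum(h_side, 1e-300)
            acc += sw[k] * wgt
        rho[A] += acc * ds
        if arch.n and n_sc:
            sw_s = _simpson_weights(n_sc + 1)
            for g in graft_nodes:
                # both walkers carry this graft's side-arm factor; the side
                # chain's complement excludes the side chain itself entirely
                comp0 = qf[g] * qb[n_bb - g] / np.maximum(h_side, 1e-300) ** 2
                _, comp = _propagate_block(comp0, n_sc, stepper, half[B], store=True)
                acc = np.zeros(grid.shape)
                for k in range(n_sc + 1):
                    acc += sw_s[k] * side_fwd[k] * comp[n_sc - k]
                rho[B] += acc * ds
    else:
        raise TypeError(f"unknown architecture {arch!r}")

    # solvent: A homopolymer of length gamma
    n_h = _nsteps(params.gamma, ds)
    _, hs = _propagate_block(one, n_h, stepper, half[A], store=True)
    q_h = grid.average(hs[-1])
    sw = _simpson_weights(n_h + 1)
    rho_s = np.zeros(grid.shape)
    for k in range(n_h + 1):
        rho_s += sw[k] * hs[k] * hs[n_h - k]
    rho_s *= ds
    return q_c, q_h, rho[A], rho[B], rho_s


def densities(grid, w, params):
    """Normalized (phi_a, phi_b, q_c, q_h); phi_a includes the solvent."""
    q_c, q_h, rho_a, rho_b, rho_s = solve_chains(grid, w, params)
    arch = params.architecture
    phi_a_c = params.phi / (arch.alpha * q_c) * rho_a
    phi_b = params.phi / (arch.alpha * q_c) * rho_b
    phi_s = (1 - params.phi) / (params.gamma * q_h) * rho_s
    return phi_a_c + phi_s, phi_b, q_c, q_h


def free_energy(grid, w, phi_a, phi_b, eta, q_c, q_h, params) -> float:
    p = params
    arch = p.architecture
    mix_term = grid.average(
        p.chiN * phi_a * phi_b
        - w[A] * phi_a
        - w[B] * phi_b
        - eta * (1.0 - phi_a - phi_b)
    )
    return (
        -(p.phi / arch.alpha) * np.log(q_c / p.phi)
        - ((1 - p.phi) / p.gamma) * np.log(q_h / (1 - p.phi))
        + mix_term
    )


def homogeneous_free_energy(params: SCFTParams) -> float:
    """Closed form for the spatially uniform (disordered) state."""
    p = params
    fa = p.architecture.f_a
    phi_a = 1 - p.phi * (1 - fa)
    phi_b = p.phi * (1 - fa)
    return (
        p.phi * np.log(p.phi) / p.architecture.alpha * 1.0
        + (1 - p.phi) / p.gamma * np.log(1 - p.phi)
        + p.chiN * phi_a * phi_b
    )


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def seed_fields(grid: Grid, params: SCFTParams, name: str,
                center: float | None = None, width: float = 0.75,
                amplitude: float = 0.8) -> np.ndarray:
    """Initial fields shaped as a target geometry.

    The minority (membrane-forming) B species is seeded as a smooth bump
    phi_b ~ amplitude * g(r); fields follow the SCF relations
    wA = chiN phi_b, wB = chiN phi_a.
    """
    chiN = params.chiN
    fb = 1 - params.architecture.f_a
    phib_bar = params.phi * fb

    def bump(d):
        return amplitude * np.exp(-(d / width) ** 2)

    if name == "uniform":
        g = np.full(grid.shape, phib_bar)
    elif name == "lamellar" and isinstance(grid, PlanarGrid):
        c = center if center is not None else grid.length / 2
        g = bump(grid.r - c)
    elif name == "vesicle" and isinstance(grid, RadialGrid) and grid.dim == 3:
        c = center if center is not None else grid.radius / 2
        g = bump(grid.r - c)
    elif name == "micelle" and isinstance(grid, RadialGrid):
        g = bump(grid.r)
    elif name == "cylinder" and isinstance(grid, RadialGrid) and grid.dim == 2:
        g = bump(grid.r)
    elif name == "toroid" and isinstance(grid, AxisymmetricGrid):
        c = center if center is not None else grid.radius / 2
        r, z = grid.coords
        d = np.sqrt((r - c) ** 2 + (z - grid.height / 2) ** 2)
        g = bump(d)
    elif name == "bowl" and isinstance(grid, AxisymmetricGrid):
        c = center if center is not None else grid.radius / 2
        r, z = grid.coords
        zc = grid.height / 2
        d = np.sqrt(r**2 + (z - zc) ** 2)
        shell = bump(d - c)
        theta = np.arctan2(r, z - zc)  # 0 at +z pole
        open_angle = np.radians(60.0)
        shell = np.where(theta > open_angle, shell, 0.0)
        g = shell
    else:
        raise ValueError(f"seed '{name}' incompatible with {type(grid).__name__}")
    g = np.clip(g, 1e-4, 0.95)
    w = np.empty((2, *grid.shape))
    w[A] = chiN * g
    w[B] = chiN * (1 - g)
    return w


# ---------------------------------------------------------------------------
# convergence loop
# ---------------------------------------------------------------------------

def converge(
    params: SCFTParams,
    grid: Grid,
    seed: str | np.ndarray = "uniform",
    raise_on_failure: bool = False,
) -> SCFTState:
    """Iterate simple-mixing field updates to the SCF fixed point.

    seed is a geometry name (see seed_fields) or an explicit (2, *shape)
    field array.  Non-convergence is flagged on the returned state (or
    raised with raise_on_failure).
    """
    if isinstance(seed, str):
        w = seed_fields(grid, params, seed)
        seed_name = seed
    else:
        w = np.array(seed, float)
        seed_name = "custom"
    chiN = params.chiN
    lam = params.mix
    history = []
    err = np.inf
    incomp = np.inf
    best_err = np.inf
    # Anderson history of field vectors and update residuals
    xs: list[np.ndarray] = []
    fs: list[np.ndarray] = []
    for it in range(params.max_iter):
        phi_a, phi_b, q_c, q_h = densities(grid, w, params)
        dev = phi_a + phi_b - 1.0
        eta = 0.5 * (w[A] + w[B] - chiN)
        res_a = chiN * phi_b + eta - w[A] + params.zeta * dev
        res_b = chiN * phi_a + eta - w[B] + params.zeta * dev
        err = max(
            np.max(np.abs(res_a - params.zeta * dev)),
            np.max(np.abs(res_b - params.zeta * dev)),
        )
        incomp = np.max(np.abs(dev))
        if it % 50 == 0 or err < params.tol:
            f = free_energy(grid, w, phi_a, phi_b, eta, q_c, q_h, params)
            history.append((it, err, incomp, f))
        if err < params.tol and incomp < params.incomp_tol:
            break
        x = w.ravel().copy()
        fvec = np.concatenate([res_a.ravel(), res_b.ravel()])
        m = params.anderson_depth
        x_new = None
        if m > 0 and it >= params.anderson_start and len(xs) >= 2:
            # type-II Anderson mixing on the fixed-point residual, with a
            # trust region: oversized or non-finite extrapolations fall
            # back to simple mixing and restart the history
            nhist = min(m, len(xs) - 1)
            df = np.stack([fs[-k] - fs[-k - 1] for k in range(1, nhist + 1)], 1)
            dx = np.stack([xs[-k] - xs[-k - 1] for k in range(1, nhist + 1)], 1)
            try:
                gamma, *_ = np.linalg.lstsq(df, fvec, rcond=1e-8)
                beta = params.anderson_beta
                cand = x + beta * fvec - (dx + beta * df) @ gamma
                step = np.max(np.abs(cand - x))
                # absolute trust region keeps the extrapolation physical
                if np.all(np.isfinite(cand)) and step < 5.0:
                    x_new = cand
            except np.linalg.LinAlgError:
                pass
            if x_new is None:
                xs.clear()
                fs.clear()
        if x_new is None:
            # bold-driver adaptation: creep the rate up while the residual
            # falls, halve it on any sustained rise
            if err < best_err:
                best_err = err
                lam = min(lam * 1.02, params.mix_max)
            elif err > 3.0 * best_err:
                lam = max(lam * 0.5, params.mix)
                best_err = err
            x_new = x + lam * fvec
        # fields stay within the physically meaningful window; the clip is
        # only ever active on transients
        np.clip(x_new, -120.0, 120.0, out=x_new)
        xs.append(x)
        fs.append(fvec)
        if len(xs) > m + 2:
            xs.pop(0)
            fs.pop(0)
        w = x_new.reshape(w.shape)
    phi_a, phi_b, q_c, q_h = densities(grid, w, params)
    eta = 0.5 * (w[A] + w[B] - chiN)
    f = free_energy(grid, w, phi_a, phi_b, eta, q_c, q_h, params)
    converged = err < params.tol and incomp < params.incomp_tol
    if not converged and raise_on_failure:
        raise SCFTConvergenceError(
            f"no SCF fixed point in {params.max_iter} iterations "
            f"(residual {err:.2e}, incompressibility {incomp:.2e})"
        )
    return SCFTState(
        params=params, grid=grid, w=w, phi_a=phi_a, phi_b=phi_b, eta=eta,
        q_c=q_c, q_h=q_h, free_energy=float(f), residual=float(err),
        incompressibility=float(incomp), iterations=it + 1,
        converged=converged, seed_name=seed_name, history=history,
    )


def optimize_cell(params: SCFTParams, make_grid, seed: str,
                  bounds: tuple[float, float]) -> tuple[SCFTState, float]:
    """Golden-section minimization of F over the cell dimension.

    make_grid(L) builds the grid at cell size L; used for periodic
    structures (lamellae) where F depends on the repeat distance.
    """
    cache = {}

    def f_of(L):
        st = converge(params, make_grid(L), seed)
        cache[L] = st
        return st.free_energy

    res = minimize_scalar(f_of, bounds=bounds, method="bounded",
                          options={"xatol": 1e-2})
    return cache[res.x], float(res.x)


def compare_structures(
    params: SCFTParams,
    structures: dict[str, tuple[Grid, str]],
    degeneracy_threshold: float = 0.01,
):
    """Converge every candidate and rank by free energy.

    structures maps name -> (grid, seed name).  Returns a list of dicts
    with F, dF vs the minimum, convergence flags, and a near_degenerate
    marker when |dF| < degeneracy_threshold * |F_min| (the coexistence
    criterion).
    """
    rows = []
    for name, (grid, seedname) in structures.items():
        st = converge(params, grid, seedname)
        rows.append({
            "structure": name,
            "free_energy": st.free_energy,
            "converged": st.converged,
            "residual": st.residual,
            "incompressibility": st.incompressibility,
            "iterations": st.iterations,
            "state": st,
        })
    fmin = min(r["free_energy"] for r in rows if r["converged"]) if any(
        r["converged"] for r in rows
    ) else min(r["free_energy"] for r in rows)
    for r in rows:
        r["delta_f"] = r["free_energy"] - fmin
        r["near_degenerate"] = bool(
            abs(r["delta_f"]) < degeneracy_threshold * abs(fmin)
        )
    rows.sort(key=lambda r: r["free_energy"])
    return rows
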