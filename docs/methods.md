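# Methods

`combsim` simulates the self-assembly of amphiphilic comb copolymers
Ax-comb-(By)n in implicit solvent with overdamped Brownian dynamics (BD),
analyses the resulting aggregates, and ranks candidate morphologies by
self-consistent field theory (SCFT) free energies.  This note records the
models, the numerical choices, and what the desk-scale protocols do and do
not establish.

## Coarse-grained model

A molecule is a bead–spring graph: a hydrophobic backbone of `x` A beads
carrying `n` hydrophilic side chains of `y` B beads grafted at `n` distinct
backbone positions drawn uniformly without replacement (`n <= x`).  All
quantities are in reduced units: lengths in the bead diameter sigma,
energies in the Lennard-Jones epsilon, kBT = 1, times in
tau = sqrt(m sigma^2/epsilon) (bookkeeping only — the dynamics is
inertialess).

Bonded interactions (backbone, side chain, and graft bonds alike) use the
finitely extensible nonlinear elastic potential

    U_FENE(r) = -0.5 kappa R0^2 ln[1 - (r/R0)^2],   kappa = 30, R0 = 1.5,

the Kremer–Grest parameterization whose combination with the repulsive LJ
core prevents chain crossing and puts the equilibrium bond length near
0.97 sigma.  Non-bonded pairs interact through the truncated-and-shifted
Lennard-Jones potential with species-dependent cutoffs that encode solvent
quality implicitly:

* A–A: rc = 2.5 sigma — the attractive well survives (poor solvent,
  hydrophobic attraction);
* A–B and B–B: rc = 2^(1/6) sigma — purely repulsive after the shift
  (good solvent, the WCA limit).

Each pair potential is shifted so U(rc) = 0 exactly; epsilon and sigma are
uniform across species (only the cutoffs differ), with per-pair overrides
configurable.  Following the Kremer–Grest convention, directly bonded
beads also feel the pair LJ term; a switch (`exclude_bonded_lj`) removes
it for sensitivity checks, since the original description does not state
which convention was used.

## Brownian dynamics

Bead positions follow the overdamped Langevin equation
dr/dt = -grad(U)/xi + f/xi with Gaussian white noise obeying
fluctuation–dissipation, <f_i(t) f_j(t')> = 2 xi kBT delta_ij delta(t-t') I.
Euler–Maruyama discretization: each step displaces a bead by
(dt/xi) F + sqrt(2 kBT dt/xi) eta.  Defaults: dt = 1e-4, xi = 0.5, kBT = 1.
The bead diffusion coefficient is D = kBT/xi = 2 (MSD = 12 t), which the
test suite verifies to percent accuracy.  Hydrodynamic interactions between
beads are not modelled.

Implementation: species-aware Verlet pair lists built from half-cutoff cell
binning (A–A pairs listed to 2.5 + skin, all others only to the WCA core +
skin; skin = 0.5 sigma, rebuilt when any bead has moved more than skin/2),
minimum-image convention on every pair, positions stored unwrapped.
Single-threaded runs are bit-for-bit reproducible for a given seed and
save cadence; changing the save cadence changes pair-summation round-off,
which chaos amplifies into statistically equivalent but not identical
trajectories.

Numerical safeguard: the explicit Euler scheme is only marginally stable
against the steep LJ core at dt = 1e-4.  Rare many-body squeezes in dense
hydrophobic cores (order one event per 1e8 bead-steps) otherwise trigger an
overshoot cascade that snaps a FENE bond.  The integrator therefore clamps
the *deterministic* (force) displacement of a bead at 0.1 sigma per step —
about five times the typical displacement, so equilibrium statistics are
untouched — and counts clamp events.  A bond that still reaches R0 aborts
the run with an "integration unstable" error rather than propagating NaNs.

System construction: chains are grown as self-avoiding random walks,
placed at random positions and orientations at the target bead volume
fraction phi = 0.15 (bead volume pi sigma^3/6 — the convention is isolated
in one function), and relaxed by a short zero-temperature capped-force
push-off until no pair is closer than 0.8 sigma.

## Morphology analysis

Aggregates are single-linkage clusters over A–A contacts within 1.5 sigma
(first coordination shell of the A–A well); each chain's B beads follow
their backbone.  Every cluster observable first unwraps the cluster across
periodic boundaries by a breadth-first walk over the bond + contact graph.
Shape is summarized by the gyration tensor eigenvalues
(lambda1 >= lambda2 >= lambda3) and the relative shape anisotropy kappa^2
(0 for spheres, 1/4 for flat disks and rings, 1 for rods).  Radial
structure uses the hydrophilic-bead density in concentric shells of width
0.25 sigma about the cluster centre of mass; a closed vesicle shows two
peaks (the inner and outer hydrophilic linings of the membrane) around an
empty solvent cavity.  Vesicle metrics: membrane thickness = separation of
the two peaks; cavity diameter and overall size from where the density
falls below 10% of the respective peak.

Classification applies ordered decision rules to the largest cluster:
dispersed (majority-cluster chain fraction < 0.5); vesicle (enclosed
cavity + two-peak B profile + kappa^2 < 0.1); non-spherical vesicle
(enclosed cavity otherwise); toroid (central hole, planar-oblate, complete
azimuthal ring occupancy, and *two* empty polar patches in the directional
occupancy map); cylinder (prolate); bowl (exactly one connected empty
direction patch subtending 5–50% of solid angle); sheet (oblate without
cavity); otherwise "unclassified" with full diagnostics.  The
toroid-versus-bowl discriminator (two openings versus one) is needed
because a deep bowl also has a central hole, an oblate tensor and complete
ring occupancy.  The directional occupancy grid uses equal-solid-angle
bins in the gyration principal frame, with resolution adapted to the bead
count so sparse clusters do not produce spurious openings.  All thresholds
are configuration constants, validated against constructed sphere / ring /
rod / disk / bowl geometries under random rotations.

Timelines classify every saved frame, smooth by majority vote over a
5-frame window, and collapse to runs of distinct labels; a run is "stable"
when the largest-cluster Rg over the final quarter of frames has relative
standard deviation below 5%.  A phase point's label is the multiset of
replica end states; labels occurring in at least 25% of replicas are kept,
and two or more surviving labels mean coexistence.

## SCFT

The blend is an incompressible melt of AB comb copolymers and short
A-homopolymer solvent under the mean-field Gaussian-chain model.  In SCFT
units (lengths in a sqrt(N/6), contour in units of N segments) block
propagators obey dq/ds = lap(q) - omega q, solved by symmetric operator
splitting with exact spectral diffusion on periodic Cartesian grids and
Crank–Nicolson finite-volume diffusion on symmetry-reduced grids (planar
slab, cylindrical and spherical radial, axisymmetric r–z).  The discrete
one-step operator is self-adjoint in the cell-volume inner product, so the
single-chain partition function is independent of the contour split point
to round-off — an internal consistency check the tests enforce at 1e-8.

The reference molecule A1-comb-(B1)1 maps to an AB2 star with fA = 0.5
(arms A:0.5N, B:0.25N, B:0.25N); general combs map 1 bead to 0.5N
segments (backbone 0.5x, side chains 0.5y, evenly spaced grafts, total
alpha = 0.5(x + ny)).  chiN = 15, solvent length gamma = 0.2N.  Fields are
iterated by simple mixing (lambda = 0.1) with a local incompressibility
penalty; convergence requires the maximum field residual < 1e-6 and
max|phiA + phiB - 1| < 1e-4.  Free energy per reference volume:

    F = -(phi/alpha) ln(Qc/phi) - ((1-phi)/gamma) ln(Qh/(1-phi))
        + < chiN phiA phiB - wA phiA - wB phiB - eta(1 - phiA - phiB) >.

Closed-form oracles: at chiN = 0 (or any uniform state) F reduces to the
Flory–Huggins expression, reproduced to 1e-8.

Composition: the copolymer volume fraction used in the original SCFT
calculations is not stated.  At the BD-matching phi = 0.15 the blend is
disordered at chiN = 15 — the B blocks are too short and too dilute to
microphase-separate — so structured free-energy comparisons use the
solvent-minority preset phi = 0.85, where lamellar, shell and ring
structures converge as local SCF minima; both presets ship and tests cover
both.  Candidate structures (sheet = planar lamella, vesicle = spherical
shell, cylinder = radial column, toroid and bowl on the axisymmetric grid)
are seeded through shaped initial fields; the lamellar period can be
optimized by golden-section search on F.  Near-degeneracy between
converged structures (free-energy gaps below 1% of |F|) is the mean-field
rationale for the coexistence of sheet/bowl/vesicle and toroid/cylinder
end states observed in the BD replicas.

## Desk-scale protocols

The published protocol (20 sigma box, phi = 0.15, 3.5–5.0e8 steps, 5–10
replicas) needs days of CPU.  The packaged tests and the acceptance script
run the same physics at desk scale, chosen once as study conditions:

* dispersed phase at saturation grafting: A4-comb-(B1)4 in a 10 sigma box,
  2e5 steps, 3 replicas.  Instantaneous single-linkage clusters percolate
  transiently at phi = 0.15 even for non-aggregating chains, so "no
  stable structure" is operationalized as the fraction of chains that
  *persist* in the largest cluster over the final frames (zero for
  saturated combs, which are sterically encapsulated single-molecule
  micelles).
* membrane closure pathway: A8-comb-(B1)2, 48 chains as a preformed flat
  aggregate in an 18 sigma box, 8e5 steps, 2 replicas.  Free-standing
  desk-scale sheets bend through bowl-like intermediates toward closed
  shells; starting from the sheet intermediate stands in for the
  published full pathway because the spontaneous small-cluster -> sheet
  stage needs orders of magnitude more steps (spontaneous desk-scale runs
  in small boxes instead end in box-spanning cylindrical aggregates — a
  finite-size selection of the competing cylinder branch).
* membrane-thickness trend: Ax-comb-(B1)2 for x = 4, 8, 10 relaxed for
  1.5e5 steps from equal-bead-budget (~900 beads) spherical-shell seeds at
  melt-like density — the BD analogue of SCFT structure seeding.  A short
  relaxation organizes the membrane locally but does not re-equilibrate
  global chain packing; radial-profile orderings measured this way retain
  memory of the seed and scatter between molecules (see Limitations).

Densely seeded initial states occasionally trip the integrator's
stability guard during the first relaxation; protocol runners retry with
a fresh construction seed (bounded attempts; failed runs abort, never
continue silently).

What desk scale shows: the dispersed phase at n = x, the sheet -> bowl ->
closure sequence, replica-to-replica morphology variability, and every
quantitative fluctuation-dissipation and Boltzmann-sampling oracle.  What
it does not show: converged phase-diagram boundaries, equilibrated vesicle
membrane profiles (the Fig-4-style inner-peak ordering and the backbone
end-to-end statistics of equilibrated vesicles), aggregate size
distributions, or long-time coarsening — those need the full protocol
(`protocol.preset: paper` in the configuration).

Equilibrium-sampling checks (dimer bond-length and trimer bond-angle
distributions against Boltzmann quadrature oracles) run at a reduced time
step: the explicit Euler scheme carries an O(dt) sampling bias on stiff
coordinates that reaches ~13% of the bond-length distribution peak at the
default dt = 1e-4 and falls below 1% at dt = 1e-5.  Histogram oracles are
bin-averaged (midpoint evaluation alone biases a sharp peak by ~1.5%).

Backbone end-to-end statistics are reported under two conventions — mean
Euclidean end-to-end distance and mean contour length — because the
published "average distance from backbone end to end approximately 4" for
a 4-bead backbone exceeds the maximum extension of a FENE chain with
0.97 sigma bonds (about 2.9 even fully stretched) and is therefore
presumably a contour-length (or bead-count) convention; reporting both
makes the discrepancy measurable instead of guessed away.

## Known limitations

* No hydrodynamic interactions, electrostatics, angular stiffness or
  explicit solvent; solvent quality lives entirely in the pair cutoffs.
* The classifier thresholds are calibrated on idealized geometries; highly
  defective aggregates fall back to "unclassified" rather than being
  forced into a label.
* SCFT finite aggregates at phi = 0.85 converge to onion-like multi-shell
  local minima in large cells; free energies are still comparable between
  seeds, but absolute aggregate geometry should not be read off them.
* The Euler force-displacement clamp makes the scheme robust but formally
  first-order; observables sensitive to integration bias should be checked
  against a smaller dt.
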