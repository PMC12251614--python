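"""Observables and morphology assignment for assembled aggregates.

The pipeline mirrors how one reads a simulation snapshot by eye, but with
explicit, configurable criteria:

* clusters: single-linkage connected components over hydrophobic (A) beads
  within a cutoff (default 1.5 sigma, the first coordination shell of the
  attractive A-A well); each chain's B beads follow their backbone.
* shape: gyration tensor eigenvalues and relative shape anisotropy
  ("asphericity" below; 0 for a sphere, 1/4 for a flat disk or ring, 1 for
  a thin rod).
* radial structure: hydrophilic-bead density in concentric spherical
  shells about the cluster centre of mass; a closed vesicle shows two
  peaks (inner and outer hydrophilic lining of the membrane) around an
  empty solvent cavity.
* label: decision rules over these diagnostics assign one of
  dispersed / vesicle / non-spherical vesicle / toroid / cylinder / sheet /
  bowl, or 'unclassified' when no rule fires cleanly.

All centre-of-mass, gyration and profile computations unwrap the cluster
across periodic boundaries first (breadth-first walk over the contact +
bond graph, placing each bead at the minimum image of its parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import kernels
from .bd import SimulationState, Trajectory

MORPHOLOGY_LABELS = (
    "dispersed", "cylinder", "toroid", "sheet", "bowl",
    "vesicle", "non-spherical vesicle", "unclassified",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Config-exposed constants of the morphology decision rules."""

    cluster_cutoff: float = 1.5  # sigma, A-A single-linkage distance
    dispersed_chain_fraction: float = 0.5
    asphericity_spherical: float = 0.1  # relative shape anisotropy bound
    cavity_min_shells: int = 2
    shell_width: float = 0.25  # sigma
    closed_max_open_fraction: float = 0.05  # solid-angle fraction
    bowl_max_open_fraction: float = 0.5
    oblate_ratio: float = 0.35  # lambda3/lambda2 below this = planar
    prolate_ratio: float = 0.4  # lambda2/lambda1 below this = elongated
    profile_peak_fraction: float = 0.1  # edge threshold vs peak height


@dataclass
class ClusterSet:
    """Partition of all beads into aggregates (labels per bead)."""

    labels: np.ndarray  # cluster index per bead
    n_clusters: int
    state: SimulationState = field(repr=False)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def largest(self) -> int:
        return int(np.argmax(self.sizes()))

    def chain_fraction(self, c: int) -> float:
        """Fraction of all chains whose backbone sits in cluster c."""
        cid = self.state.chain_id
        in_c = np.unique(cid[self.labels == c])
        return len(in_c) / len(np.unique(cid))


@dataclass
class DensityProfile:
    """Radial shell histogram of hydrophilic-bead density about a centre."""

    edges: np.ndarray  # shell edges, equal thickness
    density: np.ndarray  # B beads per sigma^3 in each shell
    counts: np.ndarray
    total_density: np.ndarray  # all-species density, for cavity detection

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def shell_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class MorphologyReport:
    label: str
    eigenvalues: tuple[float, float, float]  # lambda1 >= lambda2 >= lambda3
    asphericity: float
    rg: float
    chain_fraction: float
    diagnostics: dict


class NotSphericalVesicleError(ValueError):
    """Radial profile lacks the two-peak vesicle signature."""


# ---------------------------------------------------------------------------
# clustering and unwrapping
# ---------------------------------------------------------------------------

def find_clusters(state: SimulationState, cutoff: float = 1.5) -> ClusterSet:
    """Single-linkage clusters over A-A contacts; B beads follow their chain.

    Two chains belong to the same cluster iff some pair of their backbone
    (A) beads lies within the cutoff under minimum image.
    """
    n = state.n_beads
    a_idx = np.flatnonzero(state.species == 0)
    sub = np.ascontiguousarray(state.positions[a_idx])
    pi, pj = kernels.pair_list_uniform(sub, state.box, cutoff)
    na = len(a_idx)
    adj = csr_matrix(
        (np.ones(len(pi)), (pi, pj)), shape=(na, na)
    )
    ncl, lab_a = connected_components(adj, directed=False)
    # chains may in principle have no A beads; give them their own clusters
    labels = np.full(n, -1, np.int64)
    labels[a_idx] = lab_a
    # propagate over chains: every bead takes the label of its chain's backbone
    for cid in np.unique(state.chain_id):
        mask = state.chain_id == cid
        have = labels[mask]
        good = have[have >= 0]
        if len(good):
            # backbone beads of one chain are bonded within ~1 sigma, hence
            # always in one component
            labels[mask] = good[0]
    if np.any(labels < 0):
        nxt = ncl
        for cid in np.unique(state.chain_id):
            mask = state.chain_id == cid
            if labels[mask][0] < 0:
                labels[mask] = nxt
                nxt += 1
        ncl = nxt
    return ClusterSet(labels=labels, n_clusters=ncl, state=state)


def unwrap_positions(
    positions: np.ndarray,
    box: np.ndarray,
    bonds: np.ndarray | None = None,
    cutoff: float = 1.5,
) -> np.ndarray:
    """Embed a (sub)set of beads continuously across periodic boundaries.

    Breadth-first walk over the union of the bond graph and the proximity
    graph; each newly visited bead is placed at the minimum image relative
    to its parent.  Disconnected pieces are each unwrapped about their own
    seed bead.
    """
    pos = np.ascontiguousarray(positions, float)
    n = len(pos)
    box = np.asarray(box, float)
    pi, pj = kernels.pair_list_uniform(pos, box, cutoff)
    src = [pi]
    dst = [pj]
    if bonds is not None and len(bonds):
        src.append(bonds[:, 0])
        dst.append(bonds[:, 1])
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    # adjacency in CSR form
    deg = np.zeros(n + 1, np.int64)
    np.add.at(deg, src + 1, 1)
    np.add.at(deg, dst + 1, 1)
    ptr = np.cumsum(deg)
    nbr = np.empty(ptr[-1], np.int64)
    fill = ptr[:-1].copy()
    for a, b in zip(src, dst):
        nbr[fill[a]] = b
        fill[a] += 1
        nbr[fill[b]] = a
        fill[b] += 1

    out = pos.copy()
    seen = np.zeros(n, bool)
    for seed in range(n):
        if seen[seed]:
            continue
        seen[seed] = True
        queue = [seed]
        while queue:
            a = queue.pop()
            base = out[a]
            for k in range(ptr[a], ptr[a + 1]):
                b = nbr[k]
                if seen[b]:
                    continue
                seen[b] = True
                d = pos[b] - base
                d -= box * np.rint(d / box)
                out[b] = base + d
                queue.append(b)
    return out


def cluster_positions(cs: ClusterSet, c: int, cutoff: float = 1.5) -> np.ndarray:
    """Unwrapped coordinates of one cluster (bond + contact graph walk)."""
    idx = cs.members(c)
    remap = -np.ones(cs.state.n_beads, np.int64)
    remap[idx] = np.arange(len(idx))
    b = cs.state.bonds
    keep = remap[b[:, 0]] >= 0
    bonds = np.column_stack([remap[b[keep, 0]], remap[b[keep, 1]]])
    return unwrap_positions(cs.state.positions[idx], cs.state.box, bonds, cutoff)


# ---------------------------------------------------------------------------
# shape and radial structure
# ---------------------------------------------------------------------------

def gyration(positions: np.ndarray):
    """(Rg, eigenvalues desc, asphericity) of an unwrapped bead set.

    asphericity here is the relative shape anisotropy
    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1+l2+l3)^2,
    which is 0 for spherically symmetric clouds and 1 for a line.
    """
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or len(pos) == 0:
        raise ValueError("need at least one bead")
    d = pos - pos.mean(axis=0)
    if len(pos) == 1:
        return 0.0, (0.0, 0.0, 0.0), 0.0
    t = d.T @ d / len(pos)
    ev = np.sort(np.linalg.eigvalsh(t))[::-1]
    tr = ev.sum()
    kappa2 = 0.0
    if tr > 0:
        kappa2 = 1.0 - 3.0 * (ev[0] * ev[1] + ev[1] * ev[2] + ev[2] * ev[0]) / tr**2
    return float(np.sqrt(tr)), tuple(float(x) for x in ev), float(kappa2)


def radius_of_gyration(positions: np.ndarray) -> float:
    return gyration(positions)[0]


def density_profile(
    positions: np.ndarray,
    species: np.ndarray,
    shell_width: float = 0.25,
    center: np.ndarray | None = None,
    r_max: float | None = None,
) -> DensityProfile:
    """Hydrophilic (B) bead density in concentric shells of equal thickness.

    positions must be unwrapped; the centre defaults to the centre of mass
    of all beads in the cluster.
    """
    pos = np.asarray(positions, float)
    species = np.asarray(species)
    if center is None:
        center = pos.mean(axis=0)
    r = np.linalg.norm(pos - center, axis=1)
    if r_max is None:
        r_max = r.max() + 2 * shell_width
    nsh = max(1, int(np.ceil(r_max / shell_width)))
    edges = np.arange(nsh + 1) * shell_width
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    b_counts, _ = np.histogram(r[species == 1], bins=edges)
    all_counts, _ = np.histogram(r, bins=edges)
    return DensityProfile(
        edges=edges,
        density=b_counts / vol,
        counts=b_counts,
        total_density=all_counts / vol,
    )


def _profile_peaks(profile: DensityProfile, min_count: int = 4):
    """Indices of the significant maxima of the B density (inner, outer).

    Innermost shells hold almost no volume, so a single bead there gives a
    huge density spike; shells below min_count beads cannot be peaks.
    """
    rho = np.where(profile.counts >= min_count, profile.density, 0.0)
    if rho.max() <= 0:
        return []
    pk, props = find_peaks(rho, height=0.15 * rho.max(), distance=2)
    if len(pk) > 2:
        # keep the two tallest, in radial order
        top = np.sort(pk[np.argsort(props["peak_heights"])[-2:]])
        pk = top
    return list(pk)


def vesicle_metrics(
    profile: DensityProfile, peak_fraction: float = 0.1
) -> dict:
    """Overall size, cavity diameter and membrane thickness of a vesicle.

    Requires the two-peak hydrophilic profile; otherwise raises
    NotSphericalVesicleError.  The membrane thickness is the separation of
    the two hydrophilic peaks (inner and outer membrane surfaces); edges
    are located where the density falls below peak_fraction of the
    respective peak.
    """
    pk = _profile_peaks(profile)
    if len(pk) < 2:
        raise NotSphericalVesicleError(
            "hydrophilic density profile does not show two peaks"
        )
    r = profile.centers
    rho = profile.density
    i1, i2 = pk
    r1, r2 = r[i1], r[i2]
    # cavity: walk inward from the inner peak until below the threshold
    thr_in = peak_fraction * rho[i1]
    cavity_edge = 0.0
    for i in range(i1, -1, -1):
        if rho[i] < thr_in:
            cavity_edge = r[i]
            break
    # outer edge: walk outward from the outer peak
    thr_out = peak_fraction * rho[i2]
    outer_edge = r[-1]
    for i in range(i2, len(r)):
        if rho[i] < thr_out:
            outer_edge = r[i]
            break
    return {
        "inner_peak_radius": float(r1),
        "outer_peak_radius": float(r2),
        "membrane_thickness": float(r2 - r1),
        "cavity_diameter": float(2 * cavity_edge),
        "overall_size": float(2 * outer_edge),
    }


def backbone_end_to_end(
    state: SimulationState, backbone_len: int
) -> dict:
    """Backbone end-to-end and contour statistics over all chains.

    Chains are unwrapped by summing minimum-image bond vectors along the
    backbone (beads 0..x-1 of each chain).  Returns the mean Euclidean
    end-to-end distance and the mean contour length; for x=1 both are 0.
    """
    x = backbone_len
    cids = np.unique(state.chain_id)
    if x < 2:
        return {"end_to_end_mean": 0.0, "contour_mean": 0.0,
                "end_to_end": np.zeros(len(cids)), "contour": np.zeros(len(cids))}
    box = state.box
    e2e = np.empty(len(cids))
    contour = np.empty(len(cids))
    for k, cid in enumerate(cids):
        idx = np.flatnonzero(state.chain_id == cid)[:x]
        p = state.positions[idx]
        dv = np.diff(p, axis=0)
        dv -= box * np.rint(dv / box)
        e2e[k] = np.linalg.norm(dv.sum(axis=0))
        contour[k] = np.linalg.norm(dv, axis=1).sum()
    return {
        "end_to_end_mean": float(e2e.mean()),
        "contour_mean": float(contour.mean()),
        "end_to_end": e2e,
        "contour": contour,
    }


# ---------------------------------------------------------------------------
# directional coverage (cavity enclosure, ring closure, bowl opening)
# ---------------------------------------------------------------------------

def _direction_occupancy(rel: np.ndarray, n_theta: int | None = None,
                         n_phi: int | None = None):
    """Occupancy grid over equal-solid-angle bins of bead directions.

    Bins are uniform in (cos(theta), phi) so each bin subtends the same
    solid angle.  The resolution adapts to the bead count (expected >= 4
    beads per bin for an isotropic cloud) so sparse clusters do not produce
    spurious empty patches.  Returns the boolean occupied grid.
    """
    if n_theta is None:
        n_theta = int(np.clip(np.sqrt(len(rel) / 8.0), 4, 12))
    if n_phi is None:
        n_phi = 2 * n_theta
    r = np.linalg.norm(rel, axis=1)
    ok = r > 1e-9
    rel = rel[ok]
    r = r[ok]
    ct = np.clip(rel[:, 2] / r, -1.0, 1.0)
    phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    it = np.minimum((0.5 * (ct + 1.0) * n_theta).astype(int), n_theta - 1)
    ip = np.minimum((phi / (2 * np.pi) * n_phi).astype(int), n_phi - 1)
    occ = np.zeros((n_theta, n_phi), bool)
    occ[it, ip] = True
    return occ


def _open_patches(occ: np.ndarray, min_fraction: float = 0.02) -> list[float]:
    """Solid-angle fractions of connected empty patches, largest first.

    Empty bins are connected 4-neighbourhood with wraparound in phi (the
    azimuthal axis); all bins subtend equal solid angle.  Patches smaller
    than min_fraction are ignored (noise).  A closed shell returns [];
    a bowl one patch; a toroid two (the opposite polar openings).
    """
    empty = ~occ
    if not empty.any():
        return []
    # wrap in phi by tiling, labelling, then collapsing duplicates
    lab, nlab = ndimage.label(np.concatenate([empty, empty], axis=1))
    if nlab == 0:
        return []
    n_phi = occ.shape[1]
    # tiling duplicates non-wrapping patches and joins wrapping ones; the
    # set of cells modulo n_phi identifies each physical patch uniquely
    patches = {
        frozenset((r_, c_ % n_phi) for r_, c_ in np.argwhere(lab == l))
        for l in range(1, nlab + 1)
    }
    out = sorted((len(k) / occ.size for k in patches), reverse=True)
    return [f for f in out if f >= min_fraction]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(
    cs: ClusterSet,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> MorphologyReport:
    """Morphology label for the largest cluster of a frame.

    Rules, in order: dispersed; vesicle; non-spherical vesicle; toroid;
    cylinder; sheet; bowl; otherwise 'unclassified' with diagnostics.
    """
    th = thresholds
    c = cs.largest()
    frac = cs.chain_fraction(c)
    diagnostics: dict = {"chain_fraction": frac}
    if frac < th.dispersed_chain_fraction:
        return MorphologyReport(
            "dispersed", (np.nan,) * 3, np.nan, np.nan, frac, diagnostics
        )

    pos = cluster_positions(cs, c, th.cluster_cutoff)
    idx = cs.members(c)
    species = cs.state.species[idx]
    rg, ev, kappa2 = gyration(pos)
    diagnostics.update(rg=rg, eigenvalues=ev, asphericity=kappa2)

    com = pos.mean(axis=0)
    rel = pos - com
    prof = density_profile(pos, species, th.shell_width, center=com)
    diagnostics["profile"] = prof

    # cavity: consecutive all-species-empty shells from the centre outward
    empty0 = 0
    for d in prof.total_density:
        if d == 0:
            empty0 += 1
        else:
            break
    has_central_hole = empty0 >= th.cavity_min_shells
    diagnostics["central_empty_shells"] = empty0

    # principal frame: z along the thin (lambda3) axis so the directional
    # occupancy is orientation independent
    _, v = np.linalg.eigh((rel.T @ rel) / len(rel))
    rel_pf = rel @ v[:, ::-1]  # columns now lambda1, lambda2, lambda3
    occ = _direction_occupancy(rel_pf)
    patches = _open_patches(occ)
    open_frac = patches[0] if patches else 0.0
    diagnostics["open_fraction"] = open_frac
    diagnostics["open_patches"] = patches
    closed_shell = open_frac <= th.closed_max_open_fraction
    enclosed = has_central_hole and closed_shell

    peaks = _profile_peaks(prof)
    two_peak = len(peaks) >= 2
    diagnostics["two_peak_profile"] = two_peak

    l1, l2, l3 = ev
    oblate = l2 > 0 and l3 / l2 < th.oblate_ratio and l2 / l1 > 0.5
    prolate = l1 > 0 and l2 / l1 < th.prolate_ratio and not oblate
    diagnostics.update(oblate=oblate, prolate=prolate)

    def report(label):
        return MorphologyReport(label, ev, kappa2, rg, frac, diagnostics)

    if enclosed and two_peak and kappa2 < th.asphericity_spherical:
        return report("vesicle")
    if enclosed:
        return report("non-spherical vesicle")
    if has_central_hole and oblate and len(patches) >= 2:
        # ring closure: azimuthal occupancy around the principal (thin) axis;
        # a toroid additionally opens at both poles (>= 2 empty patches,
        # separating it from a deep bowl) and has a genuine in-plane hole
        # (separating it from a bent sheet whose COM merely sits off the
        # material)
        ang = np.arctan2(rel_pf[:, 1], rel_pf[:, 0])
        nbins = 36
        occ_ring = np.zeros(nbins, bool)
        occ_ring[
            np.minimum(((ang + np.pi) / (2 * np.pi) * nbins).astype(int), nbins - 1)
        ] = True
        diagnostics["ring_occupancy"] = float(occ_ring.mean())
        rho_inplane = np.hypot(rel_pf[:, 0], rel_pf[:, 1])
        hole_radius = float(np.quantile(rho_inplane, 0.02))
        diagnostics["in_plane_hole_radius"] = hole_radius
        if occ_ring.all() and hole_radius > 1.0:
            return report("toroid")
    if prolate:
        return report("cylinder")
    if (
        len(patches) == 1
        and th.closed_max_open_fraction < open_frac < th.bowl_max_open_fraction
    ):
        return report("bowl")
    if oblate and not has_central_hole:
        return report("sheet")
    return report("unclassified")


# ---------------------------------------------------------------------------
# timelines, stability, phase points
# ---------------------------------------------------------------------------

def classify_trajectory(
    traj: Trajectory,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    start: int = 0,
) -> list[MorphologyReport]:
    out = []
    for f in range(start, len(traj)):
        st = SimulationState(
            traj.frames[f], traj.species, traj.box, traj.bonds, traj.chain_id
        )
        cs = find_clusters(st, thresholds.cluster_cutoff)
        out.append(classify(cs, thresholds))
    return out


def pathway_timeline(
    traj: Trajectory,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    window: int = 5,
    reports: list[MorphologyReport] | None = None,
) -> list[tuple[str, int, int]]:
    """Sequence of (label, first_frame, last_frame) after majority smoothing.

    Per-frame labels of the largest cluster are smoothed by majority vote
    over a centred window, then collapsed into runs of distinct labels.
    Precomputed per-frame reports may be passed to avoid reclassification.
    """
    if reports is None:
        reports = classify_trajectory(traj, thresholds)
    labels = [r.label for r in reports]
    half = window // 2
    smooth = []
    for i in range(len(labels)):
        seg = labels[max(0, i - half) : i + half + 1]
        vals, cnts = np.unique(seg, return_counts=True)
        top = vals[cnts == cnts.max()]
        smooth.append(labels[i] if labels[i] in top else str(top[0]))
    runs: list[tuple[str, int, int]] = []
    for i, lab in enumerate(smooth):
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1], i)
        else:
            runs.append((lab, i, i))
    return runs


def persistent_largest_fraction(
    traj: Trajectory, n_frames: int = 5, cutoff: float = 1.5
) -> float:
    """Fraction of chains that stay in the largest cluster over the final
    frames.

    Instantaneous single-linkage clusters in a poor-solvent dispersion are
    transient contact networks; a *stable* aggregate keeps its membership.
    The dispersed phase therefore shows a near-zero persistent fraction
    even when instantaneous largest-cluster fractions fluctuate high.
    """
    n_frames = min(n_frames, len(traj))
    sets = []
    n_chains = len(np.unique(traj.chain_id))
    for f in range(len(traj) - n_frames, len(traj)):
        st = SimulationState(
            traj.frames[f], traj.species, traj.box, traj.bonds, traj.chain_id
        )
        cs_ = find_clusters(st, cutoff)
        c = cs_.largest()
        sets.append(set(np.unique(st.chain_id[cs_.labels == c]).tolist()))
    persist = set.intersection(*sets) if sets else set()
    return len(persist) / max(n_chains, 1)


def rg_series(traj: Trajectory, cutoff: float = 1.5) -> np.ndarray:
    """Radius of gyration of the largest cluster per frame."""
    out = np.empty(len(traj))
    for f in range(len(traj)):
        st = SimulationState(
            traj.frames[f], traj.species, traj.box, traj.bonds, traj.chain_id
        )
        cs = find_clusters(st, cutoff)
        out[f] = gyration(cluster_positions(cs, cs.largest(), cutoff))[0]
    return out


def is_stable(rg: np.ndarray, window_fraction: float = 0.25,
              rel_std_max: float = 0.05) -> bool:
    """Stable when largest-cluster Rg over the final window fluctuates < 5%."""
    w = max(2, int(len(rg) * window_fraction))
    tail = rg[-w:]
    return bool(np.std(tail) / max(np.mean(tail), 1e-12) < rel_std_max)


def phase_point_label(final_labels: list[str], coexist_fraction: float = 0.25):
    """Reduce replica end-states to a phase-diagram entry.

    Labels occurring in at least coexist_fraction of the replicas are kept;
    two or more surviving labels mean a coexistence region.
    """
    vals, cnts = np.unique([l for l in final_labels], return_counts=True)
    keep = [
        (v, int(c)) for v, c in zip(vals, cnts)
        if c / len(final_labels) >= coexist_fraction and v != "unclassified"
    ]
    keep.sort(key=lambda t: -t[1])
    names = [v for v, _ in keep]
    if not names:
        return {"label": "unclassified", "coexistence": [], "counts": dict(zip(vals.tolist(), cnts.tolist()))}
    return {
        "label": names[0] if len(names) == 1 else "coexistence",
        "coexistence": names if len(names) > 1 else [],
        "counts": dict(zip(vals.tolist(), cnts.tolist())),
    }
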