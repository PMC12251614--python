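"""Cluster detection, shape descriptors, profiles and morphology labels."""

import numpy as np
import pytest

import combsim as cs
from combsim import analysis as an
from combsim import builder as bl
from combsim.bd import SimulationState

BIGBOX = np.array([40.0, 40.0, 40.0])


def geometry_state(positions, species=None, chain_id=None):
    pos = np.asarray(positions, float) + BIGBOX / 2
    n = len(pos)
    return SimulationState(
        positions=pos,
        species=np.zeros(n, np.int8) if species is None else species,
        box=BIGBOX,
        bonds=np.empty((0, 2), np.int64),
        chain_id=np.zeros(n, np.int64) if chain_id is None else chain_id,
    )


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


class TestFindClusters:
    def test_two_beads_within_cutoff_one_cluster(self):
        st = geometry_state([[0, 0, 0], [1, 0, 0]], chain_id=np.array([0, 1]))
        assert an.find_clusters(st, 1.5).n_clusters == 1

    def test_two_beads_beyond_cutoff_two_clusters(self):
        st = geometry_state([[0, 0, 0], [2, 0, 0]], chain_id=np.array([0, 1]))
        assert an.find_clusters(st, 1.5).n_clusters == 2

    def test_matches_union_find_oracle_on_random_frames(self):
        """Single-linkage partition equals a brute-force union-find."""
        rng = np.random.default_rng(8)
        for trial in range(3):
            n = 500
            box = np.array([12.0, 12.0, 12.0])
            pos = rng.uniform(0, 1, (n, 3)) * box
            st = SimulationState(
                pos, np.zeros(n, np.int8), box,
                np.empty((0, 2), np.int64), np.arange(n),
            )
            got = an.find_clusters(st, 1.5)
            # oracle: quadratic union-find
            parent = list(range(n))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[i] - pos[j]
                    d -= box * np.rint(d / box)
                    if np.dot(d, d) < 1.5**2:
                        parent[find(i)] = find(j)
            roots = [find(i) for i in range(n)]
            # same partition iff label arrays are identical up to renaming
            seen = {}
            for a, b in zip(got.labels, roots):
                if a in seen:
                    assert seen[a] == b
                else:
                    seen[a] = b
            assert len(set(seen.values())) == got.n_clusters

    def test_cluster_spanning_periodic_boundary(self):
        """Beads straddling the box face are one cluster, COM-consistent."""
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0.2, 5, 5], [9.8, 5, 5], [9.0, 5, 5]])
        st = SimulationState(pos, np.zeros(3, np.int8), box,
                             np.empty((0, 2), np.int64), np.arange(3))
        csr = an.find_clusters(st, 1.5)
        assert csr.n_clusters == 1
        unwrapped = an.cluster_positions(csr, 0)
        # contiguous embedding: max extent ~1.2 sigma, not ~9
        assert np.ptp(unwrapped[:, 0]) < 2.0


class TestGyration:
    def test_single_bead_zero(self):
        assert an.radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_beads_half_distance(self):
        d = 1.7
        pos = np.array([[0, 0, 0], [d, 0, 0]])
        assert an.radius_of_gyration(pos) == pytest.approx(d / 2)

    def test_matches_double_loop_formula(self):
        """Rg^2 = (1/2N^2) sum_ij |ri - rj|^2 (brute-force identity)."""
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(100, 3)) * 2.0
        rg = an.radius_of_gyration(pos)
        n = len(pos)
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += np.sum((pos[i] - pos[j]) ** 2)
        assert rg**2 == pytest.approx(acc / (2 * n * n), rel=1e-12)

    def test_shape_anisotropy_limits(self):
        rng = np.random.default_rng(3)
        line = np.column_stack([np.linspace(0, 10, 200), np.zeros(200), np.zeros(200)])
        _, _, k2_line = an.gyration(line)
        assert k2_line == pytest.approx(1.0, abs=1e-6)
        sphere = bl.hollow_sphere(2000, 5.0, jitter=0.0)
        _, _, k2_sphere = an.gyration(sphere)
        assert k2_sphere < 1e-4
        disk = bl.disk(4000, 6.0, thickness=0.0, seed=1)
        _, _, k2_disk = an.gyration(disk)
        assert k2_disk == pytest.approx(0.25, abs=0.02)


class TestDensityProfile:
    def test_beads_on_sphere_single_shell(self):
        pos = 3.1 * bl._fib_sphere(100)
        prof = an.density_profile(pos, np.ones(100, np.int8), 0.5,
                                  center=np.zeros(3))
        nz = np.flatnonzero(prof.counts)
        assert len(nz) == 1
        assert prof.edges[nz[0]] <= 3.1 < prof.edges[nz[0] + 1]
        assert prof.counts[nz[0]] == 100

    def test_uniform_ball_flat_profile(self):
        rng = np.random.default_rng(0)
        n = 200_000
        u = rng.uniform(0, 1, n) ** (1 / 3)
        pos = 5.0 * u[:, None] * bl._fib_sphere(n)
        prof = an.density_profile(pos, np.ones(n, np.int8), 0.5,
                                  center=np.zeros(3))
        inner = prof.density[2:9]  # skip the noisiest central shells
        assert np.abs(inner / inner.mean() - 1).max() < 0.05

    def test_densities_nonnegative_and_shells_equal_width(self):
        pos, species = bl.vesicle_fixture()
        prof = an.density_profile(pos, species, 0.25, center=np.zeros(3))
        assert np.all(prof.density >= 0)
        assert np.allclose(np.diff(prof.edges), 0.25)


class TestVesicleMetrics:
    def _double_gaussian(self):
        edges = np.arange(0, 8.25, 0.25)
        r = 0.5 * (edges[:-1] + edges[1:])
        rho = np.exp(-((r - 2) / 0.4) ** 2) + np.exp(-((r - 5) / 0.4) ** 2)
        return an.DensityProfile(edges, rho, (100 * rho).astype(int), rho + 0.5)

    def test_thickness_from_double_gaussian(self):
        m = an.vesicle_metrics(self._double_gaussian())
        assert m["membrane_thickness"] == pytest.approx(3.0, abs=0.25)
        assert m["inner_peak_radius"] == pytest.approx(2.0, abs=0.13)
        assert m["outer_peak_radius"] == pytest.approx(5.0, abs=0.13)

    def test_single_peak_raises(self):
        edges = np.arange(0, 8.25, 0.25)
        r = 0.5 * (edges[:-1] + edges[1:])
        rho = np.exp(-((r - 3) / 0.5) ** 2)
        with pytest.raises(an.NotSphericalVesicleError):
            an.vesicle_metrics(
                an.DensityProfile(edges, rho, (100 * rho).astype(int), rho)
            )

    def test_constructed_vesicle_fixture_metrics(self):
        pos, species = bl.vesicle_fixture(radius=4.0, shell=0.8)
        prof = an.density_profile(pos, species, 0.25, center=np.zeros(3))
        m = an.vesicle_metrics(prof)
        assert m["membrane_thickness"] == pytest.approx(1.6, abs=0.3)
        assert m["outer_peak_radius"] == pytest.approx(4.8, abs=0.3)


class TestBackboneEndToEnd:
    def test_straight_backbone(self):
        top = cs.make_topology(4, 0, 0)
        pos = np.column_stack([
            np.arange(4) * 0.97, np.zeros(4), np.zeros(4)
        ]) + 20
        st = SimulationState(pos, top.species, BIGBOX, top.bonds)
        stats = an.backbone_end_to_end(st, 4)
        assert stats["end_to_end_mean"] == pytest.approx(3 * 0.97)
        assert stats["contour_mean"] == pytest.approx(3 * 0.97)

    def test_folded_chain_ends_coincide(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                        [0, 0.0, 0.5], [0, 0, 0]], float)[:5] + 20
        top = cs.make_topology(5, 0, 0)
        pos[4] = pos[0]  # ends coincide
        st = SimulationState(pos, top.species, BIGBOX, top.bonds)
        assert an.backbone_end_to_end(st, 5)["end_to_end_mean"] == pytest.approx(0.0)

    def test_single_bead_defined_as_zero(self):
        top = cs.make_topology(1, 0, 0)
        st = SimulationState(np.zeros((1, 3)) + 20, top.species, BIGBOX, top.bonds)
        assert an.backbone_end_to_end(st, 1)["end_to_end_mean"] == 0.0

    def test_chain_across_periodic_boundary(self):
        """Bond-walk unwrapping gives the physical distance, not the image."""
        box = np.array([10.0, 10.0, 10.0])
        top = cs.make_topology(4, 0, 0)
        xs = np.array([9.0, 9.9, 0.8, 1.7])  # crosses the x face
        pos = np.column_stack([xs, np.full(4, 5.0), np.full(4, 5.0)])
        st = SimulationState(pos, top.species, box, top.bonds)
        assert an.backbone_end_to_end(st, 4)["end_to_end_mean"] == pytest.approx(2.7, abs=1e-9)


class TestClassifier:
    @pytest.mark.parametrize("name", ["vesicle", "toroid", "cylinder", "sheet", "bowl"])
    def test_constructed_geometries_under_rotation(self, name):
        """Each fixture labels correctly across random rotations."""
        rng = np.random.default_rng(17)
        if name == "vesicle":
            pos, species = bl.vesicle_fixture()
        else:
            pos = {
                "toroid": bl.ring, "cylinder": bl.rod,
                "sheet": bl.disk, "bowl": bl.spherical_cap,
            }[name]()
            species = None
        for _ in range(25):
            p = np.asarray(pos) @ random_rotation(rng).T
            st = geometry_state(p, species)
            rep = an.classify(an.find_clusters(st, 1.5))
            assert rep.label == name

    def test_dispersed_when_no_majority_cluster(self):
        rng = np.random.default_rng(4)
        # 40 single-bead "chains" far apart
        pos = rng.uniform(5, 35, (40, 3))
        st = geometry_state(pos - 20, chain_id=np.arange(40))
        rep = an.classify(an.find_clusters(st, 1.5))
        assert rep.label == "dispersed"

    def test_observables_translation_invariant(self):
        pos, species = bl.vesicle_fixture()
        st1 = geometry_state(pos, species)
        st2 = geometry_state(np.asarray(pos) + np.array([40.0, -80.0, 40.0]),
                             species)
        r1 = an.classify(an.find_clusters(st1, 1.5))
        r2 = an.classify(an.find_clusters(st2, 1.5))
        assert r1.label == r2.label
        assert r1.rg == pytest.approx(r2.rg, abs=1e-9)


class TestTimelinesAndPhases:
    def _traj_of(self, geoms):
        frames = []
        species = None
        for g in geoms:
            pos, sp = g
            frames.append(np.asarray(pos) + BIGBOX / 2)
            species = sp
        return cs.Trajectory(
            frames=frames, steps=list(range(len(frames))),
            species=species, box=BIGBOX,
            bonds=np.empty((0, 2), np.int64),
            chain_id=np.zeros(len(frames[0]), np.int64),
        )

    def test_static_sheet_single_entry(self):
        d = bl.disk()
        traj = self._traj_of([(d, np.zeros(len(d), np.int8))] * 6)
        tl = an.pathway_timeline(traj, window=3)
        assert len(tl) == 1
        assert tl[0][0] == "sheet"

    def test_sheet_bowl_vesicle_sequence_detected(self):
        seq = (
            [bl.sheet_fixture(seed=s) for s in range(4)]
            + [bl.bowl_fixture(seed=s) for s in range(4)]
            + [bl.vesicle_fixture(seed=s) for s in range(4)]
        )
        tl = an.pathway_timeline(self._traj_of(seq), window=3)
        labels = [t[0] for t in tl]
        assert labels == ["sheet", "bowl", "vesicle"]

    def test_stability_criterion(self):
        rng = np.random.default_rng(0)
        assert an.is_stable(np.r_[np.linspace(9, 5, 50), 5 + 0.02 * rng.normal(size=50)])
        assert not an.is_stable(np.linspace(9, 3, 100))

    def test_phase_point_coexistence_reduction(self):
        out = an.phase_point_label(
            ["vesicle", "vesicle", "bowl", "sheet", "vesicle", "bowl"],
            coexist_fraction=0.25,
        )
        assert out["label"] == "coexistence"
        assert set(out["coexistence"]) == {"vesicle", "bowl"}
        single = an.phase_point_label(["cylinder"] * 5 + ["toroid"])
        assert single["label"] == "cylinder"
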