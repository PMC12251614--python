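"""FENE and shifted-LJ potentials, forces, and their consistency."""

import numpy as np
import pytest

import combsim as cs
from combsim.builder import _grow_chain
from combsim.forcefield import (
    WCA_CUTOFF,
    BrokenBondError,
    PairTable,
    fene_energy,
    lj_energy,
    total_energy_forces,
)


class TestFENE:
    def test_zero_extension_is_zero_energy(self):
        assert fene_energy(0.0) == 0.0

    def test_value_at_half_sigma(self):
        # -0.5 * 30 * 1.5^2 * ln(1 - (0.5/1.5)^2)
        assert fene_energy(0.5) == pytest.approx(3.975, abs=1e-3)

    def test_divergence_near_maximum_extension(self):
        # -33.75 ln(1 - (r/R0)^2) grows without bound as r -> R0
        assert fene_energy(1.4999) == pytest.approx(301.14, rel=1e-3)
        assert fene_energy(1.4999999) > fene_energy(1.4999) > fene_energy(1.49)

    def test_broken_bond_is_hard_error(self):
        with pytest.raises(BrokenBondError):
            fene_energy(1.5)
        with pytest.raises(BrokenBondError):
            fene_energy(2.0)

    def test_strictly_increasing(self):
        r = np.linspace(0.01, 1.45, 200)
        u = fene_energy(r)
        assert np.all(np.diff(u) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cs.FENEParams(kappa=-1)
        with pytest.raises(ValueError):
            cs.FENEParams(R0=0)


class TestShiftedLJ:
    def test_wca_pairs_zero_at_cutoff_minimum(self):
        # B-B and A-B are cut at the LJ minimum: purely repulsive (WCA)
        assert lj_energy(WCA_CUTOFF, ("B", "B")) == pytest.approx(0.0, abs=1e-12)
        assert lj_energy(WCA_CUTOFF, ("A", "B")) == pytest.approx(0.0, abs=1e-12)

    def test_aa_minimum_value(self):
        # -1 (unshifted minimum) minus U_unshifted(2.5) = -0.98368
        assert lj_energy(WCA_CUTOFF, ("A", "A")) == pytest.approx(-0.98368, abs=1e-5)

    def test_zero_beyond_all_cutoffs(self):
        for pair in (("A", "A"), ("A", "B"), ("B", "B")):
            assert lj_energy(3.0, pair) == 0.0

    @pytest.mark.parametrize("pair", [("A", "A"), ("A", "B"), ("B", "B")])
    def test_continuity_at_cutoff(self, pair, default_table):
        rc = default_table.rc[
            0 if pair[0] == "A" else 1, 0 if pair[1] == "A" else 1
        ]
        assert abs(lj_energy(rc - 1e-9, pair)) < 1e-6

    def test_species_asymmetry(self):
        """A-A keeps an attractive well; A-B and B-B are repulsive everywhere."""
        r = np.linspace(0.8, 3.0, 500)
        assert lj_energy(r, ("A", "A")).min() < -0.9
        assert np.all(lj_energy(r, ("A", "B")) >= 0)
        assert np.all(lj_energy(r, ("B", "B")) >= 0)

    def test_asymmetric_table_rejected(self):
        eps = np.ones((2, 2))
        eps[0, 1] = 2.0
        with pytest.raises(ValueError):
            PairTable(epsilon=eps)


class TestTotalForce:
    def test_lj_minimum_pair_has_zero_force(self):
        pos = np.array([[5.0, 5.0, 5.0], [5.0 + WCA_CUTOFF, 5.0, 5.0]])
        f = cs.total_force(
            pos, np.zeros(2, np.int8), [20.0] * 3, np.empty((0, 2), int)
        )
        assert np.linalg.norm(f, axis=1) == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_newtons_third_law_and_translational_invariance(self):
        rng = np.random.default_rng(5)
        top = cs.make_topology(8, 2, 3, seed=2)
        pos = _grow_chain(top, rng) + 10.0
        _, f = total_energy_forces(pos, top.species, [20.0] * 3, top.bonds)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    @pytest.mark.parametrize("exclude_bonded", [False, True])
    def test_forces_match_finite_differences(self, exclude_bonded):
        """Analytic gradient vs central differences on random 20-bead combs."""
        h = 1e-6
        box = np.array([20.0] * 3)
        worst = 0.0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            top = cs.make_topology(8, 2, 3, seed=seed)
            pos = _grow_chain(top, rng) + 10.0
            e0, f = total_energy_forces(
                pos, top.species, box, top.bonds,
                exclude_bonded_lj=exclude_bonded,
            )
            fnum = np.zeros_like(f)
            for i in range(len(pos)):
                for k in range(3):
                    p = pos.copy()
                    p[i, k] += h
                    ep, _ = total_energy_forces(
                        p, top.species, box, top.bonds,
                        exclude_bonded_lj=exclude_bonded,
                    )
                    p[i, k] -= 2 * h
                    em, _ = total_energy_forces(
                        p, top.species, box, top.bonds,
                        exclude_bonded_lj=exclude_bonded,
                    )
                    fnum[i, k] = -(ep - em) / (2 * h)
            scale = np.abs(f).max()
            worst = max(worst, np.abs(f - fnum).max() / scale)
        assert worst < 1e-5

    def test_distant_unbonded_beads_feel_nothing(self):
        pos = np.array([[2.0, 2.0, 2.0], [8.0, 8.0, 8.0]])
        f = cs.total_force(
            pos, np.zeros(2, np.int8), [20.0] * 3, np.empty((0, 2), int)
        )
        assert np.all(f == 0)

    def test_overlapping_beads_error_names_pair(self):
        pos = np.zeros((2, 3)) + 5.0
        with pytest.raises(Exception, match="overlap"):
            total_energy_forces(
                pos, np.zeros(2, np.int8), [20.0] * 3, np.empty((0, 2), int)
            )

    def test_bonded_lj_switch_changes_equilibrium_bond(self):
        """With the LJ core on bonded pairs the FENE+LJ minimum sits near
        0.97 sigma; excluding it moves the minimum to r=0."""
        r = np.linspace(0.7, 1.2, 2001)
        u_with = cs.fene_energy(r) + lj_energy(r, ("A", "A"))
        assert r[np.argmin(u_with)] == pytest.approx(0.97, abs=0.01)


class TestNeighbourLists:
    def test_cell_list_matches_brute_force(self, default_table):
        from combsim import kernels

        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 400
            box = np.array([9.0, 11.0, 10.0])
            pos = rng.uniform(0, 1, (n, 3)) * box
            species = rng.integers(0, 2, n).astype(np.int8)
            lc2 = default_table.rc**2
            bi, bj = kernels.brute_pair_list(pos, species, box, lc2)
            ci, cj = kernels.cell_pair_list(pos, species, box, lc2)
            brute = set(zip(bi.tolist(), bj.tolist()))
            cell = set(zip(ci.tolist(), cj.tolist()))
            assert brute == cell

    def test_forces_identical_cell_vs_brute(self, default_table):
        rng = np.random.default_rng(1)
        n = 500
        box = np.array([12.0] * 3)
        # non-overlapping random beads
        pos = rng.uniform(0, 1, (n * 3, 3)) * box
        keep = [0]
        for i in range(1, len(pos)):
            d = pos[i] - pos[keep]
            d -= box * np.rint(d / box)
            if (np.linalg.norm(d, axis=1) > 0.85).all():
                keep.append(i)
            if len(keep) == n:
                break
        pos = pos[keep]
        species = rng.integers(0, 2, len(pos)).astype(np.int8)
        bonds = np.empty((0, 2), int)
        e1, f1 = total_energy_forces(pos, species, box, bonds, brute_force=True)
        e2, f2 = total_energy_forces(pos, species, box, bonds, brute_force=False)
        assert e1 == e2
        assert np.array_equal(f1, f2)

    def test_minimum_image_lattice_shift_invariance(self):
        rng = np.random.default_rng(3)
        top = cs.make_topology(8, 1, 2, seed=4)
        pos = _grow_chain(top, rng) + 10.0
        box = np.array([20.0] * 3)
        e0, f0 = total_energy_forces(pos, top.species, box, top.bonds)
        for shift in ([20, 0, 0], [0, -40, 20], [60, 60, 60]):
            e1, f1 = total_energy_forces(
                pos + np.array(shift, float), top.species, box, top.bonds
            )
            assert abs(e1 - e0) < 1e-9
            assert np.abs(f1 - f0).max() < 1e-9


class TestPotentialProperties:
    def test_shift_makes_every_random_pair_table_continuous(self):
        """For arbitrary (epsilon, sigma, rc) tables the shifted potential
        vanishes continuously at its cutoff and is finite inside it."""
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=50, deadline=None)
        @given(
            eps=st.floats(0.1, 5.0),
            sig=st.floats(0.5, 2.0),
            rc_factor=st.floats(1.05, 3.0),
        )
        def check(eps, sig, rc_factor):
            rc = rc_factor * sig
            table = PairTable(
                epsilon=np.full((2, 2), eps),
                sigma=np.full((2, 2), sig),
                rc=np.full((2, 2), rc),
            )
            assert abs(lj_energy(rc - 1e-9 * sig, ("A", "A"), table)) < 1e-5
            assert lj_energy(rc, ("A", "A"), table) == 0.0
            r = np.linspace(0.8 * sig, rc * 0.999, 50)
            assert np.all(np.isfinite(lj_energy(r, ("A", "B"), table)))

        check()

    def test_fene_energy_monotone_for_random_parameters(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=50, deadline=None)
        @given(kappa=st.floats(1.0, 100.0), r0=st.floats(0.5, 3.0))
        def check(kappa, r0):
            p = cs.FENEParams(kappa=kappa, R0=r0)
            r = np.linspace(0, 0.999 * r0, 100)
            u = fene_energy(r, p)
            assert u[0] == 0.0
            assert np.all(np.diff(u) > 0)

        check()
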