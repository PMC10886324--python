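"""MM-GBSA: Born radii, GB energies, MM terms, binding free energy limits."""

import numpy as np
import pytest

from pepmem import memsynth
from pepmem.gbsa import (
    COULOMB_K,
    GBParams,
    free_energy,
    gb_effective_radii,
    gb_polar_energy,
    mm_energy,
    mmgbsa_binding,
    nonpolar_energy,
)
from pepmem.mdio import Trajectory

from conftest import make_atoms

PARAMS = GBParams()


def grid_descreening_radius(xyz, radii, i, scale=0.8, spacing=0.15):
    """Quadrature oracle for the pairwise-descreening Born integral.

    1/R_i = 1/rho_i - (1/4pi) * integral of r^-4 over the union of the other
    atoms' descreening spheres (radius scale*rho_j), excluding atom i's own
    sphere.  Direct 3D grid integration; independent of the closed form.
    """
    lo = xyz.min(axis=0) - radii.max() - 1.0
    hi = xyz.max(axis=0) + radii.max() + 1.0
    axes = [np.arange(lo[d], hi[d], spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.zeros(len(pts), dtype=bool)
    for j in range(len(xyz)):
        if j == i:
            continue
        inside |= ((pts - xyz[j]) ** 2).sum(axis=1) < (scale * radii[j]) ** 2
    r2 = ((pts - xyz[i]) ** 2).sum(axis=1)
    inside &= r2 > radii[i] ** 2  # outside own sphere
    integral = (1.0 / r2[inside] ** 2).sum() * spacing**3 / (4.0 * np.pi)
    return 1.0 / (1.0 / radii[i] - integral)


class TestBornRadii:
    def test_isolated_atom_effective_equals_intrinsic(self):
        top, fr = make_atoms([[0, 0, 0]], gb_radius=1.7)
        assert gb_effective_radii(top, fr)[0] == pytest.approx(1.7, abs=1e-12)

    def test_descreening_increases_both_radii(self):
        top, fr = make_atoms([[0, 0, 0], [3.5, 0, 0]], gb_radius=2.0)
        r = gb_effective_radii(top, fr)
        assert (r > 2.0).all()

    def test_cluster_matches_grid_integration_oracle(self):
        rng = np.random.default_rng(8)
        xyz = rng.uniform(0, 7.0, size=(10, 3))
        radii = rng.uniform(1.5, 2.0, size=10)
        top, fr = make_atoms(xyz, gb_radius=radii)
        r_eff = gb_effective_radii(top, fr)
        for i in (0, 4, 9):
            oracle = grid_descreening_radius(xyz, radii, i)
            assert r_eff[i] == pytest.approx(oracle, rel=0.10)

    def test_nonpositive_radius_rejected(self):
        top, fr = make_atoms([[0, 0, 0]], gb_radius=1.0)
        top.gb_radius[0] = -1.0
        with pytest.raises(ValueError):
            gb_effective_radii(top, fr)


class TestPolarEnergy:
    def test_single_ion_analytic_born(self):
        a = 2.0
        top, fr = make_atoms([[0, 0, 0]], charge=1.0, gb_radius=a)
        expect = -COULOMB_K * (1.0 - 1.0 / 78.5) / (2.0 * a)
        assert gb_polar_energy(top, fr) == pytest.approx(expect, rel=1e-6)
        assert expect == pytest.approx(-81.958, abs=1e-3)

    def test_zero_charges_zero_energy(self):
        top, fr = make_atoms([[0, 0, 0], [3, 0, 0]], charge=0.0)
        assert gb_polar_energy(top, fr) == 0.0

    def test_far_separation_approaches_born_sum(self):
        a = 2.0
        born1 = -COULOMB_K * (1.0 - 1.0 / 78.5) / (2.0 * a)
        top, fr = make_atoms([[0, 0, 0], [600.0, 0, 0]], charge=[1.0, -1.0],
                             gb_radius=a, box=(2000, 2000, 2000))
        e = gb_polar_energy(top, fr)
        # cross term decays as 1/r; at 600 A it contributes ~0.5 kcal/mol
        assert e == pytest.approx(2 * born1, abs=1.0)

    def test_salt_screening_strengthens_solvation(self):
        top, fr = make_atoms([[0, 0, 0]], charge=1.0, gb_radius=2.0)
        screened = gb_polar_energy(top, fr, params=GBParams(kappa=0.125))
        assert screened < gb_polar_energy(top, fr)


class TestMMEnergy:
    def test_lj_minimum_is_minus_epsilon(self):
        eps, rmin_h = 0.21, 1.9
        top, fr = make_atoms([[0, 0, 0], [2 * rmin_h, 0, 0]],
                             lj_epsilon=eps, lj_rmin_half=rmin_h)
        _, lj, _ = mm_energy(top, fr)
        assert lj == pytest.approx(-eps, abs=1e-12)

    def test_lj_zero_at_sigma(self):
        rmin_h = 1.9
        sigma = 2 * rmin_h / 2 ** (1 / 6)
        top, fr = make_atoms([[0, 0, 0], [sigma, 0, 0]], lj_rmin_half=rmin_h)
        _, lj, _ = mm_energy(top, fr)
        assert lj == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_pair_oracle(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(0, 12.0, size=(20, 3))
        q = rng.normal(size=20)
        eps = rng.uniform(0.05, 0.3, size=20)
        rmh = rng.uniform(1.0, 2.0, size=20)
        bonds = [[0, 1], [2, 3]]
        bk, br = [7.0, 3.0], [1.5, 2.0]
        top, fr = make_atoms(xyz, charge=q, lj_epsilon=eps, lj_rmin_half=rmh,
                             bonds=bonds, bond_k=bk, bond_r0=br)
        bonded, lj, coul = mm_energy(top, fr)
        eb = el = ec = 0.0
        for (i, j), k, r0 in zip(bonds, bk, br):
            eb += k * (np.linalg.norm(xyz[i] - xyz[j]) - r0) ** 2
        for i in range(20):
            for j in range(i + 1, 20):
                if [i, j] in bonds:
                    continue
                r = np.linalg.norm(xyz[i] - xyz[j])
                e = np.sqrt(eps[i] * eps[j])
                rm = rmh[i] + rmh[j]
                el += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
                ec += COULOMB_K * q[i] * q[j] / r
        assert bonded == pytest.approx(eb, abs=1e-8)
        assert lj == pytest.approx(el, abs=1e-8)
        assert coul == pytest.approx(ec, abs=1e-8)


@pytest.fixture(scope="module")
def bound_system():
    p = __import__("pepmem.seqdesc", fromlist=["parse_peptide"]).parse_peptide(
        "YCPYGNRLNYWSRARGHIGTKSCRRSY", amidated=True, disulfides=((2, 23),))
    mem = memsynth.build_membrane(memsynth.membrane_spec("gn", 16), seed=4)
    pep = memsynth.build_peptide_model(p)
    scen = memsynth.AdsorptionScenario(n_frames=6, tau_ns=0.5, depth_nm=0.42,
                                       jitter_sigma=0.0, seed=4)
    return memsynth.generate_trajectory(*mem, *pep, scen)


class TestBinding:
    def test_two_neutral_noninteracting_particles_give_minus_b(self):
        top, fr = make_atoms([[0, 0, 0], [0, 0, 200.0]], segment=["MEMB", "PEP"],
                             name=["P", "CA"], charge=0.0, lj_epsilon=0.0,
                             box=(1000, 1000, 1000))
        traj = Trajectory(np.repeat(fr.coords[None], 2, axis=0), [0.0, 1.0], fr.box)
        bfe = mmgbsa_binding(top, traj, window_ns=1e9)
        assert bfe.mean == pytest.approx(-PARAMS.b, abs=1e-9)
        assert bfe.sem == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_identity(self, bound_system):
        top, traj, _ = bound_system
        e = free_energy(top, traj[-1], top.segment == "PEP", t_ds=0.7)
        assert e.g_tot == pytest.approx(
            e.bonded + e.lj + e.coulomb + e.g_pol + e.g_np - 0.7, abs=1e-12)

    def test_bonded_terms_cancel_in_delta(self, bound_system):
        top, traj, _ = bound_system
        bfe = mmgbsa_binding(top, traj, window_ns=2.0)
        np.testing.assert_allclose(bfe.terms["bonded"], 0.0, atol=1e-8)

    def test_delta_hmm_is_intersegment_only(self, bound_system):
        # single-trajectory cancellation: dH_MM equals the intersegment
        # LJ + Coulomb computed directly across the two groups
        top, traj, _ = bound_system
        fr = traj[-1]
        pep = np.nonzero(top.segment == "PEP")[0]
        memb = np.nonzero(top.segment == "MEMB")[0]
        lj = coul = 0.0
        for i in pep:
            r = np.linalg.norm(fr.coords[memb] - fr.coords[i], axis=1)
            e = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[memb])
            rm = top.lj_rmin_half[i] + top.lj_rmin_half[memb]
            lj += float((e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)).sum())
            coul += float((COULOMB_K * top.charge[i] * top.charge[memb] / r).sum())
        e_c = free_energy(top, fr, None)
        e_m = free_energy(top, fr, top.segment == "MEMB")
        e_p = free_energy(top, fr, top.segment == "PEP")
        d_hmm = e_c.h_mm - e_m.h_mm - e_p.h_mm
        assert d_hmm == pytest.approx(lj + coul, abs=1e-8)

    def test_rigid_motion_invariance_of_dg(self, bound_system):
        # MM and GB terms are analytic (translation AND rotation exact);
        # the SASA term inherits the fixed-point-set discretisation noise
        # under rotation, bounded by gamma * area-noise ~ 0.05 kcal/mol
        top, traj, _ = bound_system
        last = Trajectory(traj.coords[-1:], traj.times[-1:], traj.box)
        theta = 0.6
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        params = GBParams(sasa_points=480)
        g1 = mmgbsa_binding(top, last, window_ns=1e9, params=params).mean
        shifted = Trajectory(traj.coords[-1:] + np.array([5.0, -3.0, 8.0]),
                             traj.times[-1:], traj.box)
        g_shift = mmgbsa_binding(top, shifted, window_ns=1e9, params=params).mean
        assert g_shift == pytest.approx(g1, abs=1e-6)
        rotated = Trajectory(traj.coords[-1:] @ rot.T, traj.times[-1:], traj.box)
        g_rot = mmgbsa_binding(top, rotated, window_ns=1e9, params=params).mean
        assert g_rot == pytest.approx(g1, abs=0.05)

    def test_charged_bead_near_anionic_head_binds_tighter(self):
        def dg(z):
            top, fr = make_atoms([[0, 0, 0], [0, 0, z]], segment=["MEMB", "PEP"],
                                 name=["P", "CA"], charge=[-1.0, 1.0],
                                 lj_epsilon=0.0, box=(1000, 1000, 1000))
            traj = Trajectory(fr.coords[None], [0.0], fr.box)
            return mmgbsa_binding(top, traj, window_ns=1e9).mean

        assert dg(3.0) < dg(50.0)

    def test_identical_frames_zero_sem(self, bound_system):
        top, traj, _ = bound_system
        rep = Trajectory(np.repeat(traj.coords[-1:], 3, axis=0),
                         np.arange(3.0), traj.box)
        bfe = mmgbsa_binding(top, rep, window_ns=1e9)
        assert bfe.sem == pytest.approx(0.0, abs=1e-10)


class TestNonpolarModel:
    def test_constants_surface_analytically(self):
        # gamma and b recovered from two sphere sizes: E = gamma*A + b
        from pepmem.surfgeo import sasa

        tops = [make_atoms([[0, 0, 0]], gb_radius=r) for r in (1.5, 3.0)]
        es = [nonpolar_energy(t, f) for t, f in tops]
        areas = [sasa(t, f).total for t, f in tops]
        gamma = (es[1] - es[0]) / (areas[1] - areas[0])
        b = es[0] - gamma * areas[0]
        assert gamma == pytest.approx(0.00542, abs=1e-12)
        assert b == pytest.approx(0.92, abs=1e-9)

    def test_gbparams_validation(self):
        with pytest.raises(ValueError):
            GBParams(eps_out=0.5)
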