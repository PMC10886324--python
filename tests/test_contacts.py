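"""Contact maps, occupancy semantics, hydrogen-bond detection and timelines."""

import numpy as np
import pytest

from pepmem import memsynth
from pepmem.contacts import (
    contact_map,
    detect_hbonds,
    hbond_timeline,
    residue_occupancy,
)
from pepmem.mdio import Trajectory

from conftest import make_atoms


def brute_force_contacts(top, frame, cutoff=3.0):
    """O(N^2) oracle over all heavy peptide/membrane atom pairs."""
    heavy = top.element != "H"
    pep = np.nonzero(heavy & (top.segment == "PEP"))[0]
    memb = np.nonzero(heavy & (top.segment == "MEMB"))[0]
    out = set()
    for i in pep:
        for j in memb:
            if np.linalg.norm(frame.coords[i] - frame.coords[j]) <= cutoff:
                out.add((int(top.resid[i]), int(top.molid[j])))
    return out


def residue_with_k_lipids(k, n_frames=5):
    """One peptide residue bead permanently touching k lipid beads."""
    coords = [[0.0, 0.0, 0.0]]
    seg, name, resid, molid = ["PEP"], ["CA"], [1], [0]
    for j in range(k):
        coords.append([2.0 * np.cos(2 * np.pi * j / max(k, 1)),
                       2.0 * np.sin(2 * np.pi * j / max(k, 1)), -1.5])
        seg.append("MEMB")
        name.append("P")
        resid.append(j + 1)
        molid.append(j + 1)
    top, fr = make_atoms(coords, segment=seg, name=name, resid=resid, molid=molid)
    traj = Trajectory(np.repeat(fr.coords[None], n_frames, axis=0),
                      np.arange(float(n_frames)), fr.box)
    return top, traj


class TestContactMap:
    def test_matches_brute_force_oracle(self, adsorbed_system):
        top, traj, _ = adsorbed_system
        fr = traj[-1]
        assert contact_map(top, fr) == brute_force_contacts(top, fr)

    def test_empty_when_far_apart(self):
        top, fr = make_atoms([[0, 0, 0], [0, 0, 10.0]], segment=["PEP", "MEMB"],
                             name=["CA", "P"])
        assert contact_map(top, fr) == set()

    def test_planted_pairs_recovered_exactly(self, gn_membrane, cidem_model):
        scen = memsynth.AdsorptionScenario(n_frames=8, tau_ns=0.5, depth_nm=0.42,
                                           jitter_sigma=0.0, seed=2,
                                           planted_contacts=((13, 2), (7, 1)))
        top, traj, gt = memsynth.generate_trajectory(*gn_membrane, *cidem_model, scen)
        for fi in (0, 4, 7):
            assert contact_map(top, traj[fi]) == gt.contacts[fi]

    def test_hydrogens_excluded(self):
        # H within cutoff but no heavy atom pair: no contact
        top, fr = make_atoms([[0, 0, 0], [0, 0, 2.0], [0, 0, 6.0]],
                             segment=["PEP", "PEP", "MEMB"],
                             element=["C", "H", "P"], name=["CA", "HS", "P"],
                             resid=[1, 1, 1], molid=[0, 0, 1])
        fr.coords[1] = [0, 0, 4.0]  # H 2 A from lipid
        assert contact_map(top, fr, cutoff=3.0) == set()


class TestOccupancySemantics:
    @pytest.mark.parametrize("k,expected", [(2, 200.0), (3, 300.0)])
    def test_permanent_k_lipids_is_100k_percent(self, k, expected):
        top, traj = residue_with_k_lipids(k)
        prof = residue_occupancy(top, traj, window_ns=1e9)
        assert prof.occupancy[0] == pytest.approx(expected)

    def test_no_contacts_zero_occupancy(self):
        top, fr = make_atoms([[0, 0, 0], [0, 0, 30.0]], segment=["PEP", "MEMB"],
                             name=["CA", "P"])
        traj = Trajectory(np.repeat(fr.coords[None], 3, axis=0),
                          np.arange(3.0), fr.box)
        prof = residue_occupancy(top, traj, window_ns=1e9)
        assert prof.occupancy[0] == 0.0

    def test_lipid_type_split_sums_to_total(self, adsorbed_system):
        top, traj, _ = adsorbed_system
        prof = residue_occupancy(top, traj, window_ns=20.0)
        split_sum = sum(prof.by_lipid_type.values())
        np.testing.assert_allclose(split_sum, prof.occupancy, atol=1e-9)

    def test_frame_reordering_invariance(self, adsorbed_system):
        top, traj, _ = adsorbed_system
        win = traj.window(20.0)
        prof1 = residue_occupancy(top, win, window_ns=1e9)
        rev = Trajectory(win.coords[::-1].copy(), win.times, win.box)
        prof2 = residue_occupancy(top, rev, window_ns=1e9)
        np.testing.assert_allclose(prof1.occupancy, prof2.occupancy, atol=1e-12)


def ideal_hbond_system(angle_deg=180.0, d_da=2.8):
    """Donor(O)-H...acceptor(O) with controllable angle at H."""
    d = [0.0, 0.0, 0.0]
    h = [0.0, 0.0, -1.0]
    theta = np.radians(180.0 - angle_deg)
    a = [np.sin(theta) * (d_da - 1.0), 0.0, -1.0 - np.cos(theta) * (d_da - 1.0)]
    top, fr = make_atoms(
        [d, h, a], segment=["PEP", "PEP", "MEMB"], element=["O", "H", "O"],
        name=["SP", "HP", "P"], resid=[1, 1, 1], molid=[0, 0, 1],
        hbond_role=["donor-heavy", "polar-H", "acceptor"],
        bonds=[[0, 1]], bond_k=[10.0], bond_r0=[1.0])
    return top, fr


class TestHydrogenBonds:
    def test_ideal_linear_geometry_detected(self):
        top, fr = ideal_hbond_system(angle_deg=180.0, d_da=2.8)
        assert detect_hbonds(top, fr) == [(0, 1, 2)]

    def test_bent_geometry_rejected(self):
        top, fr = ideal_hbond_system(angle_deg=90.0, d_da=2.0)
        assert detect_hbonds(top, fr) == []

    def test_distance_cutoff(self):
        top, fr = ideal_hbond_system(angle_deg=180.0, d_da=3.6)
        assert detect_hbonds(top, fr) == []
        assert detect_hbonds(top, fr, d_max=3.8) == [(0, 1, 2)]

    def test_orphan_polar_h_is_topology_error(self):
        top, fr = make_atoms([[0, 0, 0], [0, 0, 3.0]], segment=["PEP", "MEMB"],
                             element=["H", "O"], name=["HP", "P"],
                             hbond_role=["polar-H", "acceptor"], molid=[0, 1])
        with pytest.raises(ValueError, match="donor-heavy"):
            detect_hbonds(top, fr)

    def test_planted_bond_recovered_exactly(self, gn_membrane, cidem_model):
        scen = memsynth.AdsorptionScenario(n_frames=8, tau_ns=0.5, depth_nm=0.42,
                                           jitter_sigma=0.0, seed=2,
                                           planted_hbonds=(24,))
        top, traj, gt = memsynth.generate_trajectory(*gn_membrane, *cidem_model, scen)
        for fi in (0, 7):
            assert set(detect_hbonds(top, traj[fi])) == gt.hbonds[fi]


class TestTimeline:
    def test_persistent_bond_gives_full_row(self):
        top, fr = ideal_hbond_system()
        traj = Trajectory(np.repeat(fr.coords[None], 4, axis=0),
                          np.arange(4.0), fr.box)
        resids, matrix, counts = hbond_timeline(top, traj)
        assert matrix[0].all() and (counts == 1).all()

    def test_no_polar_sites_all_false(self, gn_membrane):
        top_m, fr_m = gn_membrane
        pep, frp = make_atoms([[0, 0, 40.0]], segment="PEP", name="CA")
        from pepmem.memsynth import _merge

        top = _merge(top_m, pep)
        xyz = np.vstack([fr_m.coords, frp.coords])
        traj = Trajectory(np.repeat(xyz[None], 2, axis=0), [0.0, 1.0], fr_m.box)
        _, matrix, counts = hbond_timeline(top, traj)
        assert not matrix.any() and (counts == 0).all()

    def test_column_sums_consistent_with_detection(self, gn_membrane, cidem_model):
        scen = memsynth.AdsorptionScenario(n_frames=6, tau_ns=0.5, depth_nm=0.42,
                                           jitter_sigma=0.0, seed=2,
                                           planted_hbonds=(24, 21))
        top, traj, _ = memsynth.generate_trajectory(*gn_membrane, *cidem_model, scen)
        resids, matrix, counts = hbond_timeline(top, traj)
        for fi, fr in enumerate(traj):
            bonds = detect_hbonds(top, fr)
            assert counts[fi] == len(bonds)
            marked = {int(top.resid[d]) for d, h, a in bonds}
            assert set(resids[matrix[:, fi]]) == marked
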