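"""Residue-lipid contacts, hydrogen bonds, occupancies and timelines.

A "contact" is a (peptide residue, lipid molecule) pair with any heavy-atom
distance within the cutoff (default 3 A); counting distinct lipid molecules
rather than atom pairs is what lets per-residue occupancy exceed 100% when
a residue bridges several lipids at once (200% = two lipids every frame,
and so on).  Hydrogen bonds use the common MD geometric criterion:
donor-heavy-to-acceptor distance <= 3.5 A and donor-H-acceptor angle
>= 150 deg, donor and acceptor in different segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mdio import Frame, Topology, Trajectory

__all__ = [
    "ResidueContactProfile",
    "contact_map",
    "detect_hbonds",
    "residue_occupancy",
    "hbond_timeline",
]


@dataclass
class ResidueContactProfile:
    """Per-residue occupancies over a trailing window plus per-frame series.

    ``occupancy`` is 100 x (mean number of distinct lipid molecules in
    contact per frame) per residue; ``by_lipid_type`` splits it by the
    contacted lipid's label and sums back to the total.  ``hbond_occupancy``
    is the percentage of frames in which the residue forms at least one
    intersegment H-bond.  ``timeline`` is the residue x frame H-bond
    boolean matrix over the same window.
    """

    resids: np.ndarray
    occupancy: np.ndarray
    by_lipid_type: dict[str, np.ndarray]
    hbond_occupancy: np.ndarray
    times: np.ndarray
    frame_contacts: np.ndarray
    frame_hbonds: np.ndarray
    timeline: np.ndarray


def _heavy_split(top: Topology):
    heavy = top.heavy()
    pep = np.nonzero(heavy & (top.segment == "PEP"))[0]
    memb = np.nonzero(heavy & (top.segment == "MEMB"))[0]
    if pep.size == 0 or memb.size == 0:
        raise ValueError("need heavy atoms in both PEP and MEMB segments")
    return pep, memb


def contact_map(top: Topology, frame: Frame, cutoff: float = 3.0) -> set[tuple[int, int]]:
    """(residue id, lipid molecule id) pairs within the heavy-atom cutoff."""
    pep, memb = _heavy_split(top)
    tree = cKDTree(frame.coords[memb])
    pairs = tree.query_ball_point(frame.coords[pep], r=cutoff)
    out: set[tuple[int, int]] = set()
    for pi, hits in enumerate(pairs):
        if hits:
            r = int(top.resid[pep[pi]])
            for j in hits:
                out.add((r, int(top.molid[memb[j]])))
    return out


def detect_hbonds(top: Topology, frame: Frame, d_max: float = 3.5,
                  angle_min: float = 150.0) -> list[tuple[int, int, int]]:
    """Intersegment (donor-heavy, H, acceptor) triples meeting the criterion.

    Donors are located from each polar-H's bonded donor-heavy atom; a
    polar-H with no bonded donor-heavy is a topology error.
    """
    h_atoms = np.nonzero(top.hbond_role == "polar-H")[0]
    acceptors = np.nonzero(top.hbond_role == "acceptor")[0]
    cosmin = math.cos(math.radians(angle_min))
    out: list[tuple[int, int, int]] = []
    if h_atoms.size == 0 or acceptors.size == 0:
        return out
    tree = cKDTree(frame.coords[acceptors])
    for h in h_atoms:
        donors = [d for d in top.bonded_partners(int(h))
                  if top.hbond_role[d] == "donor-heavy"]
        if not donors:
            raise ValueError(f"polar-H atom {int(h)} has no bonded donor-heavy atom")
        d = int(donors[0])
        cand = [acceptors[j] for j in tree.query_ball_point(frame.coords[d], r=d_max)
                if top.segment[acceptors[j]] != top.segment[d]]
        for a in cand:
            v1 = frame.coords[d] - frame.coords[h]
            v2 = frame.coords[a] - frame.coords[h]
            c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            if c <= cosmin:  # angle at H >= angle_min
                out.append((d, int(h), int(a)))
    return out


def _peptide_resid_of_bond(top: Topology, bond: tuple[int, int, int]) -> int | None:
    for atom in bond:
        if top.segment[atom] == "PEP":
            return int(top.resid[atom])
    return None


def residue_occupancy(
    top: Topology,
    traj: Trajectory,
    window_ns: float = 50.0,
    cutoff: float = 3.0,
    hb_dmax: float = 3.5,
    hb_angle_min: float = 150.0,
) -> ResidueContactProfile:
    """Per-residue contact and H-bond occupancy over the trailing window."""
    win = traj.window(window_ns)
    pep_mask = top.segment == "PEP"
    resids = np.unique(top.resid[pep_mask])
    r_index = {int(r): i for i, r in enumerate(resids)}
    lipid_types = sorted(set(top.lipid_type[top.segment == "MEMB"]))
    lipid_of_mol = {}
    for m in np.unique(top.molid[top.segment == "MEMB"]):
        lipid_of_mol[int(m)] = str(top.lipid_type[top.molid == m][0])

    counts = np.zeros(resids.size)
    by_type = {lt: np.zeros(resids.size) for lt in lipid_types}
    hb_frames = np.zeros(resids.size)
    frame_contacts = np.empty(win.n_frames)
    frame_hbonds = np.empty(win.n_frames)
    timeline = np.zeros((resids.size, win.n_frames), dtype=bool)

    for fi, fr in enumerate(win):
        cmap = contact_map(top, fr, cutoff)
        frame_contacts[fi] = len(cmap)
        for (r, m) in cmap:
            counts[r_index[r]] += 1
            by_type[lipid_of_mol[m]][r_index[r]] += 1
        bonds = detect_hbonds(top, fr, hb_dmax, hb_angle_min)
        frame_hbonds[fi] = len(bonds)
        seen: set[int] = set()
        for b in bonds:
            r = _peptide_resid_of_bond(top, b)
            if r is not None:
                timeline[r_index[r], fi] = True
                seen.add(r)
        for r in seen:
            hb_frames[r_index[r]] += 1

    nf = win.n_frames
    return ResidueContactProfile(
        resids=resids,
        occupancy=100.0 * counts / nf,
        by_lipid_type={lt: 100.0 * v / nf for lt, v in by_type.items()},
        hbond_occupancy=100.0 * hb_frames / nf,
        times=win.times.copy(),
        frame_contacts=frame_contacts,
        frame_hbonds=frame_hbonds,
        timeline=timeline,
    )


def hbond_timeline(top: Topology, traj: Trajectory, d_max: float = 3.5,
                   angle_min: float = 150.0):
    """Residue x frame H-bond matrix plus per-frame bond counts.

    ``matrix[r, f]`` is True when residue ``resids[r]`` donates or accepts
    at least one intersegment H-bond in frame ``f``; ``counts[f]`` is the
    total number of bonds in that frame (a residue row collapses multiple
    simultaneous bonds into one True, so column sums are <= counts).
    """
    pep_mask = top.segment == "PEP"
    resids = np.unique(top.resid[pep_mask])
    r_index = {int(r): i for i, r in enumerate(resids)}
    matrix = np.zeros((resids.size, traj.n_frames), dtype=bool)
    counts = np.empty(traj.n_frames, dtype=int)
    for fi, fr in enumerate(traj):
        bonds = detect_hbonds(top, fr, d_max, angle_min)
        counts[fi] = len(bonds)
        for b in bonds:
            r = _peptide_resid_of_bond(top, b)
            if r is not None:
                matrix[r_index[r], fi] = True
    return resids, matrix, counts
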