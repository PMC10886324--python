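"""Synthetic membrane-peptide systems with analytically known ground truth.

The generator emulates the study conditions of a peptide adsorbing onto a
planar two-leaflet bilayer: coarse pseudo-lipids on a jittered grid at the
bacterial (GN: 80:8:12 POPE/POPG/TMCL; GP: 60:40 DOPG/TMCL) and eukaryotic
(Zw: 60:40 DOPC/cholesterol) compositions, and a rigid-body peptide that
starts 30 A (COM-COM) above the membrane, approaches an adsorption depth
exponentially, follows a prescribed electric-dipole orientation schedule,
and optionally carries i.i.d. Gaussian thermal jitter.

Every quantity the analysis stages measure — COM distance, depth to the
phosphate plane, dipole cosine, residue-lipid contacts, hydrogen bonds — is
planted by construction and recorded noise-free in a :class:`GroundTruth`,
so recovery tests have exact oracles.  The generator is kinematic, not
dynamic: no forces are integrated, and engine conditions (temperature,
salt, pressure) exist only as provenance metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from . import seqdesc
from .mdio import Frame, Topology, Trajectory
from .seqdesc import PeptideRecord

__all__ = [
    "MembraneSpec",
    "AdsorptionScenario",
    "GroundTruth",
    "membrane_spec",
    "largest_remainder_counts",
    "build_membrane",
    "build_peptide_model",
    "generate_trajectory",
    "COMPOSITIONS",
]

COMPOSITIONS: dict[str, dict[str, float]] = {
    "gn": {"POPE": 0.80, "POPG": 0.08, "TMCL": 0.12},
    "gp": {"DOPG": 0.60, "TMCL": 0.40},
    "zw": {"DOPC": 0.60, "CHOL": 0.40},
}

# engine conditions carried as provenance only (the generator is kinematic)
ENGINE_METADATA = {"temperature_K": 310.0, "salt_mM": 150.0, "pressure_atm": 1.0}

CONTACT_CUTOFF = 3.0     # A, heavy-atom residue-lipid contact
HBOND_DMAX = 3.5         # A, donor-heavy to acceptor
HBOND_ANGLE_MIN = 150.0  # deg, donor-H-acceptor

_DONOR_RESIDUES = set("RKSTYNQWH")


@dataclass(frozen=True)
class MembraneSpec:
    """Planar bilayer recipe: per-leaflet composition and geometry (A units)."""

    composition: Mapping[str, float]
    lipids_per_leaflet: int
    area_per_lipid: float = 65.0
    z_phosphate: float = 18.0
    head_jitter: float = 1.0
    tail_spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if self.area_per_lipid <= 0 or self.z_phosphate <= 0:
            raise ValueError("area per lipid and phosphate offset must be positive")


def membrane_spec(model: str, lipids_per_leaflet: int = 36, **kwargs) -> MembraneSpec:
    """Named membrane recipe: ``gn``, ``gp`` or ``zw``."""
    key = model.lower()
    if key not in COMPOSITIONS:
        raise ValueError(f"unknown membrane model {model!r}; choose from {list(COMPOSITIONS)}")
    return MembraneSpec(COMPOSITIONS[key], lipids_per_leaflet, **kwargs)


def largest_remainder_counts(composition: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer lipid counts matching fractions by largest-remainder rounding."""
    names = sorted(composition)
    quotas = {k: composition[k] * total for k in names}
    counts = {k: int(math.floor(quotas[k])) for k in names}
    short = total - sum(counts.values())
    # ties broken by name order for determinism
    for k in sorted(names, key=lambda k: (-(quotas[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


# bead templates: (name, element, charge, dx, dz_from_plane, role, mass, gb_r)
# dz is signed toward the solvent (+) / core (-); tails fill in below
_HEAD_TEMPLATES: dict[str, list[tuple]] = {
    "POPG": [("P", "P", -1.0, 0.0, 0.0, "acceptor", 95.0, 2.1)],
    "DOPG": [("P", "P", -1.0, 0.0, 0.0, "acceptor", 95.0, 2.1)],
    # zwitterionic pair lies side-by-side in the head plane so nothing
    # protrudes above z_P toward the adsorbed peptide
    "POPE": [("N", "N", +1.0, 1.5, 0.0, "none", 35.0, 1.9),
             ("P", "P", -1.0, 0.0, 0.0, "acceptor", 95.0, 2.1)],
    "DOPE": [("N", "N", +1.0, 1.5, 0.0, "none", 35.0, 1.9),
             ("P", "P", -1.0, 0.0, 0.0, "acceptor", 95.0, 2.1)],
    "DOPC": [("N", "N", +1.0, 1.5, 0.0, "none", 50.0, 1.9),
             ("P", "P", -1.0, 0.0, 0.0, "acceptor", 95.0, 2.1)],
    "TMCL": [("P", "P", -1.0, -1.5, 0.0, "acceptor", 95.0, 2.1),
             ("P", "P", -1.0, +1.5, 0.0, "acceptor", 95.0, 2.1)],
    "CHOL": [("O", "O", 0.0, 0.0, 0.0, "none", 30.0, 1.8)],
}
_N_TAILS = {"POPG": 2, "DOPG": 2, "POPE": 2, "DOPE": 2, "DOPC": 2, "TMCL": 2, "CHOL": 1}
# soft beads: rmin/2 = 1.2 A keeps the scripted (not force-relaxed) contact
# geometries out of the 12-6 repulsive wall
_LJ_EPS, _LJ_RMIN_HALF = 0.10, 1.2


def build_membrane(spec: MembraneSpec, seed: int = 0) -> tuple[Topology, Frame]:
    """Build a mirrored two-leaflet slab centred at z = 0.

    Lipid head sites sit exactly at +-z_phosphate (PG: one -1 phosphate;
    PE/PC: +1/-1 zwitterionic pair; cardiolipin: two -1 phosphates;
    cholesterol: neutral head); neutral tail beads extend toward the core.
    The lower leaflet is the exact z-mirror of the upper, so the slab COM
    sits at z = 0 by construction.
    """
    rng = np.random.default_rng(seed)
    n = spec.lipids_per_leaflet
    counts = largest_remainder_counts(spec.composition, n)
    types = [t for t in sorted(counts) for _ in range(counts[t])]
    rng.shuffle(types)

    n_side = math.ceil(math.sqrt(n))
    spacing = math.sqrt(spec.area_per_lipid)
    box_xy = n_side * spacing
    sites = [(spacing * (i + 0.5) - box_xy / 2, spacing * (j + 0.5) - box_xy / 2)
             for i in range(n_side) for j in range(n_side)][:n]
    jitter = rng.uniform(-spec.head_jitter, spec.head_jitter, size=(n, 2))

    rows: list[dict] = []
    bonds: list[tuple[int, int]] = []
    molid = 0
    for leaflet_sign in (+1, -1):
        for li, ((x0, y0), lip) in enumerate(zip(sites, types)):
            x0j, y0j = x0 + jitter[li, 0], y0 + jitter[li, 1]
            z_plane = leaflet_sign * spec.z_phosphate
            start = len(rows)
            head = _HEAD_TEMPLATES[lip]
            for (nm, el, q, dx, dz, role, mass, gbr) in head:
                rows.append(dict(
                    name=nm, element=el, resid=molid + 1, resname=lip, segment="MEMB",
                    molid=molid, lipid_type=lip, charge=q, mass=mass, gb_radius=gbr,
                    lj_epsilon=_LJ_EPS, lj_rmin_half=_LJ_RMIN_HALF, hbond_role=role,
                    xyz=(x0j + dx, y0j, z_plane + leaflet_sign * dz),
                ))
            anchor = start + len(head) - 1  # deepest head bead carries the chain
            for ti in range(_N_TAILS[lip]):
                dxt = head[-1][3] if lip != "TMCL" else (-1.5 if ti == 0 else 1.5)
                depth = spec.tail_spacing * (ti + 1) if lip != "TMCL" else spec.tail_spacing
                rows.append(dict(
                    name=f"C{ti + 1}", element="C", resid=molid + 1, resname=lip,
                    segment="MEMB", molid=molid, lipid_type=lip, charge=0.0, mass=60.0,
                    gb_radius=2.0, lj_epsilon=_LJ_EPS, lj_rmin_half=_LJ_RMIN_HALF,
                    hbond_role="none",
                    xyz=(x0j + dxt, y0j, z_plane - leaflet_sign * depth),
                ))
            # chain bonds: heads in sequence, then anchor->tails (TMCL: P_i->C_i)
            for k in range(start, start + len(head) - 1):
                bonds.append((k, k + 1))
            tail0 = start + len(head)
            if lip == "TMCL":
                bonds += [(start, tail0), (start + 1, tail0 + 1)]
            else:
                prev = anchor
                for ti in range(_N_TAILS[lip]):
                    bonds.append((prev, tail0 + ti))
                    prev = tail0 + ti
            molid += 1

    coords = np.array([r.pop("xyz") for r in rows])
    fields = {k: [r[k] for r in rows] for k in rows[0]}
    bond_arr = np.array(bonds, dtype=int) if bonds else np.zeros((0, 2), int)
    r0 = np.linalg.norm(coords[bond_arr[:, 0]] - coords[bond_arr[:, 1]], axis=1) if len(bond_arr) else np.zeros(0)
    top = Topology(
        **fields, bonds=bond_arr, bond_k=np.full(len(bond_arr), 5.0), bond_r0=r0,
        metadata={"generator": "pepmem.memsynth.build_membrane", "seed": seed,
                  "composition": dict(spec.composition), "counts_per_leaflet": counts,
                  **ENGINE_METADATA},
    )
    box = np.array([box_xy, box_xy, 2.0 * (spec.z_phosphate + 30.0)])
    return top, Frame(coords, box)


def _residue_mass(aa: str) -> float:
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    return ProteinAnalysis(aa).molecular_weight() - 18.015


def build_peptide_model(p: PeptideRecord) -> tuple[Topology, Frame]:
    """Coarse rigid peptide scaffold: a flat beta-hairpin of 1-3 sites/residue.

    Each residue gets a backbone bead carrying its average residue mass;
    Arg/Lys add a +1 donor side site with a polar H, Asp/Glu a -1 acceptor
    site, and polar residues (S/T/Y/N/Q/W/H) a neutral donor site with a
    polar H.  A +1 N-terminal amine site and, for free C-termini, a -1
    carboxylate site make the model's formal charge equal the sequence-level
    :func:`pepmem.seqdesc.net_charge` exactly.
    """
    seq = p.sequence
    n = len(seq)
    n1 = math.ceil(n / 2)
    ca_xy = []
    for i in range(n):
        if i < n1:
            ca_xy.append((3.5 * i, 0.0))
        else:
            ca_xy.append((3.5 * (n - 1 - i), 4.8))
    disulfide = p.disulfide_cys

    rows: list[dict] = []
    bonds: list[tuple[int, int]] = []
    ca_index: list[int] = []

    def add(name, el, q, xyz, role, mass, gbr, lj_eps=_LJ_EPS, lj_rh=_LJ_RMIN_HALF,
            resid=1, resname="XXX"):
        rows.append(dict(name=name, element=el, resid=resid, resname=resname,
                         segment="PEP", molid=0, lipid_type="n/a", charge=q, mass=mass,
                         gb_radius=gbr, lj_epsilon=lj_eps, lj_rmin_half=lj_rh,
                         hbond_role=role, xyz=xyz))
        return len(rows) - 1

    from Bio.SeqUtils import seq3

    for i, aa in enumerate(seq):
        x, y = ca_xy[i]
        resid, resname = i + 1, seq3(aa).upper()
        side_mass = 0.0
        ca = add("CA", "C", 0.0, (x, y, 0.0), "none", 1.0, 2.0, resid=resid, resname=resname)
        ca_index.append(ca)
        if i > 0:
            bonds.append((ca_index[i - 1], ca))
        if aa in "RK":
            sc = add("SC", "N", +1.0, (x, y, -1.2), "donor-heavy", 40.0, 1.8,
                     resid=resid, resname=resname)
            hs = add("HS", "H", 0.0, (x, y, -2.2), "polar-H", 1.0, 1.15, 0.03, 0.6,
                     resid=resid, resname=resname)
            bonds += [(ca, sc), (sc, hs)]
            side_mass = 41.0
        elif aa in "DE":
            sc = add("SC", "O", -1.0, (x, y, -1.2), "acceptor", 44.0, 1.7,
                     resid=resid, resname=resname)
            bonds.append((ca, sc))
            side_mass = 44.0
        elif aa in _DONOR_RESIDUES and i + 1 not in disulfide:
            sp = add("SP", "O", 0.0, (x, y, -1.2), "donor-heavy", 30.0, 1.7,
                     resid=resid, resname=resname)
            hp = add("HP", "H", 0.0, (x, y, -2.2), "polar-H", 1.0, 1.15, 0.03, 0.6,
                     resid=resid, resname=resname)
            bonds += [(ca, sp), (sp, hp)]
            side_mass = 31.0
        rows[ca]["mass"] = max(_residue_mass(aa) - side_mass, 12.0)

    x0, y0 = ca_xy[0]
    nt = add("NT", "N", +1.0, (x0 - 1.5, y0, 0.0), "donor-heavy", 14.0, 1.6,
             resid=1, resname=seq3(seq[0]).upper())
    bonds.append((ca_index[0], nt))
    if not p.c_term_amidated:
        xl, yl = ca_xy[-1]
        ct = add("CT", "O", -1.0, (xl - 1.5, yl, 0.0), "acceptor", 16.0, 1.5,
                 resid=n, resname=seq3(seq[-1]).upper())
        bonds.append((ca_index[-1], ct))
    for (i, j) in p.disulfide_pairs:
        bonds.append((ca_index[i - 1], ca_index[j - 1]))

    coords = np.array([r.pop("xyz") for r in rows])
    masses = np.array([r["mass"] for r in rows])
    coords -= (coords * masses[:, None]).sum(axis=0) / masses.sum()  # COM at origin
    fields = {k: [r[k] for r in rows] for k in rows[0]}
    bond_arr = np.array(bonds, dtype=int)
    r0 = np.linalg.norm(coords[bond_arr[:, 0]] - coords[bond_arr[:, 1]], axis=1)
    top = Topology(**fields, bonds=bond_arr, bond_k=np.full(len(bond_arr), 10.0), bond_r0=r0,
                   metadata={"generator": "pepmem.memsynth.build_peptide_model",
                             "sequence": seq, "name": p.name,
                             "net_charge": seqdesc.net_charge(p)})
    box = np.array([200.0, 200.0, 200.0])
    return top, Frame(coords, box)


@dataclass(frozen=True)
class AdsorptionScenario:
    """Rigid-body adsorption script with planted, analytically known truth.

    ``depth_nm`` is the planted final distance of the peptide COM above the
    upper phosphate plane; ``dipole_schedule`` maps time (ns) to the target
    dipole cosine in [-1, 1] for pose model1 (model2, the 180-degree flipped
    pose, realises the negated schedule); ``jitter_sigma`` (A) is i.i.d.
    Gaussian noise added to peptide atoms only.
    """

    com_separation: float = 30.0
    tau_ns: float = 5.0
    depth_nm: float = 0.42
    pose: str = "model1"
    dipole_schedule: Callable[[float], float] | None = None
    jitter_sigma: float = 0.0
    n_frames: int = 100
    dt_ns: float = 1.0
    seed: int = 0
    planted_contacts: tuple[tuple[int, int], ...] = ()
    planted_hbonds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tau_ns <= 0:
            raise ValueError("approach time constant must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.pose not in {"model1", "model2"}:
            raise ValueError("pose must be 'model1' or 'model2'")


@dataclass
class GroundTruth:
    """Noise-free planted values, one entry per frame."""

    times: np.ndarray
    com_distance_nm: np.ndarray
    depth_nm: np.ndarray
    cos_theta: np.ndarray
    contacts: list[set[tuple[int, int]]]
    hbonds: list[set[tuple[int, int, int]]]
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "times": self.times.tolist(),
            "com_distance_nm": self.com_distance_nm.tolist(),
            "depth_nm": self.depth_nm.tolist(),
            "cos_theta": self.cos_theta.tolist(),
            "contacts": [sorted(map(list, s)) for s in self.contacts],
            "hbonds": [sorted(map(list, s)) for s in self.hbonds],
            "seed": self.seed,
        }


def _merge(mem: Topology, pep: Topology) -> Topology:
    off = mem.n_atoms
    mol_off = int(mem.molid.max()) + 1 if mem.n_atoms else 0
    fields = {}
    for f in ("name", "element", "resname", "segment", "lipid_type", "hbond_role",
              "charge", "mass", "gb_radius", "lj_epsilon", "lj_rmin_half"):
        fields[f] = np.concatenate([getattr(mem, f), getattr(pep, f)])
    fields["resid"] = np.concatenate([mem.resid, pep.resid])
    fields["molid"] = np.concatenate([mem.molid, pep.molid + mol_off])
    bonds = np.vstack([mem.bonds, pep.bonds + off])
    return Topology(**fields, bonds=bonds,
                    bond_k=np.concatenate([mem.bond_k, pep.bond_k]),
                    bond_r0=np.concatenate([mem.bond_r0, pep.bond_r0]),
                    metadata={"membrane": mem.metadata, "peptide": pep.metadata})


def _brute_contacts(top: Topology, pep_xyz: np.ndarray, mem_xyz: np.ndarray,
                    pep_idx: np.ndarray, mem_idx: np.ndarray,
                    cutoff: float) -> set[tuple[int, int]]:
    d = np.linalg.norm(pep_xyz[:, None, :] - mem_xyz[None, :, :], axis=-1)
    ii, jj = np.nonzero(d <= cutoff)
    return {(int(top.resid[pep_idx[i]]), int(top.molid[mem_idx[j]])) for i, j in zip(ii, jj)}


def _brute_hbonds(top: Topology, xyz: np.ndarray, dmax: float,
                  angle_min: float) -> set[tuple[int, int, int]]:
    out: set[tuple[int, int, int]] = set()
    h_atoms = np.nonzero(top.hbond_role == "polar-H")[0]
    acceptors = np.nonzero(top.hbond_role == "acceptor")[0]
    cosmin = math.cos(math.radians(angle_min))
    for h in h_atoms:
        partners = top.bonded_partners(int(h))
        donors = [d for d in partners if top.hbond_role[d] == "donor-heavy"]
        if not donors:
            raise ValueError(f"polar-H atom {h} has no bonded donor-heavy atom")
        d = int(donors[0])
        acc = acceptors[top.segment[acceptors] != top.segment[d]]
        if acc.size == 0:
            continue
        da = np.linalg.norm(xyz[acc] - xyz[d], axis=1)
        acc = acc[da <= dmax]
        if acc.size == 0:
            continue
        v1 = xyz[d] - xyz[h]
        v2 = xyz[acc] - xyz[h]
        cosang = (v2 @ v1) / (np.linalg.norm(v1) * np.linalg.norm(v2, axis=1))
        # angle >= angle_min <=> cos(angle) <= cos(angle_min)
        for a in acc[cosang <= cosmin]:
            out.add((d, int(h), int(a)))
    return out


def generate_trajectory(
    mem_top: Topology, mem_frame: Frame,
    pep_top: Topology, pep_frame: Frame,
    scenario: AdsorptionScenario,
    membrane: MembraneSpec | None = None,
) -> tuple[Topology, Trajectory, GroundTruth]:
    """Script the rigid-body adsorption and return system + planted truth.

    The peptide COM follows z(t) = z_f + (z0 - z_f) exp(-t/tau) above the
    membrane COM, where z_f places it ``depth_nm`` above the phosphate
    plane; the rigid orientation follows the dipole schedule; planted
    contact/H-bond lipids are relocated under the designated residues at the
    adsorbed geometry.  Deterministic given the scenario seed.
    """
    z_p = float(np.max(mem_frame.coords[:, 2][mem_top.name == "P"])) if \
        (mem_top.name == "P").any() else float(mem_frame.coords[:, 2].max())
    z_final = z_p + 10.0 * scenario.depth_nm
    if z_final < z_p - 2.5:
        raise ValueError("planted depth places the peptide inside the membrane core")

    rng = np.random.default_rng(scenario.seed)
    times = scenario.dt_ns * np.arange(scenario.n_frames)

    # body-frame peptide, COM at origin
    pep_xyz0 = pep_frame.coords.copy()
    masses = pep_top.mass
    pep_xyz0 -= (pep_xyz0 * masses[:, None]).sum(axis=0) / masses.sum()
    pose_rot = Rotation.identity() if scenario.pose == "model1" else \
        Rotation.from_rotvec([math.pi, 0.0, 0.0])
    body = pose_rot.apply(pep_xyz0)
    mu_body = (pep_top.charge[:, None] * body).sum(axis=0)
    if np.linalg.norm(mu_body) < 1e-12:
        raise ValueError("peptide model has zero dipole; cannot follow a schedule")
    mu_hat = mu_body / np.linalg.norm(mu_body)
    flip = 1.0 if scenario.pose == "model1" else -1.0

    def frame_rotation(t: float) -> tuple[Rotation, float]:
        if scenario.dipole_schedule is None:
            return Rotation.identity(), float(mu_hat[2])
        c = flip * float(np.clip(scenario.dipole_schedule(t), -1.0, 1.0))
        target = np.array([math.sqrt(max(0.0, 1.0 - c * c)), 0.0, c])
        rot, _ = Rotation.align_vectors(target[None], mu_hat[None])
        return rot, c

    mem_xyz0 = mem_frame.coords.copy()
    mem_xyz = mem_xyz0
    rot_last, _ = frame_rotation(float(times[-1]))
    z_path = z_final + (scenario.com_separation - z_final) * np.exp(-times / scenario.tau_ns)

    # plants draw on upper-leaflet anionic lipids: their head is a bare
    # phosphate at the plane, so relocation cannot bury a choline bead in
    # the peptide, and they are the physical contact partners anyway
    _anionic = {"POPG", "DOPG", "TMCL"}
    upper_heads = [m for m in np.unique(mem_top.molid)
                   if mem_top.lipid_type[mem_top.molid == m][0] in _anionic
                   and mem_xyz0[mem_top.molid == m][:, 2].mean() > 0]

    def _anchor_mask(m: int):
        msel = mem_top.molid == m
        psel = msel & (mem_top.name == "P")
        return psel if psel.any() else msel

    # planting targets depend on the final peptide position, which depends
    # on the membrane COM, which the relocations themselves shift; a short
    # fixed-point iteration (the moved mass fraction is small) converges the
    # planted geometry onto the exact criterion distances
    chosen: dict[tuple, list[int]] = {}
    has_plants = bool(scenario.planted_contacts or scenario.planted_hbonds)
    mem_com = (mem_xyz * mem_top.mass[:, None]).sum(axis=0) / mem_top.mass.sum()
    for _ in range(4 if has_plants else 0):
        pep_last = rot_last.apply(body) + mem_com + np.array([0.0, 0.0, z_path[-1]])
        mem_xyz = mem_xyz0.copy()
        used: set[int] = set()

        def take_lipids(key, xy, k: int) -> list[int]:
            if key in chosen:
                used.update(chosen[key])
                return chosen[key]
            free = [m for m in upper_heads if m not in used]
            if len(free) < k:
                raise ValueError("not enough upper-leaflet anionic lipids to plant")
            free.sort(key=lambda m: float(np.linalg.norm(
                mem_xyz0[_anchor_mask(m)][0][:2] - xy)))
            chosen[key] = free[:k]
            used.update(chosen[key])
            return chosen[key]

        for resid, k in scenario.planted_contacts:
            sel = (pep_top.resid == resid) & (pep_top.name == "CA")
            if not sel.any():
                raise ValueError(f"planted contact names unknown residue {resid}")
            p = pep_last[np.nonzero(sel)[0][0]]
            for j, m in enumerate(take_lipids(("c", resid), p[:2], k)):
                ang = 2.0 * math.pi * j / max(k, 1)
                target = p + np.array([math.cos(ang), math.sin(ang), -2.5])
                msel = mem_top.molid == m
                mem_xyz[msel] = mem_xyz0[msel] + (target - mem_xyz0[_anchor_mask(m)][0])
        for resid in scenario.planted_hbonds:
            dsel = (pep_top.resid == resid) & (pep_top.hbond_role == "donor-heavy")
            hsel = (pep_top.resid == resid) & (pep_top.hbond_role == "polar-H")
            if not dsel.any() or not hsel.any():
                raise ValueError(f"residue {resid} has no donor site for an H-bond plant")
            d = pep_last[np.nonzero(dsel)[0][0]]
            h = pep_last[np.nonzero(hsel)[0][0]]
            target = d + 2.8 * (h - d) / np.linalg.norm(h - d)
            m = take_lipids(("h", resid), d[:2], 1)[0]
            msel = mem_top.molid == m
            mem_xyz[msel] = mem_xyz0[msel] + (target - mem_xyz0[_anchor_mask(m)][0])
        mem_com = (mem_xyz * mem_top.mass[:, None]).sum(axis=0) / mem_top.mass.sum()

    pep_off = mem_top.n_atoms

    top = _merge(mem_top, pep_top)
    top.metadata["scenario"] = {
        "pose": scenario.pose, "tau_ns": scenario.tau_ns, "depth_nm": scenario.depth_nm,
        "com_separation_A": scenario.com_separation, "jitter_sigma_A": scenario.jitter_sigma,
        "dt_ns": scenario.dt_ns, "seed": scenario.seed, **ENGINE_METADATA,
    }
    mem_com = (mem_xyz * mem_top.mass[:, None]).sum(axis=0) / mem_top.mass.sum()

    pep_heavy = np.nonzero(top.heavy() & (top.segment == "PEP"))[0]
    mem_heavy = np.nonzero(top.heavy() & (top.segment == "MEMB"))[0]
    phos_upper = (mem_top.name == "P") & (mem_xyz[:, 2] > 0)
    if phos_upper.any():
        w = mem_top.mass[phos_upper]
        z_plane_actual = float((mem_xyz[phos_upper, 2] * w).sum() / w.sum())
    else:
        z_plane_actual = math.nan

    frames = np.empty((scenario.n_frames, top.n_atoms, 3))
    gt_com = np.empty(scenario.n_frames)
    gt_depth = np.empty(scenario.n_frames)
    gt_cos = np.empty(scenario.n_frames)
    gt_contacts: list[set] = []
    gt_hbonds: list[set] = []
    box = mem_frame.box.copy()
    box[2] = max(box[2], 2 * (scenario.com_separation + 20.0))

    for fi, t in enumerate(times):
        rot, c_eff = frame_rotation(float(t))
        center = mem_com + np.array([0.0, 0.0, z_path[fi]])
        pep_clean = rot.apply(body) + center
        xyz = np.vstack([mem_xyz, pep_clean])
        gt_com[fi] = (center[2] - mem_com[2]) / 10.0
        gt_depth[fi] = (center[2] - z_plane_actual) / 10.0
        gt_cos[fi] = c_eff
        gt_contacts.append(_brute_contacts(
            top, xyz[pep_heavy], xyz[mem_heavy], pep_heavy, mem_heavy, CONTACT_CUTOFF))
        gt_hbonds.append(_brute_hbonds(top, xyz, HBOND_DMAX, HBOND_ANGLE_MIN))
        if scenario.jitter_sigma > 0:
            xyz = xyz.copy()
            xyz[pep_off:] += rng.normal(0.0, scenario.jitter_sigma,
                                        size=(top.n_atoms - pep_off, 3))
        frames[fi] = xyz

    traj = Trajectory(frames, times, box)
    truth = GroundTruth(times, gt_com, gt_depth, gt_cos, gt_contacts, gt_hbonds,
                        scenario.seed)
    return top, traj, truth
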