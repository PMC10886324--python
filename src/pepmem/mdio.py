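"""Molecular-system containers and file I/O.

The in-memory model is deliberately minimal: a :class:`Topology` of flat
numpy arrays carrying everything the downstream analyses need (partial
charges, masses, GB intrinsic radii, Lennard-Jones parameters, residue /
segment / lipid labels, hydrogen-bond roles, bonds with harmonic constants),
plus a :class:`Trajectory` of ordered coordinate frames.

On disk a system is three files: a versioned JSON topology sidecar (the
standard formats cannot carry GB radii and H-bond roles), a PDB with the
first frame, and a DCD or multi-frame XYZ trajectory.  PDB/DCD/XYZ reading
and writing go through MDAnalysis.

Internally coordinates are Angstrom throughout; conversions to nm happen
only at reporting boundaries.  Atom indices are 0-based, residue ids are
1-based (PDB convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "load_system",
    "write_system",
    "write_timeseries",
    "read_timeseries",
]

SCHEMA_VERSION = 1
SEGMENTS = ("PEP", "MEMB")
LIPID_TYPES = ("POPE", "POPG", "DOPE", "DOPG", "DOPC", "TMCL", "CHOL", "n/a")
HBOND_ROLES = ("polar-H", "donor-heavy", "acceptor", "none")

_STR_FIELDS = ("name", "element", "resname", "segment", "lipid_type", "hbond_role")
_NUM_FIELDS = ("resid", "molid", "charge", "mass", "gb_radius", "lj_epsilon", "lj_rmin_half")


@dataclass
class Topology:
    """Per-atom parameter arrays plus bonded terms.

    All arrays have length ``n_atoms``; ``bonds`` is (n_bonds, 2) int with
    per-bond harmonic constants ``bond_k`` (kcal/mol/A^2) and rest lengths
    ``bond_r0`` (A).  ``molid`` partitions atoms into molecules (each lipid
    is one molecule; the whole peptide is one).
    """

    name: np.ndarray
    element: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    segment: np.ndarray
    molid: np.ndarray
    lipid_type: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    gb_radius: np.ndarray
    lj_epsilon: np.ndarray
    lj_rmin_half: np.ndarray
    hbond_role: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.name)
        for f in _STR_FIELDS:
            setattr(self, f, np.asarray(getattr(self, f), dtype="U16"))
        self.resid = np.asarray(self.resid, dtype=int)
        self.molid = np.asarray(self.molid, dtype=int)
        for f in ("charge", "mass", "gb_radius", "lj_epsilon", "lj_rmin_half"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        for f in _STR_FIELDS + _NUM_FIELDS:
            if len(getattr(self, f)) != n:
                raise ValueError(f"field {f!r} length != n_atoms")
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond indices out of range")
        if len(self.bond_k) != len(self.bonds) or len(self.bond_r0) != len(self.bonds):
            raise ValueError("per-bond parameter length != n_bonds")
        bad_seg = sorted(set(self.segment) - set(SEGMENTS))
        if bad_seg:
            raise ValueError(f"unknown segments {bad_seg}; expected {SEGMENTS}")
        bad_lip = sorted(set(self.lipid_type) - set(LIPID_TYPES))
        if bad_lip:
            raise ValueError(f"unknown lipid_type {bad_lip}; expected {LIPID_TYPES}")
        memb = self.segment == "MEMB"
        if (self.lipid_type[memb] == "n/a").any():
            raise ValueError("every MEMB atom needs a lipid_type")
        bad_role = sorted(set(self.hbond_role) - set(HBOND_ROLES))
        if bad_role:
            raise ValueError(f"unknown hbond_role {bad_role}")
        for f in ("charge", "mass", "gb_radius", "lj_epsilon", "lj_rmin_half"):
            if not np.isfinite(getattr(self, f)).all():
                raise ValueError(f"non-finite values in {f!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def select(self, segment: str | None = None) -> np.ndarray:
        """Boolean mask of atoms, optionally restricted to one segment."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if segment is not None:
            mask &= self.segment == segment
        return mask

    def heavy(self) -> np.ndarray:
        return self.element != "H"

    def bonded_partners(self, index: int) -> np.ndarray:
        hits = (self.bonds == index).any(axis=1)
        pairs = self.bonds[hits]
        return pairs[pairs != index]

    # ---- JSON sidecar ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "n_atoms": self.n_atoms,
            "atoms": {f: getattr(self, f).tolist() for f in _STR_FIELDS + _NUM_FIELDS},
            "bonds": self.bonds.tolist(),
            "bond_k": self.bond_k.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "Topology":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported topology schema {doc.get('schema_version')!r}")
        atoms = doc["atoms"]
        return cls(
            **{f: atoms[f] for f in _STR_FIELDS + _NUM_FIELDS},
            bonds=np.asarray(doc["bonds"], dtype=int).reshape(-1, 2),
            bond_k=doc["bond_k"],
            bond_r0=doc["bond_r0"],
            metadata=doc.get("metadata", {}),
        )


@dataclass
class Frame:
    """One coordinate snapshot: N x 3 Angstrom, orthorhombic box, time in ns."""

    coords: np.ndarray
    box: np.ndarray
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if (self.box <= 0).any():
            raise ValueError("box lengths must be positive")


@dataclass
class Trajectory:
    """Ordered frames with uniform time spacing (coords: F x N x 3 Angstrom)."""

    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("trajectory needs >= 1 frame of N x 3 coordinates")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length != n_frames")
        if len(self.times) > 1 and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(self.coords[i], self.box, float(self.times[i]))

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.coords[i], self.box, float(self.times[i]))

    def window(self, window_ns: float) -> "Trajectory":
        """The trailing sub-trajectory spanning the last ``window_ns`` ns."""
        t_end = self.times[-1]
        mask = self.times >= t_end - window_ns + 1e-12
        if not mask.any():
            raise ValueError("empty analysis window")
        return Trajectory(self.coords[mask], self.times[mask], self.box)

    @classmethod
    def single(cls, frame: Frame) -> "Trajectory":
        return cls(frame.coords[None], [frame.time_ns], frame.box)


# ---------------------------------------------------------------------------
# system-level file I/O (MDAnalysis behind the scenes)
# ---------------------------------------------------------------------------


def _mda_universe(top: Topology, traj: Trajectory):
    import MDAnalysis as mda

    n_res_ids = {}
    res_index = np.zeros(top.n_atoms, dtype=int)
    for i, (mol, res) in enumerate(zip(top.molid, top.resid)):
        key = (int(mol), int(res))
        if key not in n_res_ids:
            n_res_ids[key] = len(n_res_ids)
        res_index[i] = n_res_ids[key]
    n_res = len(n_res_ids)
    u = mda.Universe.empty(
        top.n_atoms, n_residues=n_res, atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=True,
    )
    u.add_TopologyAttr("names", top.name)
    u.add_TopologyAttr("elements", top.element)
    u.add_TopologyAttr("masses", top.mass)
    u.add_TopologyAttr("charges", top.charge)
    first = {}
    for i, ri in enumerate(res_index):
        first.setdefault(int(ri), i)
    order = [first[k] for k in range(n_res)]
    u.add_TopologyAttr("resids", top.resid[order])
    u.add_TopologyAttr("resnames", np.array([r[:4] for r in top.resname[order]]))
    u.add_TopologyAttr("segids", np.array(["SYS"]))
    u.atoms.positions = traj.coords[0]
    u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
    return u


def write_system(top: Topology, traj: Trajectory, outdir: str | Path,
                 traj_format: str = "dcd") -> dict[str, Path]:
    """Write topology JSON + PDB (first frame) + trajectory (DCD or XYZ).

    Returns the mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "topology": outdir / "topology.json",
        "coords": outdir / "system.pdb",
        "traj": outdir / f"traj.{traj_format}",
    }
    top.to_json(paths["topology"])
    u = _mda_universe(top, traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(paths["coords"]))
        import MDAnalysis as mda

        with mda.Writer(str(paths["traj"]), n_atoms=top.n_atoms) as w:
            for fr in traj:
                u.atoms.positions = fr.coords
                u.dimensions = [*traj.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)
    meta = {"dt_ns": float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 0.0,
            "t0_ns": float(traj.times[0]), "n_frames": traj.n_frames}
    (outdir / "trajectory_meta.json").write_text(json.dumps(meta))
    paths["meta"] = outdir / "trajectory_meta.json"
    return paths


def load_system(
    topology_path: str | Path,
    coords_path: str | Path,
    traj_path: str | Path | None = None,
    dt_ns: float | None = None,
) -> tuple[Topology, Trajectory]:
    """Load topology JSON + PDB coordinates (+ optional DCD/XYZ trajectory).

    Atom counts must agree across all sources.  Frame times are rebuilt as an
    arithmetic ladder from ``dt_ns`` (falling back to a ``trajectory_meta.json``
    sidecar next to the trajectory, then to 1 ns/frame).
    """
    import MDAnalysis as mda

    top = Topology.from_json(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coords_path))
    if u.atoms.n_atoms != top.n_atoms:
        raise ValueError(
            f"atom count mismatch: topology has {top.n_atoms}, "
            f"{coords_path} has {u.atoms.n_atoms}"
        )
    box = u.dimensions[:3] if u.dimensions is not None and u.dimensions[:3].all() else None
    t0 = 0.0
    if traj_path is None:
        if box is None:
            box = np.full(3, 1000.0)
        return top, Trajectory(u.atoms.positions.astype(float)[None], [0.0], box)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ut = mda.Universe(str(coords_path), str(traj_path))
    if ut.atoms.n_atoms != top.n_atoms:
        raise ValueError("trajectory atom count differs from topology")
    frames = []
    for ts in ut.trajectory:
        frames.append(ut.atoms.positions.astype(float).copy())
        if ts.dimensions is not None and ts.dimensions[:3].all():
            box = ts.dimensions[:3].astype(float).copy()
    if box is None:
        box = np.full(3, 1000.0)
    if dt_ns is None:
        meta_path = Path(traj_path).parent / "trajectory_meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            dt_ns = float(meta.get("dt_ns", 1.0)) or 1.0
            t0 = float(meta.get("t0_ns", 0.0))
        else:
            dt_ns = 1.0
    times = t0 + dt_ns * np.arange(len(frames))
    return top, Trajectory(np.asarray(frames), times, box)


# ---------------------------------------------------------------------------
# timeseries CSV/JSON
# ---------------------------------------------------------------------------


def write_timeseries(series: Mapping[str, Sequence[float]], path: str | Path,
                     json_mirror: bool = False) -> None:
    """Write named columns (first should be ``time_ns``) as CSV.

    NaN values are rejected — a silent NaN in a reported series is always an
    upstream bug here.  ``json_mirror=True`` writes ``<path>.json`` alongside.
    """
    import pandas as pd

    df = pd.DataFrame(dict(series))
    num = df.select_dtypes(include=[np.number])
    if num.isna().any().any() or not np.isfinite(num.to_numpy(dtype=float)).all():
        raise ValueError("timeseries contains NaN/inf values")
    path = Path(path)
    df.to_csv(path, index=False)
    if json_mirror:
        Path(str(path) + ".json").write_text(
            json.dumps({c: df[c].tolist() for c in df.columns}))


def read_timeseries(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)
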