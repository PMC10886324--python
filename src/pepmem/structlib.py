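"""Secondary-structure class fractions and rigid-body superposition RMSD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SSAssignment", "CoordSet", "ss_fractions", "superpose_rmsd", "coordset_from_pdb"]

# 8-class DSSP-style letters collapsed onto helix / strand / disordered
_CLASS_MAP = {
    "G": "H", "H": "H", "I": "H",
    "E": "B", "B": "B",
    "T": "T", "S": "T", "C": "T", "-": "T", " ": "T",
}


@dataclass(frozen=True)
class SSAssignment:
    """Per-residue secondary-structure string (H/B/T or 8-class letters)."""

    classes: str

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("empty secondary-structure assignment")
        bad = sorted(set(self.classes) - set(_CLASS_MAP))
        if bad:
            raise ValueError(f"unknown secondary-structure letters: {bad}")

    def collapsed(self) -> str:
        return "".join(_CLASS_MAP[c] for c in self.classes)


@dataclass(frozen=True)
class CoordSet:
    """Ordered atom labels with N x 3 coordinates in Angstrom."""

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError("coordinates must be a non-empty N x 3 array")
        if len(self.labels) != c.shape[0]:
            raise ValueError("label/coordinate count mismatch")
        if not np.isfinite(c).all():
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", c)


def ss_fractions(a: SSAssignment | str) -> tuple[float, float, float]:
    """Percentages (H, B, T) of helix, strand and disordered residues.

    Extended 8-class letters are collapsed first; the three values sum to
    100 exactly up to floating rounding.
    """
    if isinstance(a, str):
        a = SSAssignment(a)
    s = a.collapsed()
    n = len(s)
    return tuple(100.0 * s.count(c) / n for c in "HBT")  # type: ignore[return-value]


def superpose_rmsd(a: CoordSet | np.ndarray, b: CoordSet | np.ndarray) -> float:
    """Least-squares superposition RMSD in Angstrom (Kabsch, proper rotation).

    Atom correspondence is positional.  Both sets are centred, the optimal
    rotation is taken from the SVD of the covariance with the determinant
    constrained to +1 (no reflection), and the residual RMSD is returned.
    """
    xa = a.coords if isinstance(a, CoordSet) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, CoordSet) else np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"atom count mismatch: {xa.shape[0]} vs {xb.shape[0]}")
    pa = xa - xa.mean(axis=0)
    pb = xb - xb.mean(axis=0)
    u, s, vt = np.linalg.svd(pa.T @ pb)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = pa @ rot - pb
    return float(np.sqrt((diff**2).sum() / xa.shape[0]))


def coordset_from_pdb(path: str, ca_only: bool = False) -> CoordSet:
    """Read a CoordSet from a PDB file, optionally C-alpha atoms only."""
    import MDAnalysis as mda

    u = mda.Universe(path)
    g = u.select_atoms("name CA") if ca_only else u.atoms
    if g.n_atoms == 0:
        raise ValueError(f"no atoms selected from {path}")
    labels = tuple(f"{r}:{n}" for r, n in zip(g.resids, g.names))
    return CoordSet(labels, g.positions.astype(float))
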