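"""Shrake-Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius (default 1.4 A, a water molecule)
and covered with a deterministic golden-spiral point set; a point is
accessible when it lies outside every neighbouring inflated sphere.  The
per-atom area is the accessible fraction of the inflated sphere's area.
Neighbour culling uses a KD-tree, so the cost is O(N log N + N * points).

Atom radii are the GB intrinsic radii carried by the topology: a single
radius table serves both the surface and the implicit-solvent stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .mdio import Frame, Topology

__all__ = ["SASAResult", "sasa", "sphere_points"]


@dataclass(frozen=True)
class SASAResult:
    """Per-atom and total solvent-accessible area in A^2."""

    per_atom: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@lru_cache(maxsize=8)
def _unit_sphere(n: int) -> np.ndarray:
    return sphere_points(n)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere (n x 3)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    top: Topology,
    frame: Frame,
    subset: np.ndarray | None = None,
    probe: float = 1.4,
    points: int = 960,
) -> SASAResult:
    """Shrake-Rupley SASA of ``subset`` atoms (default: all) in A^2.

    ``subset`` may be a boolean mask or integer index array over the
    topology's atoms; only subset atoms occlude each other (the rest of the
    system is treated as absent, which is what the buried-interface-area
    bookkeeping requires).
    """
    if subset is None:
        idx = np.arange(top.n_atoms)
    else:
        subset = np.asarray(subset)
        idx = np.nonzero(subset)[0] if subset.dtype == bool else subset
    if idx.size == 0:
        raise ValueError("empty atom subset")
    radii = top.gb_radius[idx]
    if not np.isfinite(radii).all() or (radii <= 0).any():
        raise ValueError("every subset atom needs a positive radius")
    xyz = frame.coords[idx]
    inflated = radii + probe
    unit = _unit_sphere(points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * inflated.max()
    pairs = tree.query_ball_point(xyz, r=max_reach + 1e-9)

    per_atom = np.empty(idx.size)
    for i in range(idx.size):
        neigh = [j for j in pairs[i] if j != i]
        test = xyz[i] + inflated[i] * unit
        if neigh:
            nxyz = xyz[neigh]
            nrad = inflated[neigh]
            # keep only spheres that can actually reach atom i's surface
            d = np.linalg.norm(nxyz - xyz[i], axis=1)
            close = d < inflated[i] + nrad
            nxyz, nrad = nxyz[close], nrad[close]
        if neigh and len(nxyz):
            d2 = ((test[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nrad**2)[None, :] - 1e-12).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    return SASAResult(per_atom, probe, points)
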