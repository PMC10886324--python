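"""Adsorption geometry: COM distance, depth to the phosphate plane,
peptide-membrane interaction area.

Distances are computed in Angstrom internally and reported in nm (the
convention of the adsorption literature); areas stay in A^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdio import Topology, Trajectory
from .surfgeo import sasa

__all__ = [
    "AdsorptionProfile",
    "com_distance_series",
    "adsorption_depth",
    "interaction_area_series",
    "analyze_adsorption",
]


@dataclass
class AdsorptionProfile:
    """Per-frame adsorption geometry plus trailing-window means.

    ``com_nm`` is the signed peptide-membrane COM separation along the
    membrane normal, ``com_mag_nm`` its 3D magnitude, ``phosphate_ref_nm``
    the upper phosphate plane's distance from the membrane COM (the "P"
    reference line), ``depth_nm`` the unsigned peptide-COM-to-phosphate-COM
    distance with ``depth_signed_nm`` negative once the peptide passes below
    the head-group plane.
    """

    times: np.ndarray
    com_nm: np.ndarray
    com_mag_nm: np.ndarray
    phosphate_ref_nm: np.ndarray
    depth_nm: np.ndarray
    depth_signed_nm: np.ndarray
    area_A2: np.ndarray | None
    window_ns: float
    depth_mean_nm: float
    area_mean_A2: float | None


def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _segment_masks(top: Topology) -> tuple[np.ndarray, np.ndarray]:
    pep = top.segment == "PEP"
    memb = top.segment == "MEMB"
    if not pep.any():
        raise ValueError("no PEP segment in topology")
    if not memb.any():
        raise ValueError("no MEMB segment in topology")
    return pep, memb


def com_distance_series(top: Topology, traj: Trajectory, normal=(0.0, 0.0, 1.0)):
    """Signed/unsigned COM separation per frame, in nm.

    Returns ``(times, signed_nm, magnitude_nm, phosphate_ref_nm)``: the
    mass-weighted peptide COM relative to the membrane COM projected on the
    membrane normal, its 3D magnitude, and the distance of the proximal
    (upper-leaflet) phosphate COM from the membrane COM along the normal.
    """
    pep, memb = _segment_masks(top)
    n_hat = np.asarray(normal, dtype=float)
    n_hat /= np.linalg.norm(n_hat)
    phos = (top.name == "P") & memb & (top.lipid_type != "CHOL")

    signed = np.empty(traj.n_frames)
    mag = np.empty(traj.n_frames)
    pref = np.empty(traj.n_frames)
    for i, fr in enumerate(traj):
        cp = _com(fr.coords[pep], top.mass[pep])
        cm = _com(fr.coords[memb], top.mass[memb])
        dvec = cp - cm
        signed[i] = dvec @ n_hat
        mag[i] = np.linalg.norm(dvec)
        if phos.any():
            upper = phos & ((traj.coords[i] - cm) @ n_hat > 0)
            pref[i] = (_com(fr.coords[upper], top.mass[upper]) - cm) @ n_hat if upper.any() else np.nan
        else:
            pref[i] = np.nan
    return traj.times.copy(), signed / 10.0, mag / 10.0, pref / 10.0


def adsorption_depth(top: Topology, traj: Trajectory, window_ns: float = 50.0,
                     normal=(0.0, 0.0, 1.0)):
    """Distance of the peptide COM to the proximal phosphate-head COM, nm.

    Returns ``(times, depth_nm, depth_signed_nm, window_mean_nm)``; the mean
    is taken over the trailing ``window_ns`` ns.  The signed variant goes
    negative when the peptide COM crosses below the head-group plane.
    """
    pep, memb = _segment_masks(top)
    n_hat = np.asarray(normal, dtype=float)
    n_hat /= np.linalg.norm(n_hat)
    phos = (top.name == "P") & memb & (top.lipid_type != "CHOL")
    if not phos.any():
        raise ValueError("no phosphate head sites in the membrane (pure CHOL?)")

    signed = np.empty(traj.n_frames)
    for i, fr in enumerate(traj):
        cm = _com(fr.coords[memb], top.mass[memb])
        upper = phos & ((fr.coords - cm) @ n_hat > 0)
        if not upper.any():
            raise ValueError("no upper-leaflet phosphate sites")
        zp = (_com(fr.coords[upper], top.mass[upper]) - cm) @ n_hat
        zc = (_com(fr.coords[pep], top.mass[pep]) - cm) @ n_hat
        signed[i] = zc - zp
    depth = np.abs(signed) / 10.0
    signed = signed / 10.0
    t_end = traj.times[-1]
    in_win = traj.times >= t_end - window_ns + 1e-12
    return traj.times.copy(), depth, signed, float(depth[in_win].mean())


def interaction_area_series(top: Topology, traj: Trajectory, probe: float = 1.4,
                            points: int = 960, halved: bool = False) -> np.ndarray:
    """Buried-SASA interaction area per frame, A^2.

    A_int(t) = SASA(peptide) + SASA(membrane) - SASA(complex), all three in
    the complex-frame positions — i.e. total buried area counting both
    surfaces.  ``halved=True`` returns the interface-area convention
    (one side) instead.
    """
    pep, memb = _segment_masks(top)
    out = np.empty(traj.n_frames)
    for i, fr in enumerate(traj):
        a_p = sasa(top, fr, pep, probe, points).total
        a_m = sasa(top, fr, memb, probe, points).total
        a_c = sasa(top, fr, pep | memb, probe, points).total
        out[i] = a_p + a_m - a_c
    return out / 2.0 if halved else out


def analyze_adsorption(top: Topology, traj: Trajectory, window_ns: float = 50.0,
                       with_area: bool = True, probe: float = 1.4,
                       points: int = 960, area_stride: int = 1) -> AdsorptionProfile:
    """Bundle COM distance, depth and (optionally strided) interaction area."""
    times, com_nm, com_mag, pref = com_distance_series(top, traj)
    _, depth, depth_signed, depth_mean = adsorption_depth(top, traj, window_ns)
    area = None
    area_mean = None
    if with_area:
        sub = Trajectory(traj.coords[::area_stride], traj.times[::area_stride], traj.box)
        area_sub = interaction_area_series(top, sub, probe, points)
        area = np.interp(times, sub.times, area_sub)
        in_win = sub.times >= traj.times[-1] - window_ns + 1e-12
        area_mean = float(area_sub[in_win].mean())
    return AdsorptionProfile(times, com_nm, com_mag, pref, depth, depth_signed,
                             area, window_ns, depth_mean, area_mean)
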