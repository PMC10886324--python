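"""Electric-dipole orientation of the peptide on the membrane.

The dipole is mu = sum_i q_i (x_i - COM) over the group, COM mass-weighted
(for a net-charged peptide the dipole is origin-dependent; the molecular COM
is the fixed convention here).  Its cosine against the membrane normal
classifies the pose: cos ~ -1 points toward the membrane (antiparallel to
the outward normal), ~0 lies parallel to the surface, ~+1 points away.
Class boundaries are symmetric tertiles (+-1/3) and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdio import Frame, Topology, Trajectory

__all__ = ["DipoleSeries", "electric_dipole", "orientation_series", "classify_cos"]


@dataclass
class DipoleSeries:
    """Per-frame dipole vectors (e*A), cosines, classes and stability.

    ``stability`` is the standard deviation of cos(theta) over a sliding
    window (default 10 ns): small values mean a locked orientation.
    ``cos_theta`` is NaN for frames with a vanishing dipole.
    """

    times: np.ndarray
    mu: np.ndarray
    cos_theta: np.ndarray
    classes: np.ndarray
    stability: np.ndarray
    threshold: float

    def residence_fractions(self) -> dict[str, float]:
        ok = self.classes != "undefined"
        n = max(int(ok.sum()), 1)
        return {c: float((self.classes == c).sum()) / n
                for c in ("toward", "parallel", "away")}


def electric_dipole(top: Topology, frame: Frame, group: np.ndarray | None = None) -> np.ndarray:
    """Electric dipole moment of the group in e*A, about the group's COM."""
    if group is None:
        group = np.ones(top.n_atoms, dtype=bool)
    group = np.asarray(group)
    idx = np.nonzero(group)[0] if group.dtype == bool else group
    if idx.size == 0:
        raise ValueError("empty group for dipole computation")
    xyz = frame.coords[idx]
    m = top.mass[idx]
    com = (xyz * m[:, None]).sum(axis=0) / m.sum()
    return (top.charge[idx][:, None] * (xyz - com)).sum(axis=0)


def classify_cos(c: float, threshold: float = 1.0 / 3.0) -> str:
    if np.isnan(c):
        return "undefined"
    if c < -threshold:
        return "toward"
    if c > threshold:
        return "away"
    return "parallel"


def orientation_series(
    top: Topology,
    traj: Trajectory,
    normal=(0.0, 0.0, 1.0),
    group_segment: str = "PEP",
    threshold: float = 1.0 / 3.0,
    stability_window_ns: float = 10.0,
) -> DipoleSeries:
    """Dipole orientation time series of one segment against the normal."""
    n_hat = np.asarray(normal, dtype=float)
    n_hat /= np.linalg.norm(n_hat)
    group = top.segment == group_segment
    if not group.any():
        raise ValueError(f"no atoms in segment {group_segment!r}")

    mu = np.empty((traj.n_frames, 3))
    cos = np.empty(traj.n_frames)
    for i, fr in enumerate(traj):
        mu[i] = electric_dipole(top, fr, group)
        norm = np.linalg.norm(mu[i])
        cos[i] = mu[i] @ n_hat / norm if norm > 1e-12 else np.nan
    classes = np.array([classify_cos(c, threshold) for c in cos])

    stability = np.full(traj.n_frames, np.nan)
    for i in range(traj.n_frames):
        sel = np.abs(traj.times - traj.times[i]) <= stability_window_ns / 2.0
        vals = cos[sel]
        vals = vals[~np.isnan(vals)]
        if vals.size >= 2:
            stability[i] = float(vals.std())
    return DipoleSeries(traj.times.copy(), mu, cos, classes, stability, threshold)
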