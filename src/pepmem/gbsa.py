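"""End-state MM-GBSA binding free energy.

Single-trajectory protocol: for each snapshot the complex, the membrane and
the peptide are evaluated in identical coordinates and

    G_tot = H_MM + G_solv_pol + G_solv_np - T dS_conf
    dG_bind = G_tot(complex) - G_tot(membrane) - G_tot(peptide)

H_MM is the molecular-mechanics energy (harmonic bonds, 12-6 Lennard-Jones
with Lorentz-Berthelot combination, direct Coulomb over all nonbonded pairs
— no cutoff, these are end-state snapshots, not dynamics).  G_solv_pol is
the Still pairwise generalized-Born energy on OBC-II effective radii.
G_solv_np = gamma * SASA + b is the linear nonpolar model (gamma = 0.00542
kcal/mol/A^2, b = 0.92 kcal/mol, probe 1.4 A).  T dS_conf defaults to 0 —
the usual single-trajectory approximation.

Because the three subsets share coordinates, all intramolecular terms
(bonds, intrasegment LJ/Coulomb/self-GB contributions of an isolated
subset) cancel exactly in dG_bind; what remains is the intersegment
interaction plus the desolvation response of the GB and SASA terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mdio import Frame, Topology, Trajectory
from .surfgeo import sasa

__all__ = [
    "GBParams",
    "EnergyDecomposition",
    "BindingFreeEnergy",
    "gb_effective_radii",
    "gb_polar_energy",
    "mm_energy",
    "nonpolar_energy",
    "free_energy",
    "mmgbsa_binding",
]

COULOMB_K = 332.0636  # kcal * A / (mol * e^2)


@dataclass(frozen=True)
class GBParams:
    """Generalized-Born / nonpolar model constants.

    OBC-II shape parameters (alpha, beta, gamma_obc) = (1.0, 0.8, 4.85);
    ``obc_offset`` is the dielectric radius offset, kept at 0 here so an
    isolated atom's effective radius equals its intrinsic radius exactly
    and the analytic Born limit is reproduced; ``scale`` is the uniform
    HCT descreening factor.  ``kappa`` (1/A) enables Debye salt screening
    when nonzero.
    """

    eps_in: float = 1.0
    eps_out: float = 78.5
    probe: float = 1.4
    gamma: float = 0.00542  # kcal/mol per A^2 of SASA
    b: float = 0.92         # kcal/mol
    alpha: float = 1.0
    beta: float = 0.8
    gamma_obc: float = 4.85
    obc_offset: float = 0.0
    scale: float = 0.8
    kappa: float = 0.0
    coulomb_k: float = COULOMB_K
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("need eps_out > eps_in >= 1")
        if self.probe <= 0:
            raise ValueError("probe radius must be positive")


@dataclass(frozen=True)
class EnergyDecomposition:
    """Energy terms of one subset in one frame, kcal/mol."""

    bonded: float
    lj: float
    coulomb: float
    g_pol: float
    g_np: float
    t_ds: float = 0.0

    @property
    def h_mm(self) -> float:
        return self.bonded + self.lj + self.coulomb

    @property
    def g_tot(self) -> float:
        return self.h_mm + self.g_pol + self.g_np - self.t_ds


@dataclass
class BindingFreeEnergy:
    """Per-frame dG_bind with ensemble mean, standard error and term split."""

    times: np.ndarray
    dg: np.ndarray
    terms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.dg.mean())

    @property
    def sem(self) -> float:
        n = len(self.dg)
        return float(self.dg.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    def term_means(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.terms.items()}


def _subset_indices(top: Topology, subset) -> np.ndarray:
    if subset is None:
        return np.arange(top.n_atoms)
    subset = np.asarray(subset)
    idx = np.nonzero(subset)[0] if subset.dtype == bool else subset.astype(int)
    if idx.size == 0:
        raise ValueError("empty subset")
    return idx


def gb_effective_radii(top: Topology, frame: Frame, subset=None,
                       params: GBParams = GBParams()) -> np.ndarray:
    """OBC-II pairwise-descreening effective Born radii (A) of the subset.

    Uses the HCT pairwise descreening integral with a uniform scaling
    factor, rescaled through the OBC tanh form.  For an isolated atom the
    effective radius equals the intrinsic radius (with the default zero
    dielectric offset).
    """
    idx = _subset_indices(top, subset)
    rho = top.gb_radius[idx] - params.obc_offset
    if (rho <= 0).any() or not np.isfinite(rho).all():
        raise ValueError("nonpositive intrinsic GB radius")
    xyz = frame.coords[idx]
    n = idx.size

    r = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    s = params.scale * rho  # descreening radii of the "other" atoms
    np.fill_diagonal(r, np.inf)

    sj = np.broadcast_to(s[None, :], (n, n))
    rho_i = np.broadcast_to(rho[:, None], (n, n))
    upper = r + sj
    lower = np.maximum(rho_i, np.abs(r - sj))
    active = rho_i < upper  # atom j actually descreens atom i
    np.fill_diagonal(active, False)

    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            1.0 / lower - 1.0 / upper
            + (r / 4.0) * (1.0 / upper**2 - 1.0 / lower**2)
            + (1.0 / (2.0 * r)) * np.log(lower / upper)
            + (sj**2 / (4.0 * r)) * (1.0 / lower**2 - 1.0 / upper**2)
        )
        # atom i engulfed by j's descreening sphere
        engulfed = rho_i < sj - r
        term = term + np.where(engulfed, 2.0 * (1.0 / rho_i - 1.0 / lower), 0.0)
    term = np.where(active, term, 0.0)
    integral = 0.5 * term.sum(axis=1)

    psi = integral * rho
    t = np.tanh(params.alpha * psi - params.beta * psi**2 + params.gamma_obc * psi**3)
    inv_reff = 1.0 / rho - t / top.gb_radius[idx]
    if (inv_reff <= 0).any():
        raise ValueError("nonpositive inverse effective radius (overlapping system?)")
    return 1.0 / inv_reff


def gb_polar_energy(top: Topology, frame: Frame, subset=None,
                    params: GBParams = GBParams(),
                    radii: np.ndarray | None = None) -> float:
    """Still-form pairwise GB polar solvation energy, kcal/mol.

    E = -1/2 k_e (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_ij with
    f_ij = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j)); the i = j terms are
    the Born self energies.  With kappa > 0 the prefactor gains the
    Debye-Hueckel screening exp(-kappa f)/eps_out form.
    """
    idx = _subset_indices(top, subset)
    q = top.charge[idx]
    if radii is None:
        radii = gb_effective_radii(top, frame, idx, params)
    xyz = frame.coords[idx]
    r2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1)
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    if params.kappa > 0:
        dielectric = 1.0 / params.eps_in - np.exp(-params.kappa * f) / params.eps_out
    else:
        dielectric = 1.0 / params.eps_in - 1.0 / params.eps_out
    qq = q[:, None] * q[None, :]
    return float(-0.5 * params.coulomb_k * (dielectric * qq / f).sum())


def mm_energy(top: Topology, frame: Frame, subset=None,
              params: GBParams = GBParams(),
              include_coulomb: bool = True) -> tuple[float, float, float]:
    """(bonded, LJ, Coulomb) molecular-mechanics energy of the subset.

    Harmonic bonds E = k (r - r0)^2 over bonds internal to the subset;
    12-6 LJ with Lorentz-Berthelot combination and Coulomb/eps_in over all
    nonbonded (non-1-2) pairs, no cutoff.  ``include_coulomb=False`` is the
    strict-prose mode in which H_MM carries only bonded + LJ (the Coulomb
    column is then reported as 0; it cancels in single-trajectory dG
    anyway).
    """
    idx = _subset_indices(top, subset)
    inset = np.zeros(top.n_atoms, dtype=bool)
    inset[idx] = True
    pos = -np.ones(top.n_atoms, dtype=int)
    pos[idx] = np.arange(idx.size)
    xyz = frame.coords[idx]

    bonded = 0.0
    excl = set()
    for bi, (a, b) in enumerate(top.bonds):
        if inset[a] and inset[b]:
            r = float(np.linalg.norm(frame.coords[a] - frame.coords[b]))
            bonded += float(top.bond_k[bi]) * (r - float(top.bond_r0[bi])) ** 2
            excl.add((min(pos[a], pos[b]), max(pos[a], pos[b])))

    n = idx.size
    eps = top.lj_epsilon[idx]
    if not np.isfinite(eps).all():
        raise ValueError("missing LJ parameters")
    rmin_h = top.lj_rmin_half[idx]
    q = top.charge[idx]
    r = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    mask = np.ones(rij.shape, dtype=bool)
    if excl:
        ex = np.array(sorted(excl))
        flat = {(int(a), int(b)) for a, b in ex}
        mask = np.array([(int(a), int(b)) not in flat for a, b in zip(*iu)])
    eps_ij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    rmin_ij = rmin_h[iu[0]] + rmin_h[iu[1]]
    x6 = (rmin_ij / rij) ** 6
    lj = float((eps_ij * (x6**2 - 2.0 * x6))[mask].sum())
    coul = float((params.coulomb_k * q[iu[0]] * q[iu[1]] / (params.eps_in * rij))[mask].sum()) \
        if include_coulomb else 0.0
    return bonded, lj, coul


def nonpolar_energy(top: Topology, frame: Frame, subset=None,
                    params: GBParams = GBParams()) -> float:
    """Linear SASA nonpolar solvation term, gamma * SASA + b (kcal/mol)."""
    area = sasa(top, frame, subset, params.probe, params.sasa_points).total
    return params.gamma * area + params.b


def free_energy(top: Topology, frame: Frame, subset=None,
                params: GBParams = GBParams(), t_ds: float = 0.0,
                include_coulomb: bool = True) -> EnergyDecomposition:
    """Full G_tot decomposition of one subset in one frame."""
    bonded, lj, coul = mm_energy(top, frame, subset, params, include_coulomb)
    g_pol = gb_polar_energy(top, frame, subset, params)
    g_np = nonpolar_energy(top, frame, subset, params)
    return EnergyDecomposition(bonded, lj, coul, g_pol, g_np, t_ds)


def mmgbsa_binding(
    top: Topology,
    traj: Trajectory,
    window_ns: float = 50.0,
    stride: int = 1,
    params: GBParams = GBParams(),
    t_ds: float = 0.0,
    include_coulomb: bool = True,
) -> BindingFreeEnergy:
    """Single-trajectory MM-GBSA dG_bind over the trailing window.

    Complex, membrane and peptide are evaluated on identical frames taken
    every ``stride`` frames from the last ``window_ns`` ns; dG is averaged
    over snapshots with its standard error.
    """
    win = traj.window(window_ns)
    pep = top.segment == "PEP"
    memb = top.segment == "MEMB"
    if not pep.any() or not memb.any():
        raise ValueError("need both PEP and MEMB segments")
    sel = np.arange(0, win.n_frames, stride)
    if sel.size == 0:
        raise ValueError("empty snapshot selection")

    dg = np.empty(sel.size)
    term_names = ("bonded", "lj", "coulomb", "g_pol", "g_np")
    terms = {k: np.empty(sel.size) for k in term_names}
    for oi, fi in enumerate(sel):
        fr = win[int(fi)]
        e_c = free_energy(top, fr, None, params, t_ds, include_coulomb)
        e_m = free_energy(top, fr, memb, params, 0.0, include_coulomb)
        e_p = free_energy(top, fr, pep, params, 0.0, include_coulomb)
        dg[oi] = e_c.g_tot - e_m.g_tot - e_p.g_tot
        for k in term_names:
            terms[k][oi] = getattr(e_c, k) - getattr(e_m, k) - getattr(e_p, k)
    return BindingFreeEnergy(win.times[sel], dg, terms)
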