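"""Shared fixtures: reference peptides and small synthetic systems."""

from __future__ import annotations

import numpy as np
import pytest

from pepmem import memsynth, seqdesc
from pepmem.mdio import Frame, Topology

# the four disulfide-stabilised reference peptides (sequence, amidated)
TABLE_PEPTIDES = {
    "CIDEM-501": ("YCPYGNRLNYWSRARGHIGTKSCRRSY", True, ((2, 23),)),
    "Panulirin": ("SYKARSCTAYGYFCMIPPRCRGTVVANHWCRARGHICCSSPSNVYGKN", True, ()),
    "PaD": ("SYVGDCGSNGGSCVSSYCPYGNRLNYFCPLGRTCCRRSY", True, ()),
    "Ct_PaD": ("YCPYGNRLNYFCPLGRTCCRRSY", True, ()),
}


@pytest.fixture(scope="session")
def cidem():
    seq, amid, ss = TABLE_PEPTIDES["CIDEM-501"]
    return seqdesc.parse_peptide(seq, name="CIDEM-501", amidated=amid, disulfides=ss)


@pytest.fixture(scope="session")
def gn_membrane():
    return memsynth.build_membrane(memsynth.membrane_spec("gn", 25), seed=1)


@pytest.fixture(scope="session")
def cidem_model(cidem):
    return memsynth.build_peptide_model(cidem)


@pytest.fixture(scope="session")
def adsorbed_system(gn_membrane, cidem_model):
    """Noise-free flat adsorption at 0.42 nm planted depth, 60 frames."""
    scen = memsynth.AdsorptionScenario(
        n_frames=60, dt_ns=1.0, tau_ns=5.0, depth_nm=0.42, jitter_sigma=0.0, seed=3)
    return memsynth.generate_trajectory(*gn_membrane, *cidem_model, scen)


def make_atoms(
    coords,
    charge=None,
    gb_radius=2.0,
    segment="PEP",
    lj_epsilon=0.1,
    lj_rmin_half=2.0,
    element="C",
    mass=12.0,
    name="X",
    hbond_role="none",
    resid=None,
    molid=None,
    bonds=(),
    bond_k=(),
    bond_r0=(),
    box=(500.0, 500.0, 500.0),
):
    """Hand-build a minimal Topology + Frame for analytic toy tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)

    def arr(v, default):
        if v is None:
            v = default
        return np.asarray(v if np.ndim(v) else [v] * n)

    seg = arr(segment, None)
    top = Topology(
        name=arr(name, None),
        element=arr(element, None),
        resid=arr(resid, list(range(1, n + 1))),
        resname=arr("XXX", None),
        segment=seg,
        molid=arr(molid, list(range(n))),
        lipid_type=np.where(seg == "MEMB", "POPG", "n/a"),
        charge=arr(charge, [0.0] * n),
        mass=arr(mass, None),
        gb_radius=arr(gb_radius, None),
        lj_epsilon=arr(lj_epsilon, None),
        lj_rmin_half=arr(lj_rmin_half, None),
        hbond_role=arr(hbond_role, None),
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        bond_k=np.asarray(bond_k, dtype=float),
        bond_r0=np.asarray(bond_r0, dtype=float),
    )
    return top, Frame(coords, box)
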