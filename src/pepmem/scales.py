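"""Per-residue scale tables shipped as versioned data files.

Two scales are bundled:

``boman2003``
    Per-residue transfer (solubility) free energies in kcal/mol, signed so
    hydrophilic residues are positive.  Their arithmetic mean over a sequence
    is the Boman index, a proxy for protein/membrane binding potential.
``eisenberg_consensus``
    The dimensionless Eisenberg consensus hydrophobicity scale used for the
    hydrophobic moment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named residue-letter -> value table covering all 20 amino acids."""

    scale_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.scale_id!r} missing residues: {sorted(missing)}")
        for aa, v in self.values.items():
            if not (v == v and abs(v) < float("inf")):
                raise ValueError(f"scale {self.scale_id!r} has non-finite value for {aa}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def load_scale(scale_id: str) -> HydrophobicityScale:
    """Load a bundled scale by id (file ``data/<scale_id>.csv``)."""
    ref = resources.files("pepmem") / "data" / f"{scale_id}.csv"
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return HydrophobicityScale(scale_id, {r["residue"]: float(r["value"]) for r in rows})


BOMAN_2003 = load_scale("boman2003")
EISENBERG = load_scale("eisenberg_consensus")
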