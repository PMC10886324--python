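# Methods

This note documents the models implemented in `pepmem`, the conventions and
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Sequence descriptors

**Net charge** is integer formal counting at pH 7: +1 per Arg and Lys, +1
for the N-terminal amine, −1 per Asp and Glu, −1 for a free C-terminal
carboxylate (0 when amidated); His is treated as neutral (pKa ≈ 6) and Cys
as neutral (pKa ≈ 8.3), which makes disulfide-bonded Cys trivially neutral
as well.  Formal counting, not Henderson–Hasselbalch titration, is the
convention under which the reference table's printed charges (7+, 8+, 4+,
5+) are reproduced exactly; a fractional titration model would not return
integers.

**Aliphatic index** follows Ikai: `AI = X_Ala + 2.9·X_Val + 3.9·(X_Ile +
X_Leu)` with mole percentages.  Values are kept at full precision and
rounded only for display.

**Boman index** is the arithmetic mean of the per-residue transfer
(solubility) free energies of the Boman (2003) scale, shipped as a
versioned CSV data file (`data/boman2003.csv`), signed so hydrophilic
residues are positive.  A higher value indicates a stickier,
protein/membrane-binding-prone sequence.

**Hydrophobic moment** uses the Eisenberg consensus scale
(`data/eisenberg_consensus.csv`): `μH = |Σ_k H_k (cos kδ, sin kδ)| / N`.
Both the per-residue rotation δ and the windowing are exposed.  The
command and `descriptors()` default is **whole-sequence, δ = 160°** — the
β-strand periodicity.  This is a deliberate, validated choice: the
reference peptides are β-hairpins, and only this convention reproduces all
four printed moments (0.15 / 0.17 / 0.16 / 0.26); the α-helical δ = 100°
convention (whole-sequence or 11-residue windowed-max) reproduces none of
them.  The helical convention remains available via
`hydrophobic_moment(p, delta=100, mode="windowed")`.

**Mean residue ellipticity**: `[θ]_MRW = θ_mdeg · MRW / (10 · c · L)` with
c in g/mL and L in cm, and `MRW = MW / (N − 1)` (peptide-bond count, the
CD normalisation convention).  Molecular weight is the average mass from
Biopython, corrected by −0.984 Da for C-terminal amidation and −2.016 Da
per disulfide.

## Secondary structure and superposition

Eight-class secondary-structure letters collapse as G/H/I → H, E/B → B,
T/S/C/−/blank → T before computing H:B:T percentages.  Assignments are
inputs; no DSSP-style assignment from coordinates is attempted.
Superposition RMSD is the Kabsch least-squares solution with the SVD
determinant constrained to +1 (reflections disallowed), correspondence by
atom order.  The test suite cross-checks it against an independent
quaternion (Horn) implementation.

## System containers and I/O

A system is a `Topology` (flat numpy arrays: names, elements, 1-based
residue ids, PEP/MEMB segment, molecule id, lipid type, partial charge,
mass, GB intrinsic radius, Lennard-Jones ε and r_min/2, H-bond role, bonds
with harmonic k and r₀) plus a `Trajectory` (F×N×3 Å, uniform times in
ns, orthorhombic box).  On disk: a versioned JSON topology sidecar (PSF
and PRMTOP cannot carry the H-bond roles and GB radii this pipeline
needs), a PDB for the first frame, a CHARMM-style DCD (or multi-frame XYZ)
for coordinates, and a small `trajectory_meta.json` holding the frame
spacing, which DCD does not carry in ns.  Coordinates are Ångström
internally; distances are converted to nm only in reported adsorption
series.  Full-precision coordinate round-trips go through DCD (float32,
~2×10⁻⁶ Å at box scale) or XYZ; PDB's fixed format limits that path to
10⁻³ Å.

## The synthetic-data generator

The generator's defaults are the study conditions of the adsorption
problem it emulates: membrane compositions GN = 80:8:12 POPE/POPG/TMCL,
GP = 60:40 DOPG/TMCL, Zw = 60:40 DOPC/cholesterol (largest-remainder
rounding to integer lipid counts), initial peptide COM 30 Å above the
membrane COM, two poses related by a 180° in-plane-axis rotation, a
default planted depth of 0.42 nm, and trailing-window analyses over the
last 50 ns.

**Membrane.** Each leaflet is a square grid (area per lipid 65 Ų,
uniform ±1 Å xy jitter) of coarse pseudo-lipids: PG lipids have a single
−1 phosphate bead at the plane; PE/PC a +1/−1 zwitterionic pair lying
side-by-side in the head plane (so nothing protrudes toward the adsorbed
peptide); cardiolipin two −1 phosphates; cholesterol a neutral head.
Neutral tail beads extend toward the core at 4 Å spacing.  Phosphate beads
sit exactly at ±z_P (default 18 Å) and the lower leaflet is the exact
z-mirror of the upper, so the bilayer COM is exactly z = 0 and leaflet
charges are analytic (e.g. a 20-lipid GP leaflet carries −(12 + 2·8) e).

**Peptide.** A rigid flat β-hairpin scaffold: one backbone bead per
residue (3.5 Å spacing, two antiparallel strands 4.8 Å apart) carrying the
residue's average mass; Arg/Lys add a +1 donor side bead with a polar H,
Asp/Glu a −1 acceptor bead, and polar residues (S/T/Y/N/Q/W/H) a neutral
donor/H pair; a +1 N-terminal site and, for free C-termini, a −1 site.
The model's formal charge therefore equals the sequence-level net charge
exactly.  Side sites sit 1.2 Å and polar H 2.2 Å below the backbone
plane, keeping a ≥2 Å clearance above the head-group plane at the default
depth.  Lennard-Jones beads are soft (r_min/2 = 1.2 Å, ε = 0.1) because
the scripted geometries are not force-field-relaxed.

**Kinematics.** The peptide COM follows `z(t) = z_f + (z₀ − z_f)·e^(−t/τ)`
above the membrane COM, where z_f realises the planted depth above the
phosphate plane; a scenario that would place the COM below the head
region raises.  If a dipole schedule is given, each frame is rigidly
rotated so the dipole cosine equals the scheduled value (pose model2
realises the negated schedule — the 180° flip); without a schedule the
peptide stays flat, which is also the physically faithful default for an
extended hairpin (driving cos θ to ±1 necessarily tilts a rigid elongated
body steeply).  Gaussian jitter of width σ is added to peptide atoms only,
from one `numpy` generator seeded per scenario; the seed is recorded in
the output metadata.  Engine conditions (310 K, 150 mM salt, 1 atm) are
provenance metadata only — no forces are integrated.

**Planted truth.** Contact plants relocate upper-leaflet *anionic* lipids
(their heads are bare phosphates, so relocation cannot bury a choline bead
in the peptide) to 2.5 Å under the designated residue; H-bond plants place
an acceptor phosphate 2.8 Å from the donor along the donor–H axis (180°).
Because the relocations shift the membrane COM that the peptide path
references, the planting runs a short fixed-point iteration (4 passes,
contraction ≈ moved-mass fraction) so the final geometry meets the
criterion distances exactly.  The `GroundTruth` records, per frame and
noise-free: COM distance, depth, dipole cosine, and the contact pairs and
H-bond triples evaluated by direct brute-force distance/angle scans —
independent of the KD-tree implementations the analysis stages use.

**What the generator does not emulate**: membrane undulations and lipid
diffusion, peptide internal flexibility, solvent and ions, force-balanced
contact distances, pore formation.  Passing recovery tests therefore
demonstrate that the *measurement* pipeline is exact and unbiased on known
inputs, not that the generator reproduces all-atom physics.

## Surface area

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points) on each atom's sphere inflated by the probe (default 1.4 Å, a
water radius); neighbours are culled with a KD-tree.  Atom radii are the
GB intrinsic radii from the topology — one radius table serves both the
surface and the implicit-solvent stages.  The estimate is exactly
translation-invariant; under rotation it is invariant only to the
O(1/points) discretisation noise (~10⁻⁴ relative at 960 points), like any
fixed-point-set implementation.  Doubling the point count moves totals by
<0.2 %.

Interaction area is reported **unhalved**, `SASA(A) + SASA(B) −
SASA(AB)` — total buried surface counting both sides, the convention under
which a flat-lying 27-mer buries on the order of 10³ Ų; `halved=True`
gives the one-sided interface area.

## Adsorption geometry

COM distance is mass-weighted, reported both signed along the membrane
normal and as a 3D magnitude (the figure convention is unstated in the
adsorption literature, so both are emitted), together with the
phosphate-plane reference ("P" line).  Depth is the distance of the
peptide COM to the mass-weighted COM of upper-leaflet phosphate beads,
reported unsigned (the table convention) with a signed companion that goes
negative once the peptide crosses the head-group plane.  Window averages
default to the trailing 50 ns, harmonised across contacts and MM-GBSA.

## Dipole orientation

`μ = Σ qᵢ(xᵢ − COM)` with the mass-weighted COM as origin — mandatory for
a net-charged peptide, whose dipole is otherwise origin-dependent.
cos θ = μ̂·n̂ against the membrane normal; classes use symmetric tertiles
(toward < −1/3 < parallel < +1/3 < away), the symmetric reading of the
−1/0/+1 anchor interpretation, configurable.  Frames with ‖μ‖ ≈ 0 yield
NaN cosines and an "undefined" class rather than an arbitrary number.
Stability is the cos θ standard deviation over a 10 ns sliding window.

## Contacts and hydrogen bonds

A contact is a (peptide residue, lipid **molecule**) pair with any
heavy-atom distance ≤ 3 Å.  Counting distinct molecules, not atom pairs,
is what gives occupancy its >100 % semantics: a residue permanently
bridging k lipids scores exactly 100·k %.  Hydrogens are excluded from the
3 Å criterion (with hydrogens it double-counts bonded geometry).
H-bonds use the common MD geometric criterion — donor-heavy–acceptor
≤ 3.5 Å and donor–H–acceptor angle ≥ 150°, donor and acceptor in different
segments — because no criterion is standard-free; both thresholds are
flags, so the stricter 3.0 Å/160° dialect is reachable.  Donors are
located through the polar H's bonded donor-heavy atom; an orphaned polar H
is a topology error, not a silent skip.

## MM-GBSA

Single-trajectory end-state protocol: complex, membrane and peptide are
evaluated on identical snapshots (trailing window, configurable stride),
`G_tot = H_MM + G_solv-pol + G_solv-np − TΔS_conf` per subset and
`ΔG_bind = G_tot(complex) − G_tot(mem) − G_tot(pep)` per frame, then mean
± standard error.

* **H_MM**: harmonic bonds, 12-6 LJ with Lorentz–Berthelot combination,
  and direct Coulomb (ε_in = 1) over all non-1-2 pairs with no cutoff —
  these are end-state snapshots, not dynamics.  Intramolecular Coulomb is
  included although a strict reading of the energy decomposition lists
  only "bonded and Lennard-Jones": standard MM-GBSA requires it, and it
  cancels identically in the single-trajectory ΔG; `include_coulomb=False`
  gives the strict-prose mode.
* **G_solv-pol**: Still-form pairwise GB,
  `−½ k_e (1/ε_in − 1/ε_out) Σ qᵢqⱼ/f_GB`,
  `f_GB = √(r² + RᵢRⱼ e^(−r²/4RᵢRⱼ))`, ε_out = 78.5,
  k_e = 332.0636 kcal·Å/(mol·e²), on OBC-II effective radii (HCT pairwise
  descreening with uniform scale 0.8; tanh shape parameters α, β, γ =
  1.0, 0.8, 4.85).  The dielectric radius offset defaults to 0 rather than
  the conventional 0.09 Å so that an isolated atom's effective radius
  equals its intrinsic radius exactly and the analytic Born energy is
  recovered to machine precision — an internal-consistency choice for a
  pipeline whose radii are model parameters, not element assignments.
  Salt screening is off by default (κ = 0); a Debye screening flag exists.
* **G_solv-np** = γ·SASA + b with γ = 0.00542 kcal/mol/Ų and b = 0.92
  kcal/mol at probe 1.4 Å.  γ is printed in the source literature as
  kcal/mol/Å; dimensional consistency of a linear SASA model requires
  per Ų and it is applied per Ų here.
* **TΔS_conf** defaults to 0 — the common single-trajectory approximation;
  a supplied value is subtracted per the decomposition identity, which is
  asserted exactly in tests.

Exact consequences used as tests: intramolecular bonded terms cancel in
ΔG to 10⁻⁸; ΔH_MM equals the intersegment LJ + Coulomb; two neutral,
LJ-free, well-separated particles give ΔG = −b exactly (three b constants
minus two); a single ion reproduces the analytic Born energy to 10⁻⁶
relative.

**Known limitation**: on the coarse generator systems the GB desolvation
penalty of a +7 peptide approaching an anionic surface outweighs the
screened Coulomb attraction, so absolute ΔG values are small and can be
positive; the coarse beads carry no counterion release, packing or
hydrophobic-insertion contributions.  Comparative orderings (bound vs
unbound, charged vs neutral surface) are the meaningful outputs at this
resolution, and the analytic/cancellation identities hold regardless.

## Problem sizes and determinism

Defaults used throughout the examples and tests: 16–36 lipids per leaflet
(100–300 membrane beads), a 27-residue peptide (64 beads), 30–500 frames,
SASA at 960 points, MM-GBSA on every 10th trailing-window frame.  These
sizes keep every oracle analytic and the full pipeline in seconds on one
core while exercising all code paths; nothing in the algorithms is
specific to them.  All randomness flows from explicit integer seeds
(membrane jitter and scenario jitter are separately seeded); reruns of a
pipeline config are byte-identical in `summary.json`, with timings
confined to the log file.
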