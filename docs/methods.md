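# Methods

This note documents the models, conventions and numerical choices behind
each computation, and what the synthetic fixtures do and do not emulate.

## Coordinate model and parsing

Structures are read from PDB or mmCIF via gemmi into a
structure → chain → residue → atom hierarchy. Author chain identifiers
and author residue numbering are kept verbatim; peptide positions
p1…pN are resolved by ordinal within the peptide chain, never by
author seq_id, because deposited peptide numbering varies between
entries. Hydrogens and deuterium are discarded at parse time: every
cutoff used downstream (contacts, hydrogen bonds, salt bridges) is a
heavy-atom distance. Alternate-location groups are collapsed to the
highest-occupancy conformer, ties broken by the alphabetically first
altloc letter, so atom counts never increase and each group keeps
exactly one conformer. Only the first model of multi-model files is
used.

Chain roles (MHC heavy chain, β2-microglobulin, peptide, TCRα, TCRβ,
water, hetero) are assigned by length heuristics — 8–11 standard
residues → peptide, 95–105 → β2m, 270–285 → MHC heavy — with explicit
overrides always winning. When exactly two unclassified protein chains
remain they are taken as the TCR pair, the longer as TCRβ (paired
Vβ+Cβ ectodomain constructs run longer than Vα+Cα); equal lengths are
refused with an error rather than guessed, because mislabelling α/β
silently would corrupt every per-chain interface number downstream.

Waters are kept (they are needed for water bridges) but excluded from
all surface computations; hetero ligands such as cryoprotectant
glycerol are likewise excluded by default with an opt-in flag, since
they are crystallization artifacts rather than parts of the complex.

## Solvent-accessible surface area

SASA uses the Shrake-Rupley method: each atom's van der Waals sphere is
expanded by the probe radius (default 1.4 Å, the conventional water
probe) and sampled with a deterministic Fibonacci (golden-spiral)
lattice of n points (default 960); the accessible fraction of points
times the expanded-sphere area is the atom's SASA. The deterministic
lattice makes results bit-reproducible without seeds, and the
single-sphere error is bounded by the lattice discretization
(relative error < 1/√n; exact in expectation).

Radii follow a Chothia-style heavy-atom table: trigonal (sp2) carbon
1.76 Å, tetrahedral carbon 1.87 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å, with
sp2 carbons identified per residue type (carbonyl, aromatic rings,
guanidinium, carboxylate, amide). Published interface areas come from a
variety of engines and radius sets that are rarely stated, so areas
computed here are expected to match printed values within roughly ±5%
or ±10 Å² — tolerance-based agreement is the honest contract, and the
radius table is fully configurable.

Residue-level accounting distinguishes three terms: TSA (the residue's
atoms alone, at crystal coordinates), ASA (the residue within its own
free chain) and BSA = ASA − SASA_in_complex. A fully buried anchor
residue has BSA ≈ ASA; a solvent-facing residue has BSA ≈ 0. Interface
buried area between two groups of chains is Σ(SASA of the side alone −
SASA in the complex), reported per chain and per side; the literature's
single "interface BSA" figure corresponds to one side's total (or the
mean of the two, which differ only through lattice noise and shape
asymmetry).

Interface partitioning attributes per-loop shares on the TCR side
(grouping TCR-side per-residue BSA by CDR annotation), because a TCR
atom's buried area cannot be split between MHC and peptide; the
MHC-vs-peptide split is computed on the pMHC side, where each buried
atom belongs to exactly one target, making the two percentages sum to
100 by construction. Contact-count splits are reported alongside as a
cross-check. CDR ranges are configuration with IMGT defaults (CDR1
27–38, CDR2 56–65, CDR3 105–117); deposited structures keep author
numbering, so per-loop figures should be computed with per-structure
ranges.

## Contacts

Van der Waals contacts are heavy-atom pairs across the interface within
4.0 Å; hydrogen bonds are N/O–N/O pairs within 3.5 Å by distance only
(no donor-acceptor angle term, since crystallographic practice for
interface inventories is distance-based); salt bridges are Asp/Glu
carboxylate oxygens against Lys NZ, Arg NE/NH, or His ring nitrogens
within 4.0 Å, with histidine treated as chargeable. The salt-bridge
label supersedes the hydrogen-bond label for the same pair. Boundaries
are inclusive (≤); the difference from a strict inequality is below
coordinate precision. A water bridge is a water oxygen within the
hydrogen-bond cutoff of at least one polar atom on each side, one
bridge per qualifying partner pair. Neighbour search uses a k-d tree
and is tested to return exactly the brute-force all-pairs set.

## Superposition and docking geometry

Superposition is the closed-form least-squares (Kabsch) solution via
SVD with the reflection branch corrected, so the result is always a
proper rotation; RMSD is the minimized value. Degenerate (collinear)
selections are refused. Side-chain χ angles use the standard
heavy-atom quadruples per residue type, with differences wrapped to
(−180°, 180°] so a change across the ±180° seam reports the small
angle.

Docking geometry follows the common convention for class-I complexes:
peptide axis = best-fit line through peptide Cα oriented p1→pN; TCR
axis = line connecting the Vα and Vβ reference points (midpoint of each
domain's conserved intra-domain disulfide SG atoms when exactly two
cysteines are found in the V region, else the V-region Cα centroid);
platform plane = least-squares plane through the MHC α1/α2 helix Cα
(heavy-chain author residues 50–86 and 138–176 by default). The
crossing angle is measured between the two axes after projection into
the platform plane, in [0°, 180°); the incident angle is the TCR axis'
tilt out of that plane, in [0°, 90°]. Published angles rarely state
their convention, so every element is configurable and agreement within
a few degrees is the realistic expectation.

## Descriptors and dose-response

Per-residue flexibility is the heavy-atom mean B-factor; segment
statistics are mean ± SD across residue means, with the sample SD
(ddof = 1) as default and the population SD available — published
"±" values rarely state which was used. Positional-scanning libraries
substitute every position with the other 19 amino acids in
position-major, alphabetical order (19 × L variants, never the parent).
Neoantigen class assignment is a membership test of the mutated
position against a user-supplied anchor set (for H2-Db: position 5 and
the C-terminus); anchors are inputs, never predicted.

The 4PL model R(d) = bottom + (top − bottom)/(1 + (EC50/d)^hill) is fit
by least squares on log10(dose) via lmfit, hill bounded to (0.1, 10],
initial values from the data range and median log-dose. R(EC50) =
(top + bottom)/2 holds by construction. The 95% EC50 interval is a
seeded residual bootstrap, flagged as such in the output; flat response
vectors are refused rather than fit. Fold-selectivity between two
ligands is the plain EC50 ratio after unit normalisation; the package
reports the computed ratio at full precision rather than a rounded
figure.

## Synthetic fixtures and what passing tests show

The fixture module provides ground truth through two independent
oracles: the closed-form spherical-cap solution for two probe-expanded
spheres, and direct latitude/longitude quadrature over one sphere
against arbitrary occluders (these two agree to 0.1% and arbitrate the
engine). Sphere-cluster fixtures enforce a pairwise-only overlap
constraint — verified via cap geometry — which is exactly the regime
where cap subtraction is additive, so their ledgers are exact. The mock
ternary complex plants a flat platform, a straight peptide, point-like
V domains and a single interface contact, so docking angles and
contact inventories have exact known answers. Titration fixtures sample
a known 4PL curve with Gaussian noise; the default design is 10
half-log doses in triplicate, mirroring standard triplicate-well
cell-assay practice.

These fixtures deliberately lack real-protein features: no packing,
no secondary structure, no correlated B-factors, no heteroscedastic
assay noise. Passing tests therefore demonstrate the correctness of the
algorithms and bookkeeping, not the biological accuracy of any
particular radius set or angle convention on deposited structures; for
real entries the tolerance expectations above apply. Problem sizes in
the test suite and acceptance script (tens of atoms per fixture, 500
and 1000 simulated titrations, 100 random contact fixtures) were chosen
as the smallest sizes at which the statistical claims are stable across
seeds.

## Known limitations

No molecular (Connolly) surface, volumes or ΔG estimates; no
π-stacking or cation-π detection; no automatic CDR numbering from
sequence; no flexible alignment; no 5PL or kinetic (BLI) fitting. The
role heuristics target class-I complexes — class-II MHC or unusual
constructs need explicit role overrides.
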