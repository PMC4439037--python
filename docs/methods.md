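# Methods

This note records the models, conventions and numerical choices behind each
measurement, what the synthetic fixtures do and do not emulate, and the
known limitations.

## Coordinate model

Structures are parsed from PDB or mmCIF via gemmi into a small hierarchy
(Structure → Chain → Residue → Atom) holding a single model in ångströms.
Author residue numbering is authoritative throughout, because comparative
residue labels (vertex/distal/marker residues, strand ranges, loop
definitions) are quoted in author numbering. Alternate locations are
resolved at parse time to the highest-occupancy conformer, ties broken
toward altloc 'A' — deterministic and conventional. Waters and non-polymer
heteroatoms are kept but flagged, and every geometric measurement operates
on polymer heavy atoms only; hydrogens, when present, are ignored (the
crystal structures this package targets are ~2.3 Å and hydrogen-free).

## Superposition and correspondence

Residue correspondence between homologous chains is a global pairwise
alignment of one-letter sequences with fixed scoring (match +1, mismatch 0,
gap open −1, extend −0.5), keeping every aligned column that has a CA atom
on both sides; fewer than 10 pairs is an error. Eph LBDs are similar enough
that the alignment is unambiguous, which is why a sequence method stands in
for the unspecified "corresponding residues" notion. Superposition is the
closed-form Kabsch/SVD solution on paired CA coordinates; a reflection is
corrected by flipping the smallest singular vector so the rotation is always
proper. Fitting CA atoms only makes the fit robust to side-chain
differences between homologs. When a complex is superposed, the fit uses
receptor CAs only and the resulting transform is applied to all atoms of
both chains — this is what isolates the ligand's reorientation.

The test suite checks the Kabsch path against an independent quaternion
(Horn) eigendecomposition and against a 10,000-rotation Monte-Carlo bound.

## Tilt metric

The tilt of a ligand relative to a reference complex is
`raw_angle − reference_angle`, where `raw_angle` is the standard three-atom
angle (arccos of the normalized dot product, in [0, 180]°) at the receptor
vertex residue between the distal receptor residue and the ligand marker
residue, measured on the query complex after trimming both complexes to
their mutually aligned residues and superposing the query receptor onto the
reference receptor. Defaults follow the EphA3/ephrin-A5 convention (vertex
152, distal 180, ligand marker 112, CA atoms).

Choices the measurement leaves open, fixed here and stamped into results:

- **Atom**: CA. Only residues are named by the convention; CA makes the
  measure side-chain independent.
- **Sign**: the tilt is reported signed (raw − reference); comparative
  tables print magnitudes, so `tilt_magnitude_deg` (|tilt| rounded to whole
  degrees) is also provided.
- **Numbering frame**: spec residues are interpreted in the reference
  complex's numbering and mapped into the query through the alignments, so
  homologs with different numbering are handled without user bookkeeping.
- **Order**: trimming precedes superposition.

Rigid-motion invariance is exact by construction (the superposition removes
any rigid transform of the query), and is tested to 1e-6°.

## SASA and interface area

Shrake–Rupley with a deterministic spiral (generalized Fibonacci) lattice:
each heavy atom's probe-expanded sphere carries `n_points` quasi-uniform
test points, and its area is the accessible fraction times
4π(r + probe)². Defaults: probe 1.4 Å, 960 points — quadrature error is
well under 1% on analytic fixtures and halving/doubling the density moves
totals by < 1%. The lattice is deterministic so results are
bit-reproducible without seeds. Radii are a NACCESS-style per-element table
(C 1.70, N 1.65, O 1.40, S 1.85, P 1.80 Å, default 1.80), chosen for
PISA-comparable buried-area magnitudes; pseudo-atoms may carry explicit
radius overrides.

Buried interface area follows the PISA convention:
`bsa_X = SASA(X alone) − SASA(X in complex)` for each chain, and
`interface_area = (bsa_receptor + bsa_ligand)/2`. A residue is listed as
interfacial if it loses > 0.1 Å² SASA or owns a contact. Tiny negative
losses from quadrature on distant chains are clamped to zero.

## Contacts

Candidate pairs are inter-chain heavy-atom pairs within the largest cutoff,
then classified once each with the most specific class winning
(salt > hydrogen bond > vdW):

- vdW: distance ≤ 4.0 Å;
- hydrogen bond: donor/acceptor heavy-atom distance ≤ 3.5 Å and
  antecedent–donor–acceptor angle ≥ 90°, a standard hydrogen-free
  criterion; the antecedent is the donor's nearest same-residue heavy atom
  (≤ 2.0 Å, i.e. its covalent neighbor);
- salt bridge: Asp/Glu side-chain O versus Lys NZ / Arg NE, NH1, NH2 /
  His ND1, NE2 at ≤ 4.0 Å.

The cutoffs are config-overridable; the defaults are the field-standard
values. Donor/acceptor assignments are per-residue tables covering the 20
standard amino acids. The per-residue summary groups contacts by ligand
residue and moiety (backbone = N, CA, C, O, OXT), marks classes, and splits
GH-loop rows (ephrin residues 121–129 by default) from the rest, mirroring
the layout of comparative contact tables.

## Shape complementarity

The Sc statistic uses dot surfaces: dots are generated on each atom's
probe-expanded sphere at a density of 15 dots/Å² (of expanded-sphere area),
filtered to the solvent-accessible subset, and repositioned onto the vdW
sphere with outward normals — a dot approximation of the molecular surface
whose dot count tracks density × SASA. For a buried dot x on surface A with
nearest partner dot x′ on B, `S(x) = (n_x · −n_x′) exp(−w d²)`; the Sc
value is the mean of the two directional medians. Defaults are the original
method's: w = 0.5 Å⁻², interface band 1.5 Å (a dot is buried if its nearest
partner dot is closer than the band), and a 1.5 Å peripheral trim that
drops buried dots near the buried-region boundary (toggleable; it is a
no-op on fixtures that are buried everywhere). On opposing planar grids in
registry the statistic has the closed form exp(−w d²), which the tests
check to 1e-3; the monotone-decay property over separations up to 3 Å is
checked with a wider band, since with the default band surfaces farther
than 1.5 Å apart have no buried dots and correctly raise a no-interface
error.

The dot surface is an approximation to a full Connolly (re-entrant)
molecular surface; convergence with density is checked instead of building
re-entrant patches.

## Strand twist

For a residue range along a strand, twist steps compare residues two apart
— (i, i+2), advancing two residues per step, so an 8-residue strand yields
three steps — which cancels the β-pleat's 180° carbonyl alternation. Each
step projects the two carbonyl C→O vectors onto the plane perpendicular to
the local axis CA(i)→CA(i+2) and takes the signed angle between the
projections (sign from the axis-aligned cross product). The cumulative
twist is the sum of absolute steps. Steps with missing backbone atoms are
skipped and flagged rather than interpolated. Because published cumulative
twist figures do not come with a stated convention, every report carries a
convention stamp and the numbers are treated as comparable only within one
convention; reproducing any particular published twist value is explicitly
not a goal. Reversal symmetry (same cumulative value traversing the strand
backwards) is exact for odd-length ranges, where the forward and backward
stride-2 step sets coincide.

## ITC model

One-set-of-sites (Wiseman) isotherm. With dilution-corrected in-cell totals
M_i (cell species) and X_i (injectant), cumulative heat

    Q_i = (n · M_i · ΔH · V0 / 2) · [ r_i − sqrt(r_i² − 4 X_i/(n M_i)) ],
    r_i = 1 + X_i/(n M_i) + 1/(n K_a M_i)

and per-injection heat with the displacement correction
`ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`. Dilution uses the
overfilled-cell forms `M_i = M0 (1 − v/2V0)/(1 + v/2V0)` and
`X_i = X0 (v/V0)(1 − v/2V0)` with v the cumulative injected volume; the
instrument software's exact injectant correction is not published, so the
standard companion form is used, and simulation, fitting and the
equilibrium-bisection oracle all share it, making the round-trip and oracle
checks insensitive to the choice. Normalized heats are per mole of
injectant in each injection; Gaussian noise, when requested, is applied to
normalized heats under a caller-supplied seed. ΔH < 0 yields negative
(exothermic, downward) pulses.

Fitting minimizes squared residuals of normalized heats over
(n, log₁₀ K_a, ΔH) with `scipy.optimize.least_squares`, excluding the
first injection by default (the customary treatment of the small
pre-injection). Initialization is n = 1, ΔH = first usable heat, and
several K_a starts (1/cell_conc, 10⁴…10¹⁰ M⁻¹) with the lowest-cost
solution kept; non-convergence from every start raises a fit failure.
Asymptotic standard errors come from the Jacobian at the solution (delta
method for K_a). Derived quantities use R = 1.9872 cal mol⁻¹ K⁻¹ and
T = 298.15 K by default: ΔG = −RT ln K_a, TΔS = ΔH − ΔG, K_d = 1/K_a.

The two bundled schedules are the overfilled-cell protocol (2 mL of 10 µM
cell species; one 5 µL then 19 × 15 µL injections of 100 µM injectant) and
a small-cell protocol (300 µL of 46 µM; 19 × 2 µL of 460 µM), both at
25 °C. At the tight-binding end (K_d = 9 nM on the first schedule,
c ≈ 1,100) the titration is nearly a step, so ΔH and n are recovered to
within a percent under 1% noise while K_d is determined only to a small
factor — the expected design limitation, reflected in the different
tolerances of the round-trip checks.

## Synthetic fixtures: what they show and what they do not

The generators produce inputs with analytically known answers:

- **Tilted complexes** — rigid helical CA/N/C/O scaffolds (40-residue
  receptor, 20-residue ligand, seeded random sequences) whose ligand is
  rotated a stated angle about the axis through the vertex CA perpendicular
  to the three marker CAs; the construction guarantees the measured tilt
  equals the rotation. They validate the trimming/superposition/mapping
  machinery and the angle arithmetic, not the biological claim that a tilt
  metric summarizes a real ligand reorientation — real complexes reorient
  with out-of-plane and translational components the single angle only
  indicates.
- **Sphere clusters** — pseudo-atoms with explicit radii for the SASA
  closed forms; they have no covalent structure, so contact classification
  on them exercises only the vdW class.
- **Strands** — ideally repeating or uniformly twisted backbones; real
  strands twist unevenly and the per-step list, not the cumulative value,
  carries that structure.
- **Planar dot grids** — bypass the dot-surface generator to test the Sc
  scoring core against its closed form.
- **ITC curves** — exact isotherm heats plus Gaussian noise; real
  thermograms add baseline drift and integration error upstream of this
  model, which are out of scope (no raw power-trace processing).

Passing on these fixtures demonstrates the algorithms are implemented
correctly at the stated tolerances, not that any particular published
structural value is reproduced; comparisons against deposited structures
require those coordinate files as inputs and inherit their software-version
and parameter sensitivities (the areas, for instance, depend on the radius
set at the few-percent level).

## Problem sizes and tolerances

Acceptance-style checks run at the sizes the methods are designed for:
960-point SASA lattices (10,000-point self-convergence on docked clusters),
15 dots/Å² surfaces, 20-injection titrations with 20 noise seeds,
10,000-rotation Monte-Carlo bounds on N ≤ 8 point sets, and 40-residue
receptor fits. Tolerances: 1e-4 relative on noise-free ITC round trips;
5% / 2% / factor-3 on noisy ΔH / n / K_d; 0.1° on tilt recovery; 1% on SASA
closed forms; 1e-3 on planar Sc; 1e-6 Å-scale agreement between Kabsch and
the quaternion oracle.
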