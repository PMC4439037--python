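# ephcompare

Comparative structural and thermodynamic analysis of Eph receptor / ephrin
complexes, built as a reusable Python library with a thin command-line
wrapper.

Eph receptor tyrosine kinases bind their membrane-anchored ephrin ligands
through a ~200-residue ligand-binding domain (LBD); the same ephrin can sit
on different receptors in visibly different orientations, and that
orientation change reshapes the binding interface and correlates with
binding affinity. `ephcompare` implements the measurements used to compare
such complexes quantitatively:

- **Ligand tilt angle.** After trimming two complexes to their shared
  residues and superposing the query receptor onto a reference receptor
  (CA-only Kabsch fit), the angle at a receptor *vertex* residue between a
  *distal* receptor residue and an ephrin *marker* residue is measured on
  CA atoms, and the reference complex's angle is subtracted. The complex
  with the least tilted ligand defines 0 degrees.
- **Buried interface area** in the PISA convention: each chain's
  solvent-accessible surface area (SASA, Shrake–Rupley with a deterministic
  spiral lattice, 1.4 Å probe) is computed alone and in the complex, and the
  interface area is half the summed loss.
- **Classified contact table.** Inter-chain heavy-atom contacts are reported
  once each as van der Waals (≤ 4.0 Å), hydrogen bond (≤ 3.5 Å with a
  hydrogen-free ≥ 90° antecedent–donor–acceptor angle) or salt bridge
  (Asp/Glu carboxylate oxygen to Lys/Arg/His basic nitrogen ≤ 4.0 Å), with
  backbone/side-chain moiety tags and a GH-loop / non-GH-loop split.
- **Shape complementarity** (Lawrence–Colman Sc): buried surface dots are
  scored `S(x) = (n_x · −n_x') exp(−w d²)` against the nearest partner dot,
  and Sc is the mean of the two directional medians (1 = perfectly
  interlocking).
- **Strand twist**: cumulative rotation of carbonyl vectors along a
  β-strand, measured two residues apart so the β-pleat alternation cancels.
- **One-set-of-sites ITC**: simulation of the Wiseman isotherm with
  perfusion-cell dilution corrections, nonlinear least-squares recovery of
  (n, K_a, ΔH), and the thermodynamic linkage ΔG = −RT ln K_a,
  TΔS = ΔH − ΔG.

A first-class synthetic-data module generates inputs whose correct answer is
known by construction — complexes whose ligand has been rotated by a stated
angle, sphere clusters with closed-form accessible areas, uniformly twisted
strands, opposing planar dot grids, and noisy one-site titration curves — so
the whole pipeline is testable offline.

## Worked example

```sh
python examples/tilt_angle.py
```

```
raw angle        : 89.00 deg
reference angle  : 80.00 deg
tilt             : 9.00 deg
rounded (table)  : 9 deg
receptor CA pairs: 40
```

The script builds an untilted reference complex and a copy whose ligand was
rotated 9° about the axis through the vertex CA perpendicular to the plane
of the three marker CAs; the metric reads the rotation back exactly. The
receptor fit used all 40 scaffold residues.

```sh
python examples/itc_one_site_fit.py
```

```
n    =    0.998            (true 1.000)
K_d  =     9.27 nM         (true 9.00)
dH   =    -2150.5 cal/mol  (true -2145.0)
dG   =   -10959.1 cal/mol
TdS  =     8808.6 cal/mol
s.e. : n 0.001, dH 6.1
```

A tight exothermic binder (K_d = 9 nM, ΔH = −2,145 cal/mol) titrated on an
overfilled-cell schedule with 1% noise fits back to within a fraction of a
percent on n and ΔH; K_d is softer because at c ≈ 1,100 the transition is
nearly a step. The other examples (`interface_area.py`,
`shape_complementarity_demo.py`, `strand_twist_demo.py`) exercise the
remaining measurements the same way.

## Command line

`ephcompare` wraps the library for shell use: `info`, `superpose`, `tilt`,
`interface`, `sc`, `twist`, `itc-sim`, `itc-fit`, `make-fixture`, and
`table3` (a comparative tilt/interface-area report over a YAML-configured
list of complexes). Run `ephcompare --help` for details.

## Layout

- `src/ephcompare/` — the library (structure I/O, superposition, tilt
  metric, interface analysis, shape complementarity, strand geometry, ITC
  model, synthetic data, CLI)
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite with independent oracles (quaternion
  superposition, spherical-cap SASA, equilibrium-bisection ITC)
- `docs/methods.md` — models, conventions, parameter choices, limitations
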