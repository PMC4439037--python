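"""Synthetic fixtures with analytically known answers.

Every generator here produces an input whose correct measurement is known by
construction: two-chain complexes whose ligand has been rotated by a stated
angle about the tilt-defining axis, pseudo-atom sphere clusters with
closed-form accessible areas, ideally repeating or uniformly twisted strand
backbones, opposing planar dot grids whose Sc value is a closed form of the
separation, and one-site titration curves at stated (n, K_d, dH).

All randomness is drawn from one seeded generator per call; the same seed
gives byte-identical fixture files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ephcompare.structure_io import (
    Atom,
    Chain,
    Residue,
    Structure,
    load_structure,
    write_pdb,
)
from ephcompare.shape_complementarity import SurfaceDot
from ephcompare.itc_model import (
    InjectionHeats,
    ThermoParams,
    TitrationSchedule,
    simulate_titration,
    write_titration,
)

__all__ = [
    "make_tilted_complex",
    "make_sphere_cluster",
    "load_sphere_cluster",
    "make_strand",
    "make_plane_pair",
    "make_itc_curve",
]

# 20 standard residues to draw scaffold sequences from (no X)
_AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# local backbone offsets from CA (angstrom); rigid, shared by every residue
_N_OFF = np.array([-1.20, 0.80, 0.00])
_C_OFF = np.array([1.20, 0.70, 0.30])
_O_OFF = np.array([1.40, 1.90, 0.30])  # C->O roughly 1.23 A


def _scaffold_residue(chain_id: str, seq_num: int, res_name: str, ca: np.ndarray) -> Residue:
    return Residue(
        chain_id=chain_id,
        seq_num=seq_num,
        res_name=res_name,
        atoms=[
            Atom("N", "N", ca + _N_OFF),
            Atom("CA", "C", ca.copy()),
            Atom("C", "C", ca + _C_OFF),
            Atom("O", "O", ca + _O_OFF),
        ],
    )


def _helix_trace(n: int, origin: np.ndarray, radius: float = 4.0, rise: float = 1.6,
                 turn_deg: float = 100.0) -> np.ndarray:
    """Non-collinear rigid CA trace: points on a helix, (n,3)."""
    i = np.arange(n, dtype=float)
    ang = np.radians(turn_deg) * i
    return origin + np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * i]
    )


def _rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.radians(theta_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


RECEPTOR_FIRST, RECEPTOR_LAST = 145, 184  # contains vertex 152 and distal 180
LIGAND_FIRST, LIGAND_LAST = 100, 119  # contains marker 112


def make_tilted_complex(theta: float, seed: int = 0) -> Structure:
    """Two-chain complex whose measured tilt equals ``theta`` by construction.

    The receptor (chain R, residues 145-184) is a rigid helical CA/backbone
    scaffold containing the vertex (152) and distal (180) marker residues;
    the ligand (chain L, residues 100-119) contains marker residue 112.  The
    whole ligand is rotated by ``theta`` degrees about the axis through the
    vertex CA perpendicular to the plane of the three marker CAs, which
    changes the three-atom angle by exactly ``theta``.  The seed fixes the
    scaffold sequences (shared by all theta values, so complexes from the
    same seed align residue-for-residue).
    """
    if not 0.0 <= theta <= 60.0:
        raise ValueError(f"theta must be in [0, 60] degrees, got {theta}")
    rng = np.random.default_rng(seed)
    n_rec = RECEPTOR_LAST - RECEPTOR_FIRST + 1
    n_lig = LIGAND_LAST - LIGAND_FIRST + 1
    rec_seq = [_AA3[k] for k in rng.integers(0, 20, size=n_rec)]
    lig_seq = [_AA3[k] for k in rng.integers(0, 20, size=n_lig)]

    rec_ca = _helix_trace(n_rec, origin=np.zeros(3))
    receptor = Chain(
        "R",
        [
            _scaffold_residue("R", RECEPTOR_FIRST + i, rec_seq[i], rec_ca[i])
            for i in range(n_rec)
        ],
    )

    vertex = rec_ca[152 - RECEPTOR_FIRST]
    distal = rec_ca[180 - RECEPTOR_FIRST]

    # place the ligand so its marker CA sits ~12 A from the vertex at ~80 deg
    # to the distal arm, well inside [0, 180 - 60]
    vd = distal - vertex
    vd_hat = vd / np.linalg.norm(vd)
    # any unit vector not parallel to vd
    aux = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(aux, vd_hat)) > 0.9:
        aux = np.array([0.0, 1.0, 0.0])
    perp = np.cross(vd_hat, aux)
    perp /= np.linalg.norm(perp)
    ang0 = np.radians(80.0)
    marker0 = vertex + 12.0 * (np.cos(ang0) * vd_hat + np.sin(ang0) * perp)

    lig_ca = _helix_trace(n_lig, origin=marker0 - np.array([2.0, 2.0, -1.5]),
                          radius=3.0, rise=1.5, turn_deg=97.0)
    lig_ca[112 - LIGAND_FIRST] = marker0  # pin the marker residue
    ligand = Chain(
        "L",
        [
            _scaffold_residue("L", LIGAND_FIRST + i, lig_seq[i], lig_ca[i])
            for i in range(n_lig)
        ],
    )

    # rotation axis: through the vertex, normal to the (marker, vertex, distal)
    # plane, oriented so the angle at the vertex grows with theta
    normal = np.cross(vd_hat, marker0 - vertex)
    normal /= np.linalg.norm(normal)
    rot = _rotation_about_axis(normal, theta)
    for res in ligand.residues:
        for atom in res.atoms:
            atom.pos = vertex + rot @ (atom.pos - vertex)

    return Structure(f"synthetic-tilt-{theta:g}", [receptor, ligand])


def make_sphere_cluster(
    centers: Sequence[Sequence[float]],
    radii: Sequence[float],
    chain_id: str = "S",
) -> Structure:
    """Pseudo-atom cluster: one single-atom residue per sphere.

    Radii are carried as explicit per-atom overrides (and mirrored into the
    B-factor column so a written PDB round-trips through
    :func:`load_sphere_cluster`).
    """
    centers = np.asarray(centers, dtype=float)
    radii = list(map(float, radii))
    if len(centers) != len(radii):
        raise ValueError("centers and radii must have equal length")
    residues = [
        Residue(
            chain_id=chain_id,
            seq_num=i + 1,
            res_name="GLY",
            atoms=[Atom("CA", "C", centers[i], radius=radii[i], bfactor=radii[i])],
        )
        for i in range(len(radii))
    ]
    return Structure("synthetic-spheres", [Chain(chain_id, residues)])


def load_sphere_cluster(path: str | Path) -> Structure:
    """Re-read a sphere-cluster PDB, restoring radii from the B-factor column."""
    st = load_structure(path)
    for chain in st.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.radius = atom.bfactor
    return st


def make_strand(
    n_res: int = 8,
    twist_per_step_deg: float = 0.0,
    rise: float = 3.4,
    chain_id: str = "A",
    first_residue: int = 1,
) -> Chain:
    """Extended-strand backbone with a uniform, known carbonyl twist.

    With zero twist every residue is an exact translation of the previous
    one (cumulative twist 0).  Otherwise the carbonyl direction advances by
    ``twist_per_step_deg``/2 per residue around the strand axis, on top of
    the beta-pleat's 180-degree alternation, so each stride-2 twist step
    measures exactly ``twist_per_step_deg``.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    residues = []
    for i in range(n_res):
        ca = np.array([0.0, 0.0, i * rise])
        phi = np.radians(i * twist_per_step_deg / 2.0 + 180.0 * (i % 2))
        carbonyl = np.array([np.cos(phi), np.sin(phi), 0.0]) * 1.23
        c = ca + np.array([0.8, 0.0, 1.0])
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=first_residue + i,
                res_name="ALA",
                atoms=[
                    Atom("N", "N", ca + np.array([-0.8, 0.0, -1.0])),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", c + carbonyl),
                ],
            )
        )
    return Chain(chain_id, residues)


def make_plane_pair(
    separation: float,
    n_side: int = 12,
    spacing: float = 0.5,
) -> tuple[list[SurfaceDot], list[SurfaceDot]]:
    """Two opposing planar dot grids a stated distance apart.

    Grid A lies in z = 0 with normals +z; grid B in z = separation with
    normals -z, dots in registry, so every A dot's nearest partner is at
    exactly ``separation`` and the Sc statistic has the closed form
    exp(-w * separation^2).
    """
    xs = (np.arange(n_side) - (n_side - 1) / 2.0) * spacing
    up = np.array([0.0, 0.0, 1.0])
    dots_a, dots_b = [], []
    for x in xs:
        for y in xs:
            dots_a.append(SurfaceDot(np.array([x, y, 0.0]), up.copy()))
            dots_b.append(SurfaceDot(np.array([x, y, separation]), -up))
    return dots_a, dots_b


def make_itc_curve(
    params: ThermoParams,
    schedule: Optional[TitrationSchedule] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> InjectionHeats:
    """One-site titration fixture; optionally written as TSV + YAML schedule.

    Defaults mirror the overfilled-cell protocol (2 mL of 10 uM in the cell,
    100 uM in the syringe, one 5 uL then 19 x 15 uL injections, 25 C).
    """
    schedule = schedule or TitrationSchedule.vp_itc_default()
    heats = simulate_titration(params, schedule, noise_sd=noise_sd, seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_titration(heats, schedule, out_dir / "heats.tsv", out_dir / "schedule.yaml")
    return heats
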