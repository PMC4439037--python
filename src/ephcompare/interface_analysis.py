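"""Solvent-accessible surface area, buried interface area, and contacts.

SASA follows Shrake-Rupley with a deterministic spiral (generalized Fibonacci)
point lattice on each expanded sphere, so results are bit-reproducible with
no random seed.  Buried interface area uses the PISA convention: each chain's
SASA loss on complexation is computed, and the interface area is half their
sum.  Contacts between receptor and ligand heavy atoms are classified with
field-standard geometric cutoffs (vdW 4.0 A; hydrogen bond 3.5 A with a
hydrogen-free >= 90 deg antecedent angle; salt bridge 4.0 A between Asp/Glu
carboxylates and Lys/Arg/His basic nitrogens), each pair reported once with
the most specific class (salt > hbond > vdw).

Waters, non-polymer heteroatoms and hydrogens are excluded throughout.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ephcompare.structure_io import Atom, Chain, Residue, atom_radius

__all__ = [
    "SasaResult",
    "InterfaceReport",
    "ContactRecord",
    "ContactCutoffs",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "enumerate_contacts",
    "residue_contact_summary",
    "sphere_lattice",
]

PROBE_RADIUS = 1.4  # angstrom, water probe
DEFAULT_N_POINTS = 960
BSA_RESIDUE_THRESHOLD = 0.1  # angstrom^2

#: Hydrogen-bond donor heavy atoms by residue (side chain); backbone N is
#: always a donor.  Hydrogen-free criterion: distance + antecedent angle.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}
ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}


@dataclasses.dataclass
class ContactCutoffs:
    """Distance/angle criteria for contact classification (angstrom, degrees)."""

    vdw: float = 4.0
    hbond: float = 3.5
    salt: float = 4.0
    hbond_min_angle: float = 90.0


@dataclasses.dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (angstrom^2)."""

    per_atom: dict[int, float]  # id(atom) -> area
    total: float
    probe_radius: float
    n_points: int

    def area_of(self, atom: Atom) -> float:
        return self.per_atom.get(id(atom), 0.0)


@dataclasses.dataclass
class ContactRecord:
    """One classified inter-chain heavy-atom contact."""

    ligand_residue: Residue
    ligand_atom: str
    ligand_moiety: str  # "BB" | "SC"
    receptor_residue: Residue
    receptor_atom: str
    receptor_moiety: str
    distance: float
    contact_class: str  # "vdw" | "hbond" | "salt"


@dataclasses.dataclass
class InterfaceReport:
    """PISA-convention buried-area summary of a two-chain interface."""

    bsa_receptor: float
    bsa_ligand: float
    interface_area: float
    receptor_residues: list[Residue]
    ligand_residues: list[Residue]

    def __post_init__(self) -> None:
        expected = 0.5 * (self.bsa_receptor + self.bsa_ligand)
        if not np.isclose(self.interface_area, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("interface_area must be half the summed buried area")


class RadiusAssignmentError(KeyError):
    """An atom's element has no radius in the active radius set."""


def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (generalized spiral).

    Points are placed at uniformly spaced z-levels with azimuth advancing by
    the golden angle; quadrature error on sphere-area fractions falls roughly
    as 1/n.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _heavy_atoms(chains: Sequence[Chain]) -> list[Atom]:
    return [
        a
        for c in chains
        for r in c.polymer_residues()
        for a in r.atoms
        if not a.is_hydrogen
    ]


def shrake_rupley_sasa(
    atoms: Chain | Sequence[Chain] | Sequence[Atom],
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA over heavy atoms of the selection.

    Each atom's expanded sphere (vdW radius + probe) carries a deterministic
    spiral lattice of ``n_points`` test points; the accessible fraction is
    the share of points outside every neighbor's expanded sphere, scaled by
    the expanded-sphere area 4 pi (r + probe)^2.
    """
    atom_list = _as_atom_list(atoms)
    if not atom_list:
        return SasaResult({}, 0.0, probe, n_points)
    radii = np.array([atom_radius(a) for a in atom_list]) + probe
    centers = np.vstack([a.pos for a in atom_list])
    lattice = sphere_lattice(n_points)
    tree = cKDTree(centers)
    max_r = radii.max()

    per_atom: dict[int, float] = {}
    total = 0.0
    for i, atom in enumerate(atom_list):
        pts = centers[i] + radii[i] * lattice
        # neighbors whose expanded sphere could cover any test point
        neighbor_idx = [
            j for j in tree.query_ball_point(centers[i], radii[i] + max_r) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        area = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
        per_atom[id(atom)] = float(area)
        total += area
    return SasaResult(per_atom, float(total), probe, n_points)


def _as_atom_list(atoms) -> list[Atom]:
    if isinstance(atoms, Chain):
        return _heavy_atoms([atoms])
    atoms = list(atoms)
    if atoms and isinstance(atoms[0], Chain):
        return _heavy_atoms(atoms)
    return [a for a in atoms if isinstance(a, Atom) and not a.is_hydrogen]


def buried_interface_area(
    receptor: Chain,
    ligand: Chain,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    cutoffs: Optional[ContactCutoffs] = None,
) -> InterfaceReport:
    """Buried surface areas and PISA-convention interface area.

    bsa_X = SASA(X alone) - SASA of X's atoms in the complex context;
    interface_area = (bsa_receptor + bsa_ligand) / 2.  A residue enters the
    interface lists if it loses more than 0.1 A^2 of SASA or owns a contact.
    """
    if not receptor.residues or not ligand.residues:
        raise ValueError("both chains must be non-empty")
    sasa_rec = shrake_rupley_sasa(receptor, probe, n_points)
    sasa_lig = shrake_rupley_sasa(ligand, probe, n_points)
    sasa_cpx = shrake_rupley_sasa([receptor, ligand], probe, n_points)

    def _chain_loss(chain: Chain, alone: SasaResult) -> tuple[float, list[Residue]]:
        loss_total = 0.0
        residues = []
        for res in chain.polymer_residues():
            res_loss = sum(
                alone.area_of(a) - sasa_cpx.area_of(a)
                for a in res.atoms
                if not a.is_hydrogen
            )
            loss_total += res_loss
            if res_loss > BSA_RESIDUE_THRESHOLD:
                residues.append(res)
        return loss_total, residues

    bsa_rec, rec_residues = _chain_loss(receptor, sasa_rec)
    bsa_lig, lig_residues = _chain_loss(ligand, sasa_lig)
    # quadrature can make a tiny negative loss for distant chains; clamp
    bsa_rec, bsa_lig = max(bsa_rec, 0.0), max(bsa_lig, 0.0)

    contacts = enumerate_contacts(receptor, ligand, cutoffs)
    rec_ids = {r.id for r in rec_residues}
    lig_ids = {r.id for r in lig_residues}
    for rec in contacts:
        if rec.receptor_residue.id not in rec_ids:
            rec_residues.append(rec.receptor_residue)
            rec_ids.add(rec.receptor_residue.id)
        if rec.ligand_residue.id not in lig_ids:
            lig_residues.append(rec.ligand_residue)
            lig_ids.add(rec.ligand_residue.id)

    return InterfaceReport(
        bsa_receptor=float(bsa_rec),
        bsa_ligand=float(bsa_lig),
        interface_area=float(0.5 * (bsa_rec + bsa_lig)),
        receptor_residues=rec_residues,
        ligand_residues=lig_residues,
    )


def _moiety(atom_name: str) -> str:
    return "BB" if atom_name in ("N", "CA", "C", "O", "OXT") else "SC"


def _is_donor(res: Residue, atom: Atom) -> bool:
    if atom.name == "N":
        return True
    return atom.name in SIDECHAIN_DONORS.get(res.res_name.upper(), ())


def _is_acceptor(res: Residue, atom: Atom) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in SIDECHAIN_ACCEPTORS.get(res.res_name.upper(), ())


def _antecedent(res: Residue, donor: Atom) -> Optional[np.ndarray]:
    """Heavy atom covalently preceding the donor: nearest same-residue heavy atom."""
    best, best_d = None, np.inf
    for a in res.heavy_atoms():
        if a is donor:
            continue
        d = float(np.linalg.norm(a.pos - donor.pos))
        if d < best_d:
            best, best_d = a, d
    if best is None or best_d > 2.0:  # no plausible covalent neighbor
        return None
    return best.pos


def _hbond_geometry_ok(
    donor_res: Residue, donor: Atom, acceptor: Atom, min_angle: float
) -> bool:
    ante = _antecedent(donor_res, donor)
    if ante is None:
        return True  # isolated donor: distance criterion only
    u = donor.pos - ante
    v = acceptor.pos - donor.pos
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return False
    ang = np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1, 1)))
    # angle at the donor between antecedent->donor extension and acceptor
    return (180.0 - ang) >= min_angle


def _is_salt_pair(res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom) -> bool:
    def acidic(res, atom):
        return atom.name in ACIDIC_ATOMS.get(res.res_name.upper(), ())

    def basic(res, atom):
        return atom.name in BASIC_ATOMS.get(res.res_name.upper(), ())

    return (acidic(res_a, atom_a) and basic(res_b, atom_b)) or (
        basic(res_a, atom_a) and acidic(res_b, atom_b)
    )


def _is_hbond_pair(
    res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom, min_angle: float
) -> bool:
    if _is_donor(res_a, atom_a) and _is_acceptor(res_b, atom_b):
        if _hbond_geometry_ok(res_a, atom_a, atom_b, min_angle):
            return True
    if _is_donor(res_b, atom_b) and _is_acceptor(res_a, atom_a):
        if _hbond_geometry_ok(res_b, atom_b, atom_a, min_angle):
            return True
    return False


def enumerate_contacts(
    receptor: Chain, ligand: Chain, cutoffs: Optional[ContactCutoffs] = None
) -> list[ContactRecord]:
    """All classified receptor/ligand heavy-atom contacts.

    Every inter-chain heavy-atom pair within the vdW cutoff is a candidate;
    pairs meeting the salt-bridge criterion are reported as salt, otherwise
    hydrogen-bond geometry is tested, otherwise the pair is vdW.
    """
    cutoffs = cutoffs or ContactCutoffs()
    rec_atoms = [
        (res, a) for res in receptor.polymer_residues() for a in res.heavy_atoms()
    ]
    lig_atoms = [
        (res, a) for res in ligand.polymer_residues() for a in res.heavy_atoms()
    ]
    if not rec_atoms or not lig_atoms:
        return []
    rec_xyz = np.vstack([a.pos for _, a in rec_atoms])
    lig_xyz = np.vstack([a.pos for _, a in lig_atoms])
    max_cut = max(cutoffs.vdw, cutoffs.hbond, cutoffs.salt)
    pairs = cKDTree(lig_xyz).query_ball_tree(cKDTree(rec_xyz), max_cut)

    records: list[ContactRecord] = []
    for li, rec_indices in enumerate(pairs):
        lig_res, lig_atom = lig_atoms[li]
        for ri in rec_indices:
            rec_res, rec_atom = rec_atoms[ri]
            d = float(np.linalg.norm(lig_xyz[li] - rec_xyz[ri]))
            if d <= cutoffs.salt and _is_salt_pair(lig_res, lig_atom, rec_res, rec_atom):
                cls = "salt"
            elif d <= cutoffs.hbond and _is_hbond_pair(
                lig_res, lig_atom, rec_res, rec_atom, cutoffs.hbond_min_angle
            ):
                cls = "hbond"
            elif d <= cutoffs.vdw:
                cls = "vdw"
            else:
                continue
            records.append(
                ContactRecord(
                    ligand_residue=lig_res,
                    ligand_atom=lig_atom.name,
                    ligand_moiety=_moiety(lig_atom.name),
                    receptor_residue=rec_res,
                    receptor_atom=rec_atom.name,
                    receptor_moiety=_moiety(rec_atom.name),
                    distance=d,
                    contact_class=cls,
                )
            )
    records.sort(
        key=lambda r: (
            r.ligand_residue.seq_num,
            r.ligand_atom,
            r.receptor_residue.seq_num,
            r.receptor_atom,
        )
    )
    return records


GH_LOOP_RANGE = (121, 129)  # ephrin-A5 GH loop, author numbering

CLASS_MARK = {"vdw": "", "hbond": "*", "salt": "**"}


def residue_contact_summary(
    contacts: Iterable[ContactRecord],
    gh_loop_range: tuple[int, int] = GH_LOOP_RANGE,
) -> pd.DataFrame:
    """Per-ligand-residue contact table in the comparative-table layout.

    One row per (ligand residue, moiety); partner receptor residues are
    listed with moiety tags and class markers (* hydrogen bond, ** salt
    bridge), and rows are split into GH-loop and non-GH-loop blocks
    (GH loop = ephrin residues 121-129 by default).
    """
    rows = []
    grouped: dict[tuple, list[ContactRecord]] = {}
    for rec in contacts:
        key = (rec.ligand_residue.id, rec.ligand_moiety)
        grouped.setdefault(key, []).append(rec)
    for (lig_id, moiety), recs in sorted(grouped.items(), key=lambda kv: (kv[0][0][1], kv[0][1])):
        first = recs[0]
        lig_res = first.ligand_residue
        partners = []
        seen = set()
        for r in sorted(recs, key=lambda r: (r.receptor_residue.seq_num, r.receptor_moiety)):
            tag = (
                f"{r.receptor_residue.one_letter}{r.receptor_residue.seq_num}"
                f"^{r.receptor_moiety}{CLASS_MARK[r.contact_class]}"
            )
            key2 = (r.receptor_residue.id, r.receptor_moiety, r.contact_class)
            if key2 not in seen:
                partners.append(tag)
                seen.add(key2)
        rows.append(
            {
                "ligand_residue": f"{lig_res.one_letter}{lig_res.seq_num}",
                "ligand_moiety": moiety,
                "in_gh_loop": gh_loop_range[0] <= lig_res.seq_num <= gh_loop_range[1],
                "receptor_partners": ", ".join(partners),
                "n_contacts": len(recs),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "ligand_residue",
            "ligand_moiety",
            "in_gh_loop",
            "receptor_partners",
            "n_contacts",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["in_gh_loop", "ligand_residue"], kind="stable"
        ).reset_index(drop=True)
    return df
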