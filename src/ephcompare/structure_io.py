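"""Coordinate model and PDB/mmCIF input/output.

A deliberately small hierarchical model (Structure > Chain > Residue > Atom)
holds a single coordinate model in angstroms, with author residue numbering
as the authoritative addressing scheme.  Parsing and writing of the standard
formats is delegated to gemmi; altloc resolution (highest occupancy, ties to
'A') and first-model selection happen on conversion, so every downstream
measurement sees exactly one position per atom.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ComplexSpec",
    "StructureParseError",
    "SelectionError",
    "load_structure",
    "write_pdb",
    "extract_complex",
    "VDW_RADII",
    "atom_radius",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or contains no polymer."""


class SelectionError(KeyError):
    """Raised when a chain/residue selection matches nothing."""


#: NACCESS-style heavy-atom van der Waals radii (angstrom), keyed by element.
#: PISA-comparable buried-area magnitudes depend on this choice.
VDW_RADII = {
    "C": 1.70,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "H": 1.00,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Standard amino-acid three-letter -> one-letter mapping (X for anything else).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclasses.dataclass
class Atom:
    """One atom: name, element, position (angstrom), occupancy, altloc, B."""

    name: str
    element: str
    pos: np.ndarray  # shape (3,), angstrom
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    radius: Optional[float] = None  # explicit override for pseudo-atoms

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclasses.dataclass
class Residue:
    """A residue addressed by author numbering (chain, seq_num, icode)."""

    chain_id: str
    seq_num: int
    res_name: str
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    icode: str = ""
    is_hetero: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ValueError(
                    f"residue {self.res_name}{self.seq_num}: duplicate atom {key}"
                )
            seen.add(key)

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name.upper(), "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclasses.dataclass
class Chain:
    """An ordered run of residues sharing a chain identifier."""

    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_num: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not (r.is_water or r.is_hetero)]

    def subset(self, first: Optional[int] = None, last: Optional[int] = None) -> "Chain":
        """Deep copy of the residues with first <= seq_num <= last."""
        kept = [
            copy_residue(r)
            for r in self.residues
            if (first is None or r.seq_num >= first)
            and (last is None or r.seq_num <= last)
        ]
        return Chain(self.chain_id, kept)

    def coords(self, atom_name: Optional[str] = None) -> np.ndarray:
        """(N,3) array of atom positions, optionally restricted to one atom name."""
        pts = [
            a.pos
            for r in self.residues
            for a in r.atoms
            if atom_name is None or a.name == atom_name
        ]
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)


@dataclasses.dataclass
class Structure:
    """One coordinate model: an id plus an ordered list of chains."""

    id: str
    chains: list[Chain] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"structure {self.id}: duplicate chain ids {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise SelectionError(f"structure {self.id}: no chain {chain_id!r}")

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclasses.dataclass
class ComplexSpec:
    """Names the receptor and ligand selections of a two-body complex.

    Each selection is (chain_id, (first_seq, last_seq)); the range may be
    (None, None) for the whole chain.
    """

    receptor_chain: str
    ligand_chain: str
    receptor_range: tuple[Optional[int], Optional[int]] = (None, None)
    ligand_range: tuple[Optional[int], Optional[int]] = (None, None)

    def __post_init__(self) -> None:
        if self.receptor_chain == self.ligand_chain:
            r1, r2 = self.receptor_range, self.ligand_range
            if None in r1 or None in r2 or not (r1[1] < r2[0] or r2[1] < r1[0]):
                raise ValueError("receptor and ligand selections must be disjoint")


def copy_residue(r: Residue) -> Residue:
    return Residue(
        chain_id=r.chain_id,
        seq_num=r.seq_num,
        res_name=r.res_name,
        atoms=[dataclasses.replace(a, pos=a.pos.copy()) for a in r.atoms],
        icode=r.icode,
        is_hetero=r.is_hetero,
        is_water=r.is_water,
    )


def atom_radius(atom: Atom) -> float:
    """vdW radius: explicit override first, then the element table."""
    if atom.radius is not None:
        return atom.radius
    return VDW_RADII.get(atom.element.upper(), DEFAULT_RADIUS)


# ---------------------------------------------------------------------------
# Reading


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward altloc 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        # sort: highest occupancy first; within a tie 'A' (then alphabetic) wins
        best = sorted(group, key=lambda a: (-a.occupancy, a.altloc or "~"))[0]
        kept.append(dataclasses.replace(best, altloc=""))
    return kept


def _from_gemmi(gst: gemmi.Structure, structure_id: str) -> Structure:
    gst.setup_entities()
    if len(gst) == 0:
        raise StructureParseError(f"{structure_id}: no models in file")
    model = gst[0]  # first model only
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name or "C",
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc.strip() if ga.altloc else "",
                    bfactor=ga.b_iso,
                )
                for ga in gres
            ]
            is_water = gres.name in WATER_NAMES or gres.is_water()
            is_hetero = (gres.het_flag == "H" and not is_water) or (
                gres.name.upper() not in THREE_TO_ONE and not is_water
            )
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_num=gres.seqid.num,
                    res_name=gres.name,
                    atoms=_resolve_altlocs(atoms),
                    icode=(gres.seqid.icode or " ").strip(),
                    is_hetero=is_hetero,
                    is_water=is_water,
                )
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    st = Structure(structure_id, chains)
    n_polymer = sum(len(c.polymer_residues()) for c in st.chains)
    if n_polymer == 0:
        raise StructureParseError(f"{structure_id}: file contains no polymer residues")
    return st


def load_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Parameters
    ----------
    path : file path
    format : {"pdb", "mmcif", "auto"}
        "auto" dispatches on the extension (.cif/.mmcif -> mmCIF, else PDB).

    Only the first model is kept; for alternate locations the highest-occupancy
    conformer is retained (ties resolved toward altloc 'A').  Waters and
    non-polymer heteroatoms are kept but flagged, and excluded from geometry
    downstream.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "mmcif":
            doc = gemmi.cif.read(str(path))
            gst = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc
    structure_id = gst.name.strip() or path.stem
    return _from_gemmi(gst, structure_id)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            gres.het_flag = "H" if (res.is_hetero or res.is_water) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    return gst


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (single model)."""
    gst = _to_gemmi(structure)
    gst.setup_entities()
    gst.write_pdb(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Write the structure as an mmCIF (PDBx) file."""
    gst = _to_gemmi(structure)
    gst.setup_entities()
    doc = gst.make_mmcif_document()
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# Selection


def extract_complex(structure: Structure, spec: ComplexSpec) -> tuple[Chain, Chain]:
    """Return deep, independent (receptor, ligand) chain selections.

    Residues outside the requested ranges are dropped; waters and hetero
    residues are excluded from both selections.
    """
    rec_src = structure.chain(spec.receptor_chain)
    lig_src = structure.chain(spec.ligand_chain)
    receptor = _select(rec_src, spec.receptor_range)
    ligand = _select(lig_src, spec.ligand_range)
    if not receptor.residues:
        raise SelectionError(
            f"receptor selection {spec.receptor_chain}{spec.receptor_range} is empty"
        )
    if not ligand.residues:
        raise SelectionError(
            f"ligand selection {spec.ligand_chain}{spec.ligand_range} is empty"
        )
    return receptor, ligand


def _select(chain: Chain, rng: tuple[Optional[int], Optional[int]]) -> Chain:
    sub = chain.subset(rng[0], rng[1])
    sub.residues = [r for r in sub.residues if not (r.is_water or r.is_hetero)]
    return sub
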