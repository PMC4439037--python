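"""Three-atom ephrin tilt angle, measured against a 0-degree reference complex.

The metric reduces how an ephrin ligand sits on its Eph receptor to a single
angle: after trimming both complexes to their shared residues and superposing
the query receptor onto the reference receptor, the angle at a receptor
vertex residue (EphA3 F152 by convention) between a distal receptor residue
(Y180) and an ephrin interface residue (ephrin-A5 L112, or the aligned
equivalent) is measured, and the same angle in the reference complex is
subtracted.  The complex with the least tilted ligand (EphA2/ephrin-A5)
defines the 0-degree reference.

The angle is taken on CA atoms, so the measure is side-chain independent,
and the tilt is reported signed (raw minus reference); its magnitude rounded
to whole degrees matches the convention of comparative tilt tables.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ephcompare.structure_io import Chain, Residue
from ephcompare.superposition import align_residues, superpose_on_receptor

__all__ = [
    "TiltSpec",
    "TiltResult",
    "DegenerateGeometryError",
    "ResidueMappingError",
    "three_atom_angle",
    "measure_tilt",
]


class DegenerateGeometryError(ValueError):
    """An angle arm has zero length."""


class ResidueMappingError(KeyError):
    """A spec residue cannot be mapped into the query complex."""


@dataclasses.dataclass
class TiltSpec:
    """Which three residues (and which atom) define the tilt angle.

    Defaults are the EphA3/ephrin-A5 convention: vertex F152 and distal Y180
    on the receptor, L112 on the ephrin, CA atoms, with the EphA2/ephrin-A5
    complex (3MX0) as the 0-degree reference.
    """

    vertex_residue: int = 152
    distal_residue: int = 180
    ligand_residue: int = 112
    atom_name: str = "CA"
    reference_complex: str = "3MX0"

    def __post_init__(self) -> None:
        ids = {self.vertex_residue, self.distal_residue}
        if len(ids) != 2:
            raise ValueError("vertex and distal residues must be distinct")


@dataclasses.dataclass
class TiltResult:
    """Raw and reference angles (degrees) and their signed difference."""

    raw_angle: float
    reference_angle: float
    tilt: float
    pairs_used: int
    convention: str = "CA three-atom angle, signed raw-minus-reference"

    def __post_init__(self) -> None:
        if not np.isclose(self.tilt, self.raw_angle - self.reference_angle, atol=1e-9):
            raise ValueError("tilt must equal raw_angle - reference_angle")

    @property
    def tilt_magnitude_deg(self) -> int:
        """|tilt| rounded to whole degrees, the comparative-table convention."""
        return int(round(abs(self.tilt)))


def three_atom_angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Standard three-atom angle a-vertex-c in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    vertex = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u, v = a - vertex, c - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("angle arm has zero length")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _spec_atom(res: Residue, atom_name: str) -> np.ndarray:
    atom = res.atom(atom_name)
    if atom is None:
        raise ResidueMappingError(
            f"residue {res.res_name}{res.seq_num} has no atom {atom_name!r}"
        )
    return atom.pos


def _lookup(chain: Chain, seq_num: int, icode: str = "") -> Residue:
    res = chain.residue(seq_num, icode)
    if res is None:
        raise ResidueMappingError(f"chain {chain.chain_id} has no residue {seq_num}{icode}")
    return res


def _trim_to_correspondence(a: Chain, b: Chain) -> tuple[Chain, Chain]:
    """Restrict both chains to their mutually aligned residues (deep copies)."""
    cmap = align_residues(a, b)
    keep_a = {ra.id for ra, _ in cmap.pairs}
    keep_b = {rb.id for _, rb in cmap.pairs}
    ta = Chain(a.chain_id, [r for r in a.subset().residues if r.id in keep_a])
    tb = Chain(b.chain_id, [r for r in b.subset().residues if r.id in keep_b])
    return ta, tb


def _reference_raw_angle(reference: tuple[Chain, Chain], spec: TiltSpec) -> float:
    ref_rec, ref_lig = reference
    return three_atom_angle(
        _spec_atom(_lookup(ref_lig, spec.ligand_residue), spec.atom_name),
        _spec_atom(_lookup(ref_rec, spec.vertex_residue), spec.atom_name),
        _spec_atom(_lookup(ref_rec, spec.distal_residue), spec.atom_name),
    )


def measure_tilt(
    complex_: tuple[Chain, Chain],
    reference: tuple[Chain, Chain],
    spec: Optional[TiltSpec] = None,
) -> TiltResult:
    """Tilt of a query complex's ligand relative to the reference complex.

    Procedure: (1) trim both receptors and both ligands to mutually aligned
    residues; (2) superpose the query receptor onto the reference receptor
    and carry the whole query complex along; (3) map the spec residues,
    which are named in the reference complex's numbering, through the
    alignments into the query; (4) measure the three-atom angle on the
    query's own mapped atoms; (5) subtract the reference complex's angle.

    The spec residues live on the reference complex; for the query, the
    aligned equivalents are used, so homologs with different numbering are
    handled transparently.
    """
    spec = spec or TiltSpec()
    qry_rec, qry_lig = complex_
    ref_rec, ref_lig = reference

    # trim to the shared residue inventory before fitting
    ref_rec_t, qry_rec_t = _trim_to_correspondence(ref_rec, qry_rec)
    ref_lig_t, qry_lig_t = _trim_to_correspondence(ref_lig, qry_lig)

    (sup_rec, sup_lig), _, rec_map = superpose_on_receptor(
        (qry_rec_t, qry_lig_t), (ref_rec_t, ref_lig_t)
    )

    # map the reference-numbered spec residues into the query complex
    try:
        qry_vertex = rec_map.map_residue(spec.vertex_residue)
        qry_distal = rec_map.map_residue(spec.distal_residue)
    except KeyError as exc:
        raise ResidueMappingError(str(exc)) from exc
    lig_map = align_residues(ref_lig_t, qry_lig_t)
    try:
        qry_ligres = lig_map.map_residue(spec.ligand_residue)
    except KeyError as exc:
        raise ResidueMappingError(str(exc)) from exc

    # re-address the mapped residues in the *transformed* copies
    raw = three_atom_angle(
        _spec_atom(_lookup(sup_lig, qry_ligres.seq_num, qry_ligres.icode), spec.atom_name),
        _spec_atom(_lookup(sup_rec, qry_vertex.seq_num, qry_vertex.icode), spec.atom_name),
        _spec_atom(_lookup(sup_rec, qry_distal.seq_num, qry_distal.icode), spec.atom_name),
    )
    ref_raw = _reference_raw_angle((ref_rec_t, ref_lig_t), spec)
    return TiltResult(
        raw_angle=raw,
        reference_angle=ref_raw,
        tilt=raw - ref_raw,
        pairs_used=len(rec_map),
    )
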