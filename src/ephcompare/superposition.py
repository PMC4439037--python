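"""Residue correspondence and least-squares rigid superposition.

Correspondences between homologous chains come from a global pairwise
alignment of one-letter sequences (match +1, mismatch 0, gap open -1,
extend -0.5); only aligned positions with a CA atom on both sides enter the
map.  Superposition is the closed-form Kabsch solution on paired CA
coordinates, with the reflection corrected so a proper rotation is always
returned.  Fitting the receptor only and applying the transform to the whole
complex is what isolates the ligand's orientation for the tilt metric.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from Bio import Align

from ephcompare.structure_io import Chain, Residue, copy_residue

__all__ = [
    "CorrespondenceMap",
    "RigidTransform",
    "AlignmentTooSparseError",
    "DegenerateInputError",
    "align_residues",
    "kabsch",
    "superpose_on_receptor",
]

MIN_PAIRS = 10


class AlignmentTooSparseError(ValueError):
    """Fewer than the minimum number of aligned CA pairs were found."""


class DegenerateInputError(ValueError):
    """Point sets too small or rank-deficient for a unique rotation."""


@dataclasses.dataclass
class CorrespondenceMap:
    """Ordered residue pairs (a_i, b_i), strictly increasing in both chains."""

    pairs: list[tuple[Residue, Residue]]

    def __len__(self) -> int:
        return len(self.pairs)

    def ca_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Paired (N,3) CA coordinate arrays for chains A and B."""
        pa = np.array([a.ca.pos for a, _ in self.pairs])
        pb = np.array([b.ca.pos for _, b in self.pairs])
        return pa, pb

    def map_residue(self, seq_num: int, icode: str = "") -> Residue:
        """Residue of chain B paired with the chain-A residue (seq_num, icode)."""
        for a, b in self.pairs:
            if a.seq_num == seq_num and a.icode == icode:
                return b
        raise KeyError(f"residue {seq_num}{icode} has no aligned partner")


@dataclasses.dataclass
class RigidTransform:
    """x -> rotation @ x + translation, rotation proper orthonormal."""

    rotation: np.ndarray  # (3,3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def apply_to_chain(self, chain: Chain) -> Chain:
        """Deep copy of the chain with all atom positions transformed."""
        out = Chain(chain.chain_id, [copy_residue(r) for r in chain.residues])
        for res in out.residues:
            for atom in res.atoms:
                atom.pos = self.rotation @ atom.pos + self.translation
        return out

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _ca_residues(chain: Chain) -> list[Residue]:
    return [r for r in chain.polymer_residues() if r.ca is not None]


def align_residues(a: Chain, b: Chain) -> CorrespondenceMap:
    """Correspondence map between two homologous chains.

    Globally aligns the one-letter sequences of CA-bearing polymer residues
    and keeps every aligned (non-gap) column.  Raises
    :class:`AlignmentTooSparseError` if fewer than 10 pairs result.
    """
    res_a, res_b = _ca_residues(a), _ca_residues(b)
    if len(res_a) < MIN_PAIRS or len(res_b) < MIN_PAIRS:
        raise AlignmentTooSparseError(
            f"chains have {len(res_a)} and {len(res_b)} CA residues; need >= {MIN_PAIRS}"
        )
    seq_a = "".join(r.one_letter for r in res_a)
    seq_b = "".join(r.one_letter for r in res_b)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]

    pairs: list[tuple[Residue, Residue]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((res_a[i], res_b[j]))
    if len(pairs) < MIN_PAIRS:
        raise AlignmentTooSparseError(
            f"only {len(pairs)} aligned CA pairs (need >= {MIN_PAIRS})"
        )
    return CorrespondenceMap(pairs)


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of q onto p (Kabsch, SVD form).

    Returns the transform T minimizing RMSD(p, T(q)) and that minimum RMSD.
    A reflection in the SVD solution is corrected by flipping the sign of the
    smallest singular vector, so the rotation is always proper.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise DegenerateInputError(f"need matching (N,3) arrays, got {p.shape}, {q.shape}")
    n = p.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = q0.T @ p0  # cross-covariance
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise DegenerateInputError("points are collinear; rotation not unique")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = pc - rot @ qc
    transform = RigidTransform(rot, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(q) - p) ** 2, axis=1))))
    return transform, rmsd


def superpose_on_receptor(
    moving: tuple[Chain, Chain], reference: tuple[Chain, Chain]
) -> tuple[tuple[Chain, Chain], float, CorrespondenceMap]:
    """Superpose a (receptor, ligand) complex onto a reference complex.

    The fit uses corresponding receptor CA atoms only; the resulting transform
    is applied to every atom of the moving complex, receptor and ligand alike.

    Returns ((receptor', ligand'), receptor_rmsd, receptor_correspondence)
    where the correspondence maps reference receptor residues to the moving
    receptor's residues.
    """
    mov_rec, mov_lig = moving
    ref_rec, _ = reference
    cmap = align_residues(ref_rec, mov_rec)
    ref_xyz, mov_xyz = cmap.ca_coords()
    transform, rmsd = kabsch(ref_xyz, mov_xyz)
    return (
        (transform.apply_to_chain(mov_rec), transform.apply_to_chain(mov_lig)),
        rmsd,
        cmap,
    )
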