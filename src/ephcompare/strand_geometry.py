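"""Cumulative twist along a beta-strand from carbonyl-vector rotation.

A beta-strand's pleat makes adjacent carbonyls alternate direction, so twist
is measured between residues two apart: for each residue i with i+2 in
range, the carbonyl vectors C(i)->O(i) and C(i+2)->O(i+2) are projected onto
the plane perpendicular to the local strand axis CA(i)->CA(i+2), and the
signed angle between the projections (sign from the axis-aligned cross
product) is one twist step.  Steps advance two residues at a time
((1,3), (3,5), ...), so an 8-residue strand contributes three steps.  The
cumulative twist is the sum of absolute step angles.  The convention is
stamped into every report because twist numbers are not comparable across
conventions.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ephcompare.structure_io import Chain, Residue

__all__ = ["TwistReport", "strand_twist"]

CONVENTION = (
    "carbonyl C->O projection onto plane normal to CA(i)->CA(i+2); "
    "signed per-step (i, i+2); cumulative = sum of |steps|"
)


@dataclasses.dataclass
class TwistReport:
    """Signed per-step twists (degrees) and their absolute cumulative sum."""

    per_step: list[Optional[float]]  # None where backbone atoms were missing
    cumulative: float
    residues: tuple[int, int]
    skipped_steps: list[int]
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        defined = [s for s in self.per_step if s is not None]
        if defined and self.cumulative + 1e-9 < max(abs(s) for s in defined):
            raise ValueError("cumulative twist below the largest single step")


def _signed_angle(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from u to v about axis, degrees in (-180, 180]."""
    cross = np.cross(u, v)
    ang = np.degrees(np.arctan2(np.dot(cross, axis), np.dot(u, v)))
    return float(ang)


def strand_twist(chain: Chain, first_residue: int, last_residue: int) -> TwistReport:
    """Cumulative twist of the strand ``first_residue``..``last_residue``.

    Requires at least 4 residues in range; steps whose residues lack any of
    CA, C, O are skipped and recorded in ``skipped_steps``.
    """
    residues = [
        r
        for r in chain.polymer_residues()
        if first_residue <= r.seq_num <= last_residue
    ]
    residues.sort(key=lambda r: (r.seq_num, r.icode))
    if len(residues) < 4:
        raise ValueError(
            f"strand {first_residue}-{last_residue} spans {len(residues)} residues; need >= 4"
        )

    per_step: list[Optional[float]] = []
    skipped: list[int] = []
    for i in range(0, len(residues) - 2, 2):
        r0, r2 = residues[i], residues[i + 2]
        atoms = [r0.atom("CA"), r0.atom("C"), r0.atom("O"),
                 r2.atom("CA"), r2.atom("C"), r2.atom("O")]
        if any(a is None for a in atoms):
            per_step.append(None)
            skipped.append(r0.seq_num)
            continue
        ca0, c0, o0, ca2, c2, o2 = (a.pos for a in atoms)
        axis = ca2 - ca0
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            per_step.append(None)
            skipped.append(r0.seq_num)
            continue
        axis = axis / norm
        u = (o0 - c0) - np.dot(o0 - c0, axis) * axis
        v = (o2 - c2) - np.dot(o2 - c2, axis) * axis
        if np.linalg.norm(u) < 1e-9 or np.linalg.norm(v) < 1e-9:
            per_step.append(None)
            skipped.append(r0.seq_num)
            continue
        per_step.append(_signed_angle(u, v, axis))

    cumulative = float(sum(abs(s) for s in per_step if s is not None))
    return TwistReport(
        per_step=per_step,
        cumulative=cumulative,
        residues=(first_residue, last_residue),
        skipped_steps=skipped,
    )
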