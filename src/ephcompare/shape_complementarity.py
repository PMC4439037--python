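"""Lawrence-Colman shape complementarity (Sc) of a two-body interface.

Each body's surface is represented by dots with outward unit normals.  For a
buried dot x on surface A with nearest partner dot x' on B, the local score is

    S(x) = (n_x . -n_x') * exp(-w * d(x, x')^2)

with w = 0.5 A^-2 by default.  Sc is the mean of the two directional medians
(A against B and B against A); 1 means perfectly interlocking surfaces, 0 no
correlation, negative values clashes of like-facing surfaces.

Dots are generated on each atom's probe-expanded sphere with a deterministic
spiral lattice, filtered to the solvent-accessible subset, and repositioned
onto the van der Waals sphere — a dot-surface approximation of the molecular
surface that converges with dot density.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ephcompare.structure_io import Atom, Chain, atom_radius
from ephcompare.interface_analysis import PROBE_RADIUS, sphere_lattice, _as_atom_list

__all__ = [
    "SurfaceDot",
    "ScReport",
    "NoInterfaceError",
    "dot_surface",
    "sc_statistic",
]

DEFAULT_DENSITY = 15.0  # dots per angstrom^2
DEFAULT_W = 0.5  # angstrom^-2, distance-decay weight
DEFAULT_BAND = 1.5  # angstrom, interface (buried-dot) band
DEFAULT_PERIPHERY = 1.5  # angstrom, peripheral-band trim width


class NoInterfaceError(ValueError):
    """No buried dots: the two surfaces are not in contact within the band."""


@dataclasses.dataclass
class SurfaceDot:
    """A surface sample point with its outward unit normal."""

    pos: np.ndarray
    normal: np.ndarray
    owner_atom: Optional[Atom] = None
    buried: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"normal must be unit length, |n| = {n}")


@dataclasses.dataclass
class ScReport:
    """Sc statistic with its two directional medians and bookkeeping."""

    sc: float
    s_ab_median: float
    s_ba_median: float
    n_dots_a: int
    n_dots_b: int
    w: float

    def __post_init__(self) -> None:
        if not np.isclose(self.sc, 0.5 * (self.s_ab_median + self.s_ba_median), atol=1e-9):
            raise ValueError("sc must be the mean of the two directional medians")
        if not -1.0 - 1e-9 <= self.sc <= 1.0 + 1e-9:
            raise ValueError(f"sc {self.sc} outside [-1, 1]")


def dot_surface(
    atoms: Chain | Sequence[Chain] | Sequence[Atom],
    density: float = DEFAULT_DENSITY,
    probe: float = PROBE_RADIUS,
) -> list[SurfaceDot]:
    """Dot surface of a selection: accessible dots repositioned to the vdW sphere.

    ``density`` is dots per A^2 of probe-expanded sphere area, so the number
    of dots returned tracks density x SASA of the selection.
    """
    atom_list = _as_atom_list(atoms)
    if not atom_list:
        return []
    radii = np.array([atom_radius(a) for a in atom_list])
    expanded = radii + probe
    centers = np.vstack([a.pos for a in atom_list])
    tree = cKDTree(centers)
    max_r = expanded.max()

    dots: list[SurfaceDot] = []
    for i, atom in enumerate(atom_list):
        n_pts = max(1, int(round(density * 4.0 * np.pi * expanded[i] ** 2)))
        lattice = sphere_lattice(n_pts)
        pts = centers[i] + expanded[i] * lattice
        neighbor_idx = [
            j for j in tree.query_ball_point(centers[i], expanded[i] + max_r) if j != i
        ]
        accessible = np.ones(n_pts, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        for k in np.nonzero(accessible)[0]:
            normal = lattice[k]
            dots.append(
                SurfaceDot(
                    pos=centers[i] + radii[i] * normal,
                    normal=normal.copy(),
                    owner_atom=atom,
                )
            )
    return dots


def _dot_arrays(dots: Sequence[SurfaceDot]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.vstack([d.pos for d in dots]),
        np.vstack([d.normal for d in dots]),
    )


def _directional_scores(
    pos_a: np.ndarray,
    nrm_a: np.ndarray,
    pos_b: np.ndarray,
    nrm_b: np.ndarray,
    w: float,
    band: float,
    trim_periphery: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dot S values for A's buried dots against B; also the buried mask."""
    tree_b = cKDTree(pos_b)
    dist, idx = tree_b.query(pos_a)
    buried = dist < band
    if trim_periphery > 0 and buried.any() and (~buried).any():
        # drop buried dots near the buried-region boundary (peripheral band)
        boundary_tree = cKDTree(pos_a[~buried])
        d_boundary, _ = boundary_tree.query(pos_a[buried])
        keep = d_boundary > trim_periphery
        full = np.zeros_like(buried)
        full[np.nonzero(buried)[0][keep]] = True
        buried = full
    scores = np.array([])
    if buried.any():
        dots_n = nrm_a[buried]
        partner_n = nrm_b[idx[buried]]
        s = np.sum(dots_n * (-partner_n), axis=1) * np.exp(-w * dist[buried] ** 2)
        scores = s
    return scores, buried


def sc_statistic(
    receptor_dots: Sequence[SurfaceDot],
    ligand_dots: Sequence[SurfaceDot],
    w: float = DEFAULT_W,
    band: float = DEFAULT_BAND,
    trim_periphery: float = DEFAULT_PERIPHERY,
) -> ScReport:
    """Sc statistic over two dot surfaces.

    Buried dots are those within ``band`` of the partner surface; dots within
    ``trim_periphery`` of the buried-region boundary are dropped (set 0 to
    disable).  Raises :class:`NoInterfaceError` if either direction has no
    buried dots.
    """
    if not receptor_dots or not ligand_dots:
        raise NoInterfaceError("empty dot surface")
    pos_a, nrm_a = _dot_arrays(receptor_dots)
    pos_b, nrm_b = _dot_arrays(ligand_dots)

    s_ab, buried_a = _directional_scores(pos_a, nrm_a, pos_b, nrm_b, w, band, trim_periphery)
    s_ba, buried_b = _directional_scores(pos_b, nrm_b, pos_a, nrm_a, w, band, trim_periphery)
    if s_ab.size == 0 or s_ba.size == 0:
        raise NoInterfaceError(
            f"no buried dots within the {band} A band "
            f"({s_ab.size} A-side, {s_ba.size} B-side)"
        )
    for dot, flag in zip(receptor_dots, buried_a):
        dot.buried = bool(flag)
    for dot, flag in zip(ligand_dots, buried_b):
        dot.buried = bool(flag)

    med_ab = float(np.median(s_ab))
    med_ba = float(np.median(s_ba))
    return ScReport(
        sc=0.5 * (med_ab + med_ba),
        s_ab_median=med_ab,
        s_ba_median=med_ba,
        n_dots_a=int(s_ab.size),
        n_dots_b=int(s_ba.size),
        w=w,
    )
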