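"""Independent oracles used to check the package's own implementations.

Each routine here reaches the same quantity as a package operation by a
different route: quaternion eigendecomposition instead of SVD for optimal
superposition, the spherical-cap closed form instead of numerical SASA
quadrature, and a per-injection equilibrium bisection instead of the
closed-form binding isotherm.
"""

from __future__ import annotations

import numpy as np


def quaternion_superposition_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD of q onto p via Horn's quaternion eigen-decomposition."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    m = q0.T @ p0
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(k)[-1]
    n = p.shape[0]
    e0 = (np.sum(p0**2) + np.sum(q0**2)) - 2.0 * lam_max
    return float(np.sqrt(max(e0, 0.0) / n))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    a = rng.normal(size=(3, 3))
    qm, r = np.linalg.qr(a)
    qm *= np.sign(np.diag(r))
    if np.linalg.det(qm) < 0:
        qm[:, 0] *= -1
    return qm


def best_rmsd_random_rotations(
    p: np.ndarray, q: np.ndarray, n_trials: int, seed: int
) -> float:
    """Monte-Carlo lower-quality bound: best RMSD over random rotations."""
    rng = np.random.default_rng(seed)
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    best = np.inf
    for _ in range(n_trials):
        rot = random_rotation(rng)
        rmsd = np.sqrt(np.mean(np.sum((q0 @ rot.T - p0) ** 2, axis=1)))
        best = min(best, rmsd)
    return float(best)


def two_sphere_sasa(r1: float, r2: float, d: float) -> float:
    """Closed-form accessible area of two overlapping spheres (radii already
    probe-expanded), center distance d with |r1 - r2| < d < r1 + r2."""
    if d >= r1 + r2:
        return 4.0 * np.pi * (r1**2 + r2**2)
    if d <= abs(r1 - r2):
        big = max(r1, r2)
        return 4.0 * np.pi * big**2
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2.0 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2.0 * d)
    return 4.0 * np.pi * (r1**2 + r2**2) - 2.0 * np.pi * (r1 * h1 + r2 * h2)


def itc_heats_by_bisection(
    n: float,
    ka: float,
    dh: float,
    m_tot: np.ndarray,
    x_tot: np.ndarray,
    v0: float,
    dv: np.ndarray,
) -> np.ndarray:
    """Per-injection heats from a numerical binding equilibrium.

    For each injection the free-injectant concentration is solved by
    bisection of  Ka = B / ((X - B)(n M - B))  with B the bound injectant;
    the cumulative heat is B * dH * V0, and the same displacement correction
    as the instrument convention gives per-injection heats.
    """
    q = np.empty(len(m_tot))
    for i, (m, x) in enumerate(zip(m_tot, x_tot)):
        lo, hi = 0.0, min(x, n * m)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            free_x = x - mid
            free_sites = n * m - mid
            # f > 0 when mid below the equilibrium bound concentration
            f = ka * free_x * free_sites - mid
            if f > 0:
                lo = mid
            else:
                hi = mid
        bound = 0.5 * (lo + hi)
        q[i] = bound * dh * v0
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0
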