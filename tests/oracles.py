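"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they validate: the rotational
search below never calls the SVD-based superposition, and the grid scorer
re-implements the mock step potential with plain loops.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _rmsd_after_rotation(rotvec: np.ndarray, a0: np.ndarray, b0: np.ndarray) -> float:
    moved = Rotation.from_rotvec(rotvec).apply(b0)
    return float(np.sqrt(np.mean(np.sum((a0 - moved) ** 2, axis=1))))


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def brute_force_min_rmsd(a: np.ndarray, b: np.ndarray, n_axes: int = 60,
                         n_angles: int = 24) -> float:
    """Minimum RMSD of b onto a over all proper rotations (+ centroid shift),
    found by an axis-angle grid search followed by local refinement."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    best_vec = np.zeros(3)
    best = _rmsd_after_rotation(best_vec, a0, b0)
    for axis in _fibonacci_sphere(n_axes):
        for angle in np.linspace(0, np.pi, n_angles + 1)[1:]:
            vec = axis * angle
            val = _rmsd_after_rotation(vec, a0, b0)
            if val < best:
                best, best_vec = val, vec
    res = minimize(_rmsd_after_rotation, best_vec, args=(a0, b0), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return min(best, float(res.fun))


def step_potential_score(protein: np.ndarray, ligand: np.ndarray) -> float:
    """Plain-loop re-implementation of the mock engine's step potential."""
    score = 0.0
    for lx in ligand:
        for px in protein:
            d = float(np.linalg.norm(lx - px))
            if d < 2.0:
                score += 10.0
            elif d <= 4.0:
                score -= 0.1
    return score


def grid_best_score(protein: np.ndarray, ligand: np.ndarray, lo: np.ndarray,
                    hi: np.ndarray, step: float) -> float:
    """Exhaustive translational search (no rotation) over the box grid."""
    lig0 = ligand - ligand.mean(axis=0)
    best = np.inf
    for x in np.arange(lo[0], hi[0] + 1e-9, step):
        for y in np.arange(lo[1], hi[1] + 1e-9, step):
            for z in np.arange(lo[2], hi[2] + 1e-9, step):
                s = step_potential_score(protein, lig0 + np.array([x, y, z]))
                best = min(best, s)
    return best
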