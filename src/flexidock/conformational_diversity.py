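"""Conformational-diversity analysis of a crystal-structure ensemble.

Given C-alpha traces of several deposited conformers of one protein, this
module superposes every pair (Kabsch least-squares fit), builds the
pairwise RMSD matrix, locates the maximum-diversity pair, and standardizes
the per-residue displacements of that pair into a Z-score profile:

    d_i = |CA_a,i - (R . CA_b,i + t)|       one global superposition
    z_i = (d_i - mean(d)) / SD_pop(d)

Residues with z < 0 move less than the average residue of the pair —
a binding site whose residues all satisfy z < 0 sits in a relatively
rigid region of the structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .structure_io import CaTrace, ResidueCorrespondence, map_common_residues

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "RmsdMatrix",
    "ZScoreProfile",
    "SiteFlexibilityReport",
    "standardize_displacements",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "max_diversity_pair",
    "zscore_profile",
    "site_flexibility",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid fit of coordinate set b onto a."""

    rotation: np.ndarray     # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float              # Angstrom
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, Angstrom
    n_common: np.ndarray | None = None  # paired C-alpha counts per cell

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("RMSD matrix shape does not match id list")
        if not np.allclose(v, v.T):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("RMSD matrix diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("RMSD values must be non-negative")
        self.values = v


@dataclass
class ZScoreProfile:
    """Per-residue displacement and Z-score for one conformer pair."""

    pair: tuple[str, str]
    residue_numbers: list[int]
    displacements: np.ndarray  # d_i, Angstrom
    zscores: np.ndarray        # z_i, dimensionless
    mean_d: float
    sd_d: float                # population SD (ddof = 0)

    def z_of(self, residue_number: int) -> float:
        idx = self.residue_numbers.index(residue_number)
        return float(self.zscores[idx])


@dataclass
class SiteFlexibilityReport:
    site_residues: list[int]
    zscores: dict[int, float]
    missing: list[int] = field(default_factory=list)
    fraction_below_zero: float = 0.0
    verdict: str = ""


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of b onto a.

    Kabsch algorithm via SVD of the covariance matrix; the reflection
    branch is corrected through the sign of det(V W^T) so the result is
    always a proper rotation (det = +1).

    Parameters are (n, 3) arrays with n >= 3 and equal lengths; returns the
    fit and the minimized RMSD in Angstrom.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in length: {a.shape[0]} vs {b.shape[0]}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 paired atoms")

    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0 = a - cen_a
    b0 = b - cen_b

    # covariance of b (moving) against a (fixed)
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        logger.warning("degenerate (near-collinear) coordinates in superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cen_a - rotation @ cen_b

    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_atoms=n)


def pairwise_rmsd_matrix(ensemble: list[CaTrace]) -> RmsdMatrix:
    """C-alpha RMSD between all conformers.

    Each unordered pair is mapped onto its own common-residue set and
    superposed once; the matrix is symmetric by construction.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 conformers for a pairwise RMSD matrix")
    ids = [t.label for t in ensemble]
    n = len(ensemble)
    values = np.zeros((n, n))
    n_common = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        try:
            corr = map_common_residues(ensemble[i], ensemble[j])
        except ValueError as exc:
            raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
        ca, cb = corr.coords(ensemble[i], ensemble[j])
        fit = kabsch_superpose(ca, cb)
        values[i, j] = values[j, i] = fit.rmsd
        n_common[i, j] = n_common[j, i] = fit.n_atoms
    return RmsdMatrix(ids=ids, values=values, n_common=n_common)


def max_diversity_pair(matrix: RmsdMatrix) -> tuple[str, str, float]:
    """Arg-max over the strict upper triangle; ties broken lexicographically
    by (id_i, id_j)."""
    n = len(matrix.ids)
    best: tuple[str, str] | None = None
    best_val = -1.0
    for i, j in combinations(range(n), 2):
        ids = tuple(sorted((matrix.ids[i], matrix.ids[j])))
        v = matrix.values[i, j]
        if v > best_val or (v == best_val and best is not None and ids < best):
            best_val = v
            best = ids
    assert best is not None
    if np.isclose(best_val, matrix.values[np.triu_indices(n, 1)]).sum() > 1:
        logger.warning("maximum-diversity pair is tied; lexicographic tie-break applied")
    return best[0], best[1], float(best_val)


def standardize_displacements(d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize displacements to z-scores with the population SD.

    Returns (z, mean, SD).  When all displacements are equal (SD = 0) the
    z-scores are all 0 (degenerate profile, warned).
    """
    d = np.asarray(d, dtype=float)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=0))
    if sd_d > 0:
        z = (d - mean_d) / sd_d
    else:
        logger.warning("all per-residue displacements equal (SD = 0); z-scores set to 0")
        z = np.zeros_like(d)
    return z, mean_d, sd_d


def zscore_profile(
    a: CaTrace,
    b: CaTrace,
    correspondence: ResidueCorrespondence | None = None,
) -> ZScoreProfile:
    """Per-residue displacement Z-scores after ONE global superposition.

    Displacements use the Kabsch fit over all common C-alphas (no local or
    windowed refits); the Z-score standardizes with the population SD
    (ddof = 0).  If all displacements are equal (SD = 0) the profile is
    degenerate and all z_i are set to 0 with a warning.
    """
    corr = correspondence or map_common_residues(a, b)
    ca, cb = corr.coords(a, b)
    fit = kabsch_superpose(ca, cb)
    d = np.linalg.norm(ca - fit.transform(cb), axis=1)
    z, mean_d, sd_d = standardize_displacements(d)
    residue_numbers = [a.residue_numbers[i] for i, _ in corr.pairs]
    return ZScoreProfile(
        pair=(a.label, b.label),
        residue_numbers=residue_numbers,
        displacements=d,
        zscores=z,
        mean_d=mean_d,
        sd_d=sd_d,
    )


def site_flexibility(profile: ZScoreProfile, site: list[int]) -> SiteFlexibilityReport:
    """Z-scores of binding-site residues and the fraction with z < 0.

    Verdict is "low-mobility site" iff every present site residue has
    z < 0.  Site residues missing from the profile are reported, not fatal.
    """
    if not site:
        raise ValueError("site residue list is empty")
    zmap: dict[int, float] = {}
    missing: list[int] = []
    for res in site:
        if res in profile.residue_numbers:
            zmap[res] = profile.z_of(res)
        else:
            missing.append(res)
    if missing:
        logger.warning("site residues missing from profile: %s", missing)
    if zmap:
        fraction = sum(1 for z in zmap.values() if z < 0) / len(zmap)
    else:
        fraction = 0.0
    verdict = "low-mobility site" if zmap and fraction == 1.0 else "not uniformly low-mobility"
    return SiteFlexibilityReport(
        site_residues=list(site),
        zscores=zmap,
        missing=missing,
        fraction_below_zero=fraction,
        verdict=verdict,
    )
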