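"""Synthetic conformer ensembles and toy complexes with known ground truth.

The generator emulates the statistical structure that ensemble analysis
assumes in real crystal-structure collections: one common chain observed
many times, with heterogeneous per-residue mobility (a rigid core and
mobile loops) and an arbitrary rigid placement of each deposited copy.

* ``generate_ensemble`` builds a self-avoiding C-alpha backbone (3.8 A
  consecutive spacing), then emits conformers as
  ``base + isotropic Gaussian per-residue displacement (sigma_i) -> random
  rigid transform``.  An optional per-conformer amplitude scale makes the
  expected maximum-diversity pair known by construction.
* ``generate_complex`` plants a ligand next to a chain with exact contact
  distances and an exact hydrogen-bond geometry, so contact detection and
  H-bond detection can be checked against construction.

All randomness is driven by the spec seed; identical specs give
byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .interaction_analysis import LigandPose
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "EnsembleSpec",
    "ComplexSpec",
    "EnsembleGroundTruth",
    "ComplexGroundTruth",
    "generate_ensemble",
    "generate_complex",
]

_CA_SPACING = 3.8  # A, consecutive C-alpha distance in an extended chain
_MIN_SELF_DISTANCE = 3.8  # A, self-avoidance for non-consecutive residues


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic conformer ensemble.

    ``sigma`` is the default per-residue displacement SD (A);
    ``sigma_ranges`` overrides it on 1-based inclusive residue ranges,
    e.g. ``[(20, 35, 2.0)]`` makes residues 20..35 a mobile loop.
    ``conformer_scale`` multiplies every sigma for that conformer; the
    two largest-scale conformers form the expected maximum-diversity pair.
    """

    n_residues: int = 100
    n_conformers: int = 10
    sigma: float = 0.3
    sigma_ranges: list[tuple[int, int, float]] = field(default_factory=list)
    conformer_scale: list[float] | None = None
    site_residue: int | None = 56  # written as TRP (W56-centred workflows)
    max_translation: float = 20.0  # A, range of the random rigid placement
    seed: int = 0

    def sigma_profile(self) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        prof = np.full(self.n_residues, float(self.sigma))
        for lo, hi, s in self.sigma_ranges:
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"sigma range ({lo}, {hi}) outside 1..{self.n_residues}")
            if s < 0:
                raise ValueError("sigma must be >= 0")
            prof[lo - 1: hi] = s
        return prof

    def scales(self) -> np.ndarray:
        if self.conformer_scale is None:
            return np.ones(self.n_conformers)
        if len(self.conformer_scale) != self.n_conformers:
            raise ValueError("conformer_scale length must equal n_conformers")
        return np.asarray(self.conformer_scale, dtype=float)


@dataclass
class EnsembleGroundTruth:
    sigma_per_residue: np.ndarray
    conformer_scale: np.ndarray
    conformer_ids: list[str]
    base_coords: np.ndarray
    displacements: np.ndarray  # (n_conformers, n_residues, 3), before rigid motion

    def expected_max_pair(self) -> tuple[str, str]:
        """Pair maximizing expected squared displacement, i.e. scale_i^2 + scale_j^2."""
        s2 = self.conformer_scale**2
        best = None
        best_val = -np.inf
        for i in range(len(s2)):
            for j in range(i + 1, len(s2)):
                v = s2[i] + s2[j]
                if v > best_val:
                    best_val = v
                    best = (self.conformer_ids[i], self.conformer_ids[j])
        assert best is not None
        return tuple(sorted(best))


def _self_avoiding_backbone(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random C-alpha walk with fixed 3.8 A steps avoiding self-overlap."""
    coords = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        for _ in range(200):
            # bend the previous direction by a bounded random angle
            perturb = rng.normal(scale=0.6, size=3)
            cand = direction + perturb
            cand /= np.linalg.norm(cand)
            pos = coords[i - 1] + _CA_SPACING * cand
            prev = coords[: max(i - 1, 0)]
            if prev.size == 0 or np.min(np.linalg.norm(prev - pos, axis=1)) >= _MIN_SELF_DISTANCE:
                coords[i] = pos
                direction = cand
                break
        else:  # fall back to a straight extension, always self-avoiding locally
            coords[i] = coords[i - 1] + _CA_SPACING * direction
    return coords


def _ca_only_structure(structure_id: str, coords: np.ndarray,
                       site_residue: int | None) -> Structure:
    chain = Chain(id="A")
    for i, xyz in enumerate(coords, start=1):
        name = "TRP" if site_residue is not None and i == site_residue else "ALA"
        chain.residues.append(
            Residue(number=i, icode="", name=name,
                    atoms={"CA": Atom(name="CA", element="C", coord=np.array(xyz))})
        )
    return Structure(id=structure_id, chains=[chain])


def generate_ensemble(spec: EnsembleSpec) -> tuple[list[Structure], EnsembleGroundTruth]:
    """Generate an ensemble of conformers plus its ground-truth table."""
    if spec.n_residues < 3 or spec.n_conformers < 1:
        raise ValueError("need >= 3 residues and >= 1 conformer")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.sigma_profile()
    scales = spec.scales()
    base = _self_avoiding_backbone(spec.n_residues, rng)
    site = spec.site_residue if spec.site_residue and spec.site_residue <= spec.n_residues else None

    structures: list[Structure] = []
    ids: list[str] = []
    displacements = np.zeros((spec.n_conformers, spec.n_residues, 3))
    for c in range(spec.n_conformers):
        noise = rng.normal(size=(spec.n_residues, 3)) * (scales[c] * sigma)[:, None]
        displacements[c] = noise
        coords = base + noise
        rot = Rotation.random(random_state=np.random.RandomState(
            (spec.seed + 1) * 1000 + c)).as_matrix()
        trans = rng.uniform(-spec.max_translation, spec.max_translation, size=3)
        coords = coords @ rot.T + trans
        cid = f"SYN{c:02d}"
        structures.append(_ca_only_structure(cid, coords, site))
        ids.append(cid)
    truth = EnsembleGroundTruth(
        sigma_per_residue=sigma,
        conformer_scale=scales,
        conformer_ids=ids,
        base_coords=base,
        displacements=displacements,
    )
    return structures, truth


# ---------------------------------------------------------------------------
# toy complexes


@dataclass
class ComplexSpec:
    """Recipe for a toy protein-ligand complex with planted geometry.

    ``contacts`` maps residue number -> planted minimum heavy-atom
    distance (A).  ``hbond`` optionally plants a ligand donor N (with
    explicit H) at the given heavy-atom distance and D-H...A angle from a
    carbonyl-like acceptor O added to the named residue.
    """

    n_residues: int = 60
    contacts: dict[int, float] = field(default_factory=dict)
    hbond: tuple[int, float, float] | None = None  # (residue, distance A, angle deg)
    clearance: float = 4.5  # A, min ligand distance to every unplanted residue
    seed: int = 0

    def validate(self) -> None:
        for res, d in self.contacts.items():
            if not 1 <= res <= self.n_residues:
                raise ValueError(f"contact residue {res} outside chain")
            if d <= 0:
                raise ValueError("planted distances must be positive")
        if self.hbond is not None:
            res, dist, angle = self.hbond
            if not 1 <= res <= self.n_residues:
                raise ValueError(f"h-bond residue {res} outside chain")
            if dist <= 0 or not 0 < angle <= 180:
                raise ValueError("h-bond geometry must have d > 0 and 0 < angle <= 180")


@dataclass
class ComplexGroundTruth:
    contact_residues: list[int]
    contact_distances: dict[int, float]
    hbond: tuple[int, float, float] | None


def _hbond_fragment(acceptor: np.ndarray, direction: np.ndarray,
                    dist: float, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Place donor N and its H so that |N-A| = dist and D-H...A = angle.

    H sits 1.0 A from the donor.  Solved in the plane spanned by
    ``direction`` and an arbitrary perpendicular.
    """
    direction = direction / np.linalg.norm(direction)
    # perpendicular axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, ref)
    perp /= np.linalg.norm(perp)

    donor = acceptor + dist * direction
    alpha = np.radians(angle_deg)
    # H at distance 1.0 from donor, making the prescribed angle at H:
    # place H = donor - cos(delta)*u*1.0 ... solve via triangle D-H-A with
    # |DH| = 1, |DA| = dist, angle at H = alpha -> angle at A from sine rule.
    sin_at_a = np.clip(np.sin(alpha) * 1.0 / dist, -1.0, 1.0)
    beta = np.arcsin(sin_at_a)             # angle at acceptor
    gamma = np.pi - alpha - beta           # angle at donor
    # H direction from donor: rotate (acceptor-donor) unit vector by gamma
    u = -direction  # donor -> acceptor
    h_dir = np.cos(gamma) * u + np.sin(gamma) * perp
    h = donor + 1.0 * h_dir
    return donor, h


def generate_complex(spec: ComplexSpec) -> tuple[Structure, LigandPose, ComplexGroundTruth]:
    """Build a toy complex realizing exactly the planted contacts/H-bond.

    The chain is laid out as a straight C-alpha trace along x and ligand
    atoms are planted perpendicular to it (+y), so each planted atom is
    within its stated distance of exactly one residue: the next residue
    along the chain is already sqrt(3.8^2 + d^2) away.  The H-bond
    residue (mirroring W56) is written as TRP.
    """
    spec.validate()
    backbone = np.zeros((spec.n_residues, 3))
    backbone[:, 0] = _CA_SPACING * np.arange(spec.n_residues)
    site = spec.hbond[0] if spec.hbond is not None else None
    structure = _ca_only_structure("SYNCPLX", backbone, site)
    chain = structure.chains[0]

    direction = np.array([0.0, 1.0, 0.0])  # perpendicular to the chain axis
    lig_coords: list[np.ndarray] = []
    lig_elements: list[str] = []
    lig_names: list[str] = []
    truth_contacts: dict[int, float] = {}

    for res_num, dist in sorted(spec.contacts.items()):
        ca = backbone[res_num - 1]
        pos = ca + dist * direction
        lig_coords.append(pos)
        lig_elements.append("C")
        lig_names.append(f"C{len(lig_coords)}")
        truth_contacts[res_num] = dist

    hbond_truth = None
    if spec.hbond is not None:
        res_num, dist, angle = spec.hbond
        res = chain.residue(res_num)
        ca = backbone[res_num - 1]
        acceptor_xyz = ca + 1.5 * direction  # carbonyl-like O off the C-alpha
        res.atoms["O"] = Atom(name="O", element="O", coord=acceptor_xyz)
        donor, h = _hbond_fragment(acceptor_xyz, direction, dist, angle)
        lig_coords += [donor, h]
        lig_elements += ["N", "H"]
        lig_names += ["N1", "H1"]
        hbond_truth = (res_num, dist, angle)

    if not lig_coords:
        pose = LigandPose(pose_id="planted", conformer_id=structure.id,
                          coords=np.zeros((0, 3)), elements=[])
        return structure, pose, ComplexGroundTruth([], {}, None)

    pose = LigandPose(
        pose_id="planted",
        conformer_id=structure.id,
        coords=np.array(lig_coords),
        elements=lig_elements,
        atom_names=lig_names,
    )

    # verify no accidental extra contacts closer than the planted ones
    planted = set(truth_contacts)
    if hbond_truth is not None:
        planted.add(hbond_truth[0])
    heavy = pose.coords[pose.heavy_mask()]
    for i, ca in enumerate(backbone, start=1):
        if i in planted:
            continue
        dmin = float(np.min(np.linalg.norm(heavy - ca, axis=1)))
        if dmin < spec.clearance:
            raise ValueError(
                f"infeasible geometry: residue {i} lies {dmin:.1f} A from the ligand "
                f"(clearance {spec.clearance:.1f} A); use fewer/looser planted contacts"
            )
    return structure, pose, ComplexGroundTruth(
        contact_residues=sorted(planted),
        contact_distances=truth_contacts,
        hbond=hbond_truth,
    )
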