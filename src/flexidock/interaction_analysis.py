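"""Docking-box geometry, ligand contacts, hydrogen bonds and pose RMSD.

Ligand poses are compared in the *receptor-aligned frame*: when the two
receptors are different conformers, the rigid fit that superposes the
conformers is first applied to the second pose, then the RMSD over mapped
heavy atoms is computed without re-fitting the ligand.  This measures
displacement of the binding mode, not internal ligand geometry.

Contacts use a heavy-atom distance cutoff (default 4.0 A).  Hydrogen
bonds use donor/acceptor heavy-atom distance <= 3.5 A and, when an
explicit hydrogen is present, a D-H...A angle >= 120 deg; crystal
structures usually lack hydrogens, in which case the distance-only
criterion is applied and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Structure

__all__ = [
    "DockingBox",
    "LigandPose",
    "ResidueContact",
    "HBond",
    "make_docking_box",
    "contact_residues",
    "detect_hbonds",
    "pose_rmsd",
    "substructure_rmsd",
    "load_ligand_pose",
    "parse_pdbqt_poses",
]

#: residues whose side chains offer N/O H-bond partners; backbone N (donor)
#: and O (acceptor) are always considered.
_PROTEIN_DONOR_ATOMS = {
    "N",  # backbone amide
    "ND1", "NE2",          # His
    "ND2",                 # Asn
    "NE", "NH1", "NH2",    # Arg
    "NE1",                 # Trp
    "NZ",                  # Lys
    "OG", "OG1", "OH",     # Ser/Thr/Tyr
    "SG",                  # Cys (weak, kept for completeness)
}
_PROTEIN_ACCEPTOR_ATOMS = {
    "O", "OXT",            # backbone / terminus
    "OD1", "OD2",          # Asp/Asn
    "OE1", "OE2",          # Glu/Gln
    "OG", "OG1", "OH",
    "ND1", "NE2",          # His
    "SD",                  # Met
}


@dataclass
class DockingBox:
    """Axis-aligned cubic search volume for pose sampling."""

    center: np.ndarray  # (3,), Angstrom
    edge: float = 14.0  # Angstrom

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.edge <= 0:
            raise ValueError("docking box edge must be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.edge / 2

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.edge / 2

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.lo) & (pts <= self.hi), axis=1)


@dataclass
class LigandPose:
    """One docked placement of a ligand against a named conformer."""

    pose_id: str
    conformer_id: str
    coords: np.ndarray            # (n, 3) Angstrom
    elements: list[str]
    atom_names: list[str] | None = None
    graph_mapping: list[int] | None = None  # pose atom -> MolecularGraph atom
    h_counts: list[int] | None = None       # hydrogens on each pose atom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("element list length does not match coordinates")

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        return LigandPose(
            pose_id=self.pose_id,
            conformer_id=self.conformer_id,
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            elements=list(self.elements),
            atom_names=self.atom_names,
            graph_mapping=self.graph_mapping,
            h_counts=self.h_counts,
        )


@dataclass
class ResidueContact:
    chain_id: str
    residue_number: int
    residue_name: str
    min_distance: float  # Angstrom


@dataclass
class HBond:
    donor: str            # "protein:A/TRP56/NE1" or "ligand:N1"
    acceptor: str
    distance: float       # heavy-atom D...A, Angstrom
    angle: float | None   # D-H...A degrees, None when no explicit H
    distance_only: bool = field(init=False)

    def __post_init__(self) -> None:
        self.distance_only = self.angle is None


def make_docking_box(structure: Structure, chain_id: str, residue_number: int,
                     edge: float = 14.0) -> DockingBox:
    """Cubic box centred on the C-alpha of the given residue."""
    chain = structure.chain(chain_id)
    res = chain.residue(residue_number)
    ca = res.ca
    if ca is None:
        raise ValueError(
            f"residue {residue_number} of chain {chain_id} has no C-alpha to centre the box on"
        )
    return DockingBox(center=ca.coord.copy(), edge=edge)


def _protein_heavy_atoms(structure: Structure):
    """Yield (chain_id, residue, atom) for all heavy protein atoms."""
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                if atom.element.upper() != "H":
                    yield chain.id, res, atom


def contact_residues(structure: Structure, pose: LigandPose,
                     cutoff: float = 4.0) -> list[ResidueContact]:
    """Residues with any heavy-atom pair within ``cutoff`` of the ligand,
    sorted by minimum distance (closest first)."""
    lig = pose.coords[pose.heavy_mask()]
    if lig.shape[0] == 0:
        raise ValueError("ligand pose has no heavy atoms")
    contacts: list[ResidueContact] = []
    for chain in structure.chains:
        for res in chain.residues:
            coords = np.array(
                [a.coord for a in res.atoms.values() if a.element.upper() != "H"]
            )
            if coords.size == 0:
                continue
            dmin = float(cdist(coords, lig).min())
            if dmin <= cutoff:
                contacts.append(ResidueContact(chain.id, res.number, res.name, dmin))
    contacts.sort(key=lambda c: c.min_distance)
    return contacts


def _ligand_hbond_roles(pose: LigandPose) -> tuple[list[int], list[int]]:
    """Indices of ligand donor and acceptor atoms (N/O; donor needs >= 1 H)."""
    donors, acceptors = [], []
    explicit_h = [i for i, e in enumerate(pose.elements) if e.upper() == "H"]
    for i, e in enumerate(pose.elements):
        if e.upper() not in ("N", "O"):
            continue
        acceptors.append(i)
        n_h = 0
        if pose.h_counts is not None:
            n_h = pose.h_counts[i]
        elif explicit_h:
            d = np.linalg.norm(pose.coords[explicit_h] - pose.coords[i], axis=1)
            n_h = int(np.sum(d < 1.25))
        else:
            n_h = 1  # hydrogens unknown: assume donor-capable, flagged downstream
        if n_h >= 1:
            donors.append(i)
    return donors, acceptors


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triangle a-b-c, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _best_h_angle(donor_xyz: np.ndarray, acceptor_xyz: np.ndarray,
                  h_coords: np.ndarray) -> float | None:
    """Largest D-H...A angle over hydrogens bonded to the donor."""
    if h_coords.size == 0:
        return None
    d = np.linalg.norm(h_coords - donor_xyz, axis=1)
    bonded = h_coords[d < 1.25]
    if bonded.size == 0:
        return None
    return max(_angle_deg(donor_xyz, h, acceptor_xyz) for h in bonded)


def detect_hbonds(structure: Structure, pose: LigandPose, d_max: float = 3.5,
                  angle_min: float = 120.0) -> list[HBond]:
    """Protein-ligand hydrogen bonds in both directions.

    Criterion: donor/acceptor heavy-atom distance <= ``d_max``; when an
    explicit hydrogen is bonded to the donor, additionally require the
    D-H...A angle >= ``angle_min``; otherwise distance-only (flagged on
    the returned HBond).
    """
    lig_donors, lig_acceptors = _ligand_hbond_roles(pose)
    lig_h = pose.coords[[i for i, e in enumerate(pose.elements) if e.upper() == "H"]]

    prot_donors, prot_acceptors = [], []
    for chain_id, res, atom in _protein_heavy_atoms(structure):
        label = f"protein:{chain_id}/{res.name}{res.number}/{atom.name}"
        res_h = np.array(
            [a.coord for a in res.atoms.values() if a.element.upper() == "H"]
        ).reshape(-1, 3)
        if atom.name in _PROTEIN_DONOR_ATOMS and atom.element.upper() in ("N", "O", "S"):
            prot_donors.append((label, atom.coord, res_h))
        if atom.name in _PROTEIN_ACCEPTOR_ATOMS and atom.element.upper() in ("N", "O", "S"):
            prot_acceptors.append((label, atom.coord))

    def lig_label(i: int) -> str:
        name = pose.atom_names[i] if pose.atom_names else f"{pose.elements[i]}{i}"
        return f"ligand:{name}"

    bonds: list[HBond] = []
    # ligand donor -> protein acceptor
    for i in lig_donors:
        for label, axyz in prot_acceptors:
            dist = float(np.linalg.norm(pose.coords[i] - axyz))
            if dist > d_max:
                continue
            angle = _best_h_angle(pose.coords[i], axyz, lig_h)
            if angle is not None and angle < angle_min:
                continue
            bonds.append(HBond(donor=lig_label(i), acceptor=label,
                               distance=dist, angle=angle))
    # protein donor -> ligand acceptor
    for label, dxyz, res_h in prot_donors:
        for i in lig_acceptors:
            dist = float(np.linalg.norm(dxyz - pose.coords[i]))
            if dist > d_max:
                continue
            angle = _best_h_angle(dxyz, pose.coords[i], res_h)
            if angle is not None and angle < angle_min:
                continue
            bonds.append(HBond(donor=label, acceptor=lig_label(i),
                               distance=dist, angle=angle))
    bonds.sort(key=lambda b: b.distance)
    return bonds


def _mapped_heavy_coords(a: LigandPose, b: LigandPose) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of a and b ordered by their shared graph mapping."""
    heavy_a = a.heavy_mask()
    heavy_b = b.heavy_mask()
    if a.graph_mapping is None or b.graph_mapping is None:
        if heavy_a.sum() != heavy_b.sum():
            raise ValueError("poses differ in heavy-atom count and carry no graph mapping")
        return a.coords[heavy_a], b.coords[heavy_b]
    map_a = {g: i for i, g in enumerate(a.graph_mapping) if heavy_a[i]}
    map_b = {g: i for i, g in enumerate(b.graph_mapping) if heavy_b[i]}
    unmatched = sorted(set(map_a) ^ set(map_b))
    if unmatched:
        raise ValueError(f"unmapped graph atoms between poses: {unmatched}")
    order = sorted(map_a)
    return (
        a.coords[[map_a[g] for g in order]],
        b.coords[[map_b[g] for g in order]],
    )


def pose_rmsd(a: LigandPose, b: LigandPose, receptor_fit=None, refit: bool = False) -> float:
    """Heavy-atom RMSD between two poses in the receptor-aligned frame.

    ``receptor_fit`` is the :class:`SuperpositionResult` that superposes
    b's receptor conformer onto a's; it is applied to pose b before the
    RMSD.  By default no ligand re-fitting is done (binding-mode
    displacement); ``refit=True`` additionally superposes the ligand
    itself (internal-geometry comparison).
    """
    if receptor_fit is not None:
        b = b.transformed(receptor_fit.rotation, receptor_fit.translation)
    ca, cb = _mapped_heavy_coords(a, b)
    if refit:
        from .conformational_diversity import kabsch_superpose
        return kabsch_superpose(ca, cb).rmsd
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def substructure_rmsd(a: LigandPose, b: LigandPose, groups, receptor_fit=None) -> dict[str, float]:
    """In-frame RMSD per named substructure group.

    Group atom indices refer to the shared MolecularGraph.  When the
    groups partition the heavy atoms, overall RMSD^2 equals the
    atom-count-weighted mean of the per-group RMSD^2.
    """
    if receptor_fit is not None:
        b = b.transformed(receptor_fit.rotation, receptor_fit.translation)
    heavy_a = a.heavy_mask()
    heavy_b = b.heavy_mask()
    if a.graph_mapping is not None and b.graph_mapping is not None:
        map_a = {g: i for i, g in enumerate(a.graph_mapping) if heavy_a[i]}
        map_b = {g: i for i, g in enumerate(b.graph_mapping) if heavy_b[i]}
    else:
        idx_a = np.flatnonzero(heavy_a)
        idx_b = np.flatnonzero(heavy_b)
        map_a = {int(g): int(i) for g, i in zip(idx_a, idx_a)}
        map_b = {int(g): int(i) for g, i in zip(idx_b, idx_b)}
    out: dict[str, float] = {}
    for name, idxs in groups.groups.items():
        if not idxs:
            raise ValueError(f"substructure group {name!r} is empty")
        missing = [g for g in idxs if g not in map_a or g not in map_b]
        if missing:
            raise ValueError(f"group {name!r}: atoms {missing} not present in both poses")
        pa = a.coords[[map_a[g] for g in idxs]]
        pb = b.coords[[map_b[g] for g in idxs]]
        out[name] = float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
    return out


# ---------------------------------------------------------------------------
# pose file input


def parse_pdbqt_poses(text: str, pose_id: str = "pose",
                      conformer_id: str = "") -> list["LigandPose"]:
    """Parse ligand poses from a PDBQT block (one pose per MODEL).

    Only element and coordinates are used; partial charges and AutoDock
    atom types are parsed past, not interpreted.
    """
    models: list[tuple[list[np.ndarray], list[str], list[str]]] = []
    current: tuple[list[np.ndarray], list[str], list[str]] | None = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if line.startswith("MODEL"):
            current = ([], [], [])
            models.append(current)
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = ([], [], [])
                models.append(current)
            try:
                xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise ValueError(f"malformed coordinate field in line: {line!r}") from exc
            ad_type = line[77:79].strip() or line[12:16].strip()
            element = "".join(c for c in ad_type if c.isalpha())[:2].capitalize()
            if element in ("Oa", "Na", "Nd", "Hd", "Sa"):  # AutoDock subtype suffixes
                element = element[0]
            current[0].append(xyz)
            current[1].append(element)
            current[2].append(line[12:16].strip())
    poses = []
    for k, (coords, elements, names) in enumerate(models):
        if not coords:
            continue
        poses.append(
            LigandPose(
                pose_id=f"{pose_id}:{k}" if len(models) > 1 else pose_id,
                conformer_id=conformer_id,
                coords=np.array(coords),
                elements=elements,
                atom_names=names,
            )
        )
    if not poses:
        raise ValueError("no atoms found in PDBQT input")
    return poses


def load_ligand_pose(path, conformer_id: str = "") -> "LigandPose":
    """Load a ligand pose from an SDF/MOL, PDB or PDBQT file.

    SDF parsing goes through RDKit (hydrogen counts and the graph mapping
    are filled in); PDB/PDBQT blocks yield coordinates and elements only.
    """
    from pathlib import Path

    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".mol"):
        from rdkit import Chem

        mol = Chem.MolFromMolBlock(text, removeHs=False)
        if mol is None:
            raise ValueError(f"could not parse SDF/MOL file {path}")
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions(), dtype=float)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        return LigandPose(
            pose_id=path.stem,
            conformer_id=conformer_id,
            coords=coords,
            elements=elements,
            graph_mapping=list(range(mol.GetNumAtoms())),
            h_counts=[a.GetTotalNumHs() for a in mol.GetAtoms()],
        )
    if suffix == ".pdbqt":
        return parse_pdbqt_poses(text, pose_id=path.stem, conformer_id=conformer_id)[0]
    # PDB: take ATOM/HETATM coordinates as the ligand
    coords, elements, names = [], [], []
    for line in text.splitlines():
        if line[:6].strip() in ("ATOM", "HETATM"):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            el = line[76:78].strip() or line[12:16].strip()[0]
            elements.append(el.capitalize())
            names.append(line[12:16].strip())
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return LigandPose(
        pose_id=path.stem,
        conformer_id=conformer_id,
        coords=np.array(coords, dtype=float),
        elements=elements,
        atom_names=names,
    )
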