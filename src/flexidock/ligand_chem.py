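"""Small-molecule graphs and the drug-likeness panel.

Molecules enter as SMILES or SDF (V2000) and are held as a thin wrapper
around an RDKit ``Mol``.  The panel computed here is the classic oral
drug-likeness screen:

* Lipinski's rule of five: MW <= 500, logP <= 5, H-bond donors <= 5,
  H-bond acceptors <= 10 — donors counted as N/O heavy atoms bearing at
  least one hydrogen, acceptors as the N + O count (the original Lipinski
  convention);
* Veber's criteria: rotatable bonds <= 10 and TPSA <= 140 A^2.

TPSA uses Ertl's fragment contributions and logP the Crippen atomic
contributions, both through RDKit; the logP method is tagged in the output
because predicted logP is strongly method-dependent.

Rotatable bonds follow the Veber definition — single, non-ring bonds
between two non-terminal heavy atoms — excluding amide-like C-N bonds
(carbon double-bonded to O or N: amides and amidines share the partial
double-bond character that hinders rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

__all__ = [
    "MolecularGraph",
    "SubstructureMap",
    "DrugLikenessProfile",
    "MoleculeParseError",
    "parse_molecule",
    "mol_weight",
    "hbond_counts",
    "rotatable_bonds",
    "tpsa",
    "logp",
    "druglikeness",
    "RAC1_INHIBITOR_SMILES",
    "rac1_inhibitor",
    "rac1_inhibitor_substructures",
]

#: 1A-116, the Rac1 GEF-interface inhibitor: a diaryl amidine/guanidine
#: bearing a 2-trifluoromethylphenyl group (ring A) and a
#: 3,5-dimethylphenyl group (ring B).  Tautomer with one =N-aryl, one N-H
#: and one NH2 (C16H16F3N3, MW 307.32, TPSA 50.41 A^2).
RAC1_INHIBITOR_SMILES = "NC(Nc1cc(C)cc(C)c1)=Nc1ccccc1C(F)(F)F"


class MoleculeParseError(ValueError):
    """Raised when SMILES/SDF input cannot be parsed."""


@dataclass
class MolecularGraph:
    """Molecular graph with optional 3D coordinates (Angstrom)."""

    mol: Chem.Mol
    source: str = ""

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def formula(self) -> str:
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula
        return CalcMolFormula(self.mol)

    @property
    def n_rings(self) -> int:
        return self.mol.GetRingInfo().NumRings()

    def coords(self) -> np.ndarray | None:
        if self.mol.GetNumConformers() == 0:
            return None
        return np.array(self.mol.GetConformer().GetPositions(), dtype=float)

    def heavy_atom_elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]


@dataclass
class SubstructureMap:
    """Named heavy-atom groups over a molecular graph (0-based indices)."""

    groups: dict[str, list[int]]
    allow_overlap: bool = False

    def validate(self, graph: MolecularGraph) -> None:
        n = graph.mol.GetNumAtoms()
        seen: set[int] = set()
        for name, idxs in self.groups.items():
            if not idxs:
                raise ValueError(f"substructure group {name!r} is empty")
            for i in idxs:
                if not 0 <= i < n:
                    raise ValueError(f"group {name!r}: atom index {i} out of range")
                if i in seen and not self.allow_overlap:
                    raise ValueError(f"atom {i} appears in multiple groups")
            seen.update(idxs)


@dataclass
class DrugLikenessProfile:
    molecular_weight: float  # g/mol
    logp: float
    logp_method: str
    hbd: int
    hba: int
    rotatable_bonds: int
    tpsa: float              # A^2
    lipinski_pass: bool = field(init=False)
    veber_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        self.lipinski_pass = (
            self.molecular_weight <= 500
            and self.logp <= 5
            and self.hbd <= 5
            and self.hba <= 10
        )
        self.veber_pass = self.rotatable_bonds <= 10 and self.tpsa <= 140

    def as_dict(self) -> dict:
        return {
            "molecular_weight": round(self.molecular_weight, 2),
            "logp": round(self.logp, 2),
            "logp_method": self.logp_method,
            "hbd": self.hbd,
            "hba": self.hba,
            "rotatable_bonds": self.rotatable_bonds,
            "tpsa": round(self.tpsa, 2),
            "lipinski_pass": self.lipinski_pass,
            "veber_pass": self.veber_pass,
        }


def parse_molecule(text: str) -> MolecularGraph:
    """Parse SMILES text or an SDF/MOL (V2000) block into a MolecularGraph."""
    stripped = text.strip()
    if "V2000" in text or "$$$$" in text or "\n" in stripped:
        mol = Chem.MolFromMolBlock(text, removeHs=False)
        source = "sdf"
    else:
        mol = Chem.MolFromSmiles(stripped)
        source = "smiles"
    if mol is None:
        snippet = stripped.splitlines()[0][:60] if stripped else "<empty>"
        raise MoleculeParseError(f"could not parse molecule input ({source}): {snippet!r}")
    return MolecularGraph(mol=mol, source=source)


def mol_weight(graph: MolecularGraph) -> float:
    """Average molecular weight in g/mol: standard atomic weights summed
    over all atoms including implicit hydrogens."""
    pt = Chem.GetPeriodicTable()
    total = 0.0
    for atom in graph.mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise ValueError("unknown element (atomic number 0) in molecule")
        total += pt.GetAtomicWeight(atom.GetAtomicNum())
        total += atom.GetTotalNumHs() * pt.GetAtomicWeight(1)
    return total


def hbond_counts(graph: MolecularGraph) -> tuple[int, int]:
    """Lipinski H-bond counts: (donors, acceptors).

    Donors are N/O heavy atoms bearing >= 1 hydrogen; acceptors are all
    N and O atoms.
    """
    hbd = 0
    hba = 0
    for atom in graph.mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hba += 1
            if atom.GetTotalNumHs() >= 1:
                hbd += 1
    return hbd, hba


def _is_amide_like(bond: Chem.Bond) -> bool:
    """C-N single bond where the carbon is double-bonded to O or N."""
    a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a1, a2), (a2, a1)):
        if c.GetAtomicNum() == 6 and n.GetAtomicNum() == 7:
            for other in c.GetBonds():
                if (
                    other.GetIdx() != bond.GetIdx()
                    and other.GetBondType() == Chem.BondType.DOUBLE
                    and other.GetOtherAtom(c).GetAtomicNum() in (7, 8)
                ):
                    return True
    return False


def rotatable_bonds(graph: MolecularGraph) -> int:
    """Count rotatable bonds: single, non-ring bonds between two
    non-terminal heavy atoms, excluding amide-like C-N bonds."""
    count = 0
    for bond in graph.mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a1.GetAtomicNum() == 1 or a2.GetAtomicNum() == 1:
            continue
        if a1.GetDegree() < 2 or a2.GetDegree() < 2:
            continue  # terminal heavy atom
        if _is_amide_like(bond):
            continue
        count += 1
    return count


def tpsa(graph: MolecularGraph) -> float:
    """Topological polar surface area (Ertl fragment contributions), A^2."""
    return float(Descriptors.TPSA(graph.mol))


def logp(graph: MolecularGraph, method: str = "crippen") -> tuple[float, str]:
    if method != "crippen":
        raise ValueError(f"unknown logP method {method!r}; available: crippen")
    return float(Crippen.MolLogP(graph.mol)), "crippen"


def druglikeness(graph: MolecularGraph, logp_method: str = "crippen") -> DrugLikenessProfile:
    """Full drug-likeness panel with Lipinski and Veber verdicts."""
    lp, tag = logp(graph, logp_method)
    hbd, hba = hbond_counts(graph)
    return DrugLikenessProfile(
        molecular_weight=mol_weight(graph),
        logp=lp,
        logp_method=tag,
        hbd=hbd,
        hba=hba,
        rotatable_bonds=rotatable_bonds(graph),
        tpsa=tpsa(graph),
    )


def rac1_inhibitor() -> MolecularGraph:
    """The 1A-116 molecular graph from its canonical SMILES encoding."""
    return parse_molecule(RAC1_INHIBITOR_SMILES)


def rac1_inhibitor_substructures(graph: MolecularGraph | None = None) -> SubstructureMap:
    """Named substructures of 1A-116: ring_A (2-trifluoromethylphenyl,
    CF3 included), ring_B (3,5-dimethylphenyl, methyls included) and the
    guanidine/amidine core (three N + central C)."""
    graph = graph or rac1_inhibitor()
    mol = graph.mol
    core = mol.GetSubstructMatch(Chem.MolFromSmarts("[NX3]C(=[NX2])[NX3]"))
    ring_a = mol.GetSubstructMatch(Chem.MolFromSmarts("c1ccccc1C(F)(F)F"))
    ring_b = mol.GetSubstructMatch(Chem.MolFromSmarts("Cc1cc(C)cc([NX3])c1"))
    if not (core and ring_a and ring_b):
        raise ValueError("substructure patterns did not match the molecule")
    ring_b = tuple(i for i in ring_b if i not in core)
    groups = {
        "ring_A": sorted(ring_a),
        "ring_B": sorted(ring_b),
        "guanidine": sorted(core),
    }
    smap = SubstructureMap(groups=groups)
    smap.validate(graph)
    return smap
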