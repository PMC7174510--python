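"""Read/write macromolecular structures and extract C-alpha traces.

Protein coordinates are handled in PDB format (fixed-column ATOM/HETATM
records).  Parsing is delegated to :mod:`gemmi`; on top of it this module
applies the policies needed for ensemble analysis of crystal structures:

* only the first MODEL of multi-model files is used,
* alternate locations are collapsed to a single conformation per residue
  (highest occupancy wins, ties go to altloc ``'A'``),
* waters and other het groups never enter the polymer chains — they are
  kept in a separate ligand/het block so interaction analysis can still
  see them.

All coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "HetGroup",
    "Structure",
    "CaTrace",
    "ResidueCorrespondence",
    "StructureParseError",
    "parse_structure",
    "parse_structure_file",
    "extract_ca_trace",
    "map_common_residues",
    "write_structure",
]

#: standard 3-letter -> 1-letter amino-acid code (used by the alignment fallback)
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureParseError(ValueError):
    """Raised when PDB text cannot be parsed into a Structure."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    number: int            # author residue number
    icode: str             # insertion code, '' if none
    name: str              # 3-letter residue name
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def ca(self) -> Atom | None:
        return self.atoms.get("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"residue {number}{icode} not in chain {self.id}")


@dataclass
class HetGroup:
    """A non-polymer group (ligand, ion, water) kept outside the chains."""

    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    het_groups: list[HetGroup] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        avail = ", ".join(c.id for c in self.chains) or "<none>"
        raise KeyError(f"chain {chain_id!r} not in structure {self.id} (available: {avail})")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclass
class CaTrace:
    """Ordered C-alpha trace of one chain: the carrier of per-residue RMSD."""

    structure_id: str
    chain_id: str
    residue_numbers: list[int]
    icodes: list[str]
    residue_names: list[str]
    coords: np.ndarray            # (n, 3) Angstrom
    gaps: list[tuple[int, str]] = field(default_factory=list)  # residues lacking CA

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.residue_numbers)
        if not (len(self.icodes) == len(self.residue_names) == self.coords.shape[0] == n):
            raise ValueError("CaTrace fields must have equal length")
        keys = list(zip(self.residue_numbers, self.icodes))
        if any(keys[i] >= keys[i + 1] for i in range(n - 1)):
            raise ValueError("CaTrace residues must be strictly increasing in (number, icode)")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def label(self) -> str:
        return f"{self.structure_id}:{self.chain_id}"

    def one_letter_sequence(self) -> str:
        return "".join(_AA3TO1.get(n, "X") for n in self.residue_names)


@dataclass
class ResidueCorrespondence:
    """Paired indices between two CaTraces (strictly increasing in both)."""

    pairs: list[tuple[int, int]]
    method: str  # "number-match" | "alignment-fallback"

    def __post_init__(self) -> None:
        for k in range(len(self.pairs) - 1):
            i0, j0 = self.pairs[k]
            i1, j1 = self.pairs[k + 1]
            if not (i0 < i1 and j0 < j1):
                raise ValueError("correspondence pairs must be strictly increasing in both traces")

    def __len__(self) -> int:
        return len(self.pairs)

    def coords(self, a: CaTrace, b: CaTrace) -> tuple[np.ndarray, np.ndarray]:
        ia = [i for i, _ in self.pairs]
        jb = [j for _, j in self.pairs]
        return a.coords[ia], b.coords[jb]


# ---------------------------------------------------------------------------
# parsing


def _resolve_altlocs(atoms: list[Atom]) -> Atom:
    """Pick one atom among altloc variants: highest occupancy, tie -> 'A'."""
    if len(atoms) == 1:
        return atoms[0]
    return max(atoms, key=lambda a: (a.occupancy, a.altloc in ("", "A")))


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read; het groups and waters are separated from
    the polymer chains; altlocs are resolved to a single atom per
    (residue, atom name).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureParseError(f"{structure_id}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{structure_id}: no ATOM records found")
    if len(st) > 1:
        logger.info("%s: %d models present, using the first", structure_id, len(st))
    model = st[0]

    out = Structure(id=structure_id)
    n_atom_records = 0
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            # group altloc variants by atom name
            by_name: dict[str, list[Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                    )
                )
            resolved = {name: _resolve_altlocs(v) for name, v in by_name.items()}
            is_het = gres.het_flag == "H"
            if is_het:
                out.het_groups.append(
                    HetGroup(
                        chain_id=gchain.name,
                        number=gres.seqid.num,
                        name=gres.name,
                        atoms=list(resolved.values()),
                    )
                )
            else:
                n_atom_records += len(resolved)
                chain.residues.append(
                    Residue(
                        number=gres.seqid.num,
                        icode=gres.seqid.icode.strip(),
                        name=gres.name,
                        atoms=resolved,
                    )
                )
        if chain.residues:
            out.chains.append(chain)
    if n_atom_records == 0:
        raise StructureParseError(f"{structure_id}: no ATOM records found")
    return out


def parse_structure_file(path, structure_id: str | None = None) -> Structure:
    from pathlib import Path

    path = Path(path)
    return parse_structure(path.read_text(), structure_id or path.stem)


# ---------------------------------------------------------------------------
# C-alpha traces and residue correspondence


def extract_ca_trace(structure: Structure, chain_id: str) -> CaTrace:
    """Extract the ordered C-alpha trace of one chain.

    Residues lacking a C-alpha are omitted and reported in ``gaps``.
    """
    chain = structure.chain(chain_id)
    numbers, icodes, names, coords, gaps = [], [], [], [], []
    for res in chain.residues:
        ca = res.ca
        if ca is None:
            gaps.append((res.number, res.icode))
            continue
        numbers.append(res.number)
        icodes.append(res.icode)
        names.append(res.name)
        coords.append(ca.coord)
    if gaps:
        logger.warning(
            "%s:%s: %d residue(s) lack a C-alpha and were omitted",
            structure.id, chain_id, len(gaps),
        )
    return CaTrace(
        structure_id=structure.id,
        chain_id=chain_id,
        residue_numbers=numbers,
        icodes=icodes,
        residue_names=names,
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        gaps=gaps,
    )


def _align_fallback(a: CaTrace, b: CaTrace) -> list[tuple[int, int]]:
    """Global sequence alignment (identity scoring, affine gaps); pair
    aligned identical residues."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.one_letter_sequence(), b.one_letter_sequence())[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a.residue_names[i] == b.residue_names[j]:
                pairs.append((i, j))
    return pairs


def map_common_residues(a: CaTrace, b: CaTrace) -> ResidueCorrespondence:
    """Pair residues of two traces.

    Primary strategy: identical author number + insertion code with
    agreeing residue names.  If fewer than half of the shorter trace pairs
    this way, fall back to global sequence alignment and pair aligned
    identical residues.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot map residues: empty trace")
    index_b = {(n, ic): j for j, (n, ic) in enumerate(zip(b.residue_numbers, b.icodes))}
    pairs = []
    for i, key in enumerate(zip(a.residue_numbers, a.icodes)):
        j = index_b.get(key)
        if j is not None and a.residue_names[i] == b.residue_names[j]:
            pairs.append((i, j))
    method = "number-match"
    if len(pairs) < 0.5 * min(len(a), len(b)):
        pairs = _align_fallback(a, b)
        method = "alignment-fallback"
    if not pairs:
        raise ValueError(f"no common residues between {a.label} and {b.label}")
    return ResidueCorrespondence(pairs=pairs, method=method)


# ---------------------------------------------------------------------------
# writing


def _format_atom_line(record: str, serial: int, atom: Atom, res_name: str,
                      chain_id: str, res_num: int, icode: str) -> str:
    name = atom.name
    # PDB column rules: 1-3 char names start in column 14 unless 4 chars
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coord
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{res_name:>3} {chain_id:1}"
        f"{res_num:>4}{icode or '':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2}"
    )


def write_structure(structure: Structure) -> str:
    """Serialize a Structure to fixed-column PDB text (coords to 3 decimals)."""
    lines = [f"HEADER    {structure.id}"]
    serial = 0
    if structure.n_atoms == 0 and not structure.het_groups:
        warnings.warn(f"writing empty structure {structure.id}", stacklevel=2)
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                serial += 1
                lines.append(
                    _format_atom_line("ATOM", serial, atom, res.name,
                                      chain.id, res.number, res.icode)
                )
        serial += 1
        lines.append(f"TER   {serial:>5}")
    for het in structure.het_groups:
        for atom in het.atoms:
            serial += 1
            lines.append(
                _format_atom_line("HETATM", serial, atom, het.name,
                                  het.chain_id, het.number, "")
            )
    lines.append("END")
    return "\n".join(lines) + "\n"
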