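"""Ensemble docking orchestration with a pluggable engine contract.

One ligand is docked repeatedly against every conformer of an ensemble;
the best (lowest, kcal/mol) score of each run is recorded and aggregated
into per-conformer mean +/- SD and a pooled distribution.  The engine is
a contract: an external AutoDock-Vina-style executable can be plugged in
through :class:`VinaDockingEngine`, and :class:`MockDockingEngine`
provides a deterministic, dependency-free engine so the orchestration and
aggregation layers are fully testable.

The mock engine samples rigid-body placements of the ligand inside the
docking box from a seeded RNG and scores each placement with a step
potential over protein-ligand heavy-atom pair distances d:

    f(d) = +10.0   d < 2.0 A      (steric clash)
           -0.1    2.0 <= d <= 4.0 A  (favourable contact)
            0.0    otherwise

Seed schedule: run (conformer c, repeat r) uses
``(base_seed + crc32("c|r")) % 2**31`` — deterministic, documented, and
disjoint across runs for all practical ensembles.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .interaction_analysis import DockingBox, LigandPose
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredPose",
    "AffinityRecord",
    "AffinityTable",
    "MockDockingEngine",
    "VinaDockingEngine",
    "EngineConfigurationError",
    "EngineRunError",
    "EngineOutputError",
    "run_seed",
    "ensemble_dock",
    "affinity_histogram",
    "score_mock_pose",
    "write_pdbqt",
    "write_ligand_pdbqt",
    "parse_vina_output",
]


class EngineConfigurationError(RuntimeError):
    """The engine is not usable as configured (e.g. missing executable)."""


class EngineRunError(RuntimeError):
    """The engine started but exited abnormally."""


class EngineOutputError(RuntimeError):
    """The engine produced output that could not be parsed."""


@dataclass
class ScoredPose:
    score: float  # kcal/mol, lower is better
    pose: LigandPose


@dataclass
class AffinityRecord:
    conformer_id: str
    repeat: int          # 1-based
    score: float         # best score of the run, kcal/mol
    pose: LigandPose | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("affinity score must be finite")
        if self.repeat < 1:
            raise ValueError("repeat index is 1-based")


@dataclass
class AffinityTable:
    """Per-run best scores with per-conformer and pooled aggregation.

    SD is the sample standard deviation (ddof = 1), the convention for
    reporting "mean docking energy +/- SD" over repeated runs.
    """

    records: list[AffinityRecord]
    n_repeats: int
    failures: list[tuple[str, int, str]] = field(default_factory=list)

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conformer": [r.conformer_id for r in self.records],
                "repeat": [r.repeat for r in self.records],
                "score_kcal_mol": self.scores(),
            }
        )

    def per_conformer(self) -> pd.DataFrame:
        df = self.to_dataframe()
        agg = df.groupby("conformer", sort=True)["score_kcal_mol"].agg(
            mean="mean", sd=lambda s: s.std(ddof=1), n="count"
        )
        return agg.reset_index()

    @property
    def pooled_mean(self) -> float:
        return float(self.scores().mean())

    @property
    def pooled_sd(self) -> float:
        s = self.scores()
        return float(s.std(ddof=1)) if len(s) > 1 else 0.0

    @property
    def pooled_n(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# mock engine


def _structure_heavy_coords(structure: Structure) -> np.ndarray:
    coords = [
        atom.coord
        for chain in structure.chains
        for res in chain.residues
        for atom in res.atoms.values()
        if atom.element.upper() != "H"
    ]
    return np.array(coords, dtype=float).reshape(-1, 3)


def score_mock_pose(protein_coords: np.ndarray, ligand_coords: np.ndarray,
                    tree: cKDTree | None = None) -> float:
    """Step-potential score of one placement (see module docstring)."""
    if tree is None:
        tree = cKDTree(protein_coords)
    pairs = tree.query_ball_point(ligand_coords, r=4.0)
    score = 0.0
    for lig_idx, prot_idxs in enumerate(pairs):
        if not prot_idxs:
            continue
        d = np.linalg.norm(protein_coords[prot_idxs] - ligand_coords[lig_idx], axis=1)
        score += 10.0 * np.sum(d < 2.0) - 0.1 * np.sum(d >= 2.0)
    return float(score)


@dataclass
class MockDockingEngine:
    """Deterministic rigid-body sampling engine over the step potential.

    ``mode="random"`` samples ``n_samples`` random rotations+translations
    inside the box; ``mode="grid"`` enumerates an axis-aligned
    translational grid (``grid_step`` A) with no rotation.
    """

    n_samples: int = 500
    mode: str = "random"
    grid_step: float = 0.5
    keep_poses: int = 1

    name: str = "mock"
    deterministic: bool = True

    def dock(self, receptor: Structure, ligand: LigandPose, box: DockingBox,
             seed: int) -> list[ScoredPose]:
        prot = _structure_heavy_coords(receptor)
        heavy = ligand.heavy_mask()
        lig = ligand.coords[heavy]
        centroid = lig.mean(axis=0)
        lig0 = lig - centroid
        radius = float(np.linalg.norm(lig0, axis=1).max()) if len(lig0) else 0.0
        if 2 * radius > box.edge:
            raise ValueError(
                f"ligand diameter {2 * radius:.1f} A exceeds box edge {box.edge:.1f} A"
            )
        lo = box.lo + radius
        hi = box.hi - radius

        placements: list[np.ndarray] = []
        if self.mode == "grid":
            axes = [np.arange(lo[k], hi[k] + 1e-9, self.grid_step) for k in range(3)]
            for x in axes[0]:
                for y in axes[1]:
                    for z in axes[2]:
                        placements.append(lig0 + np.array([x, y, z]))
        elif self.mode == "random":
            rng = np.random.default_rng(seed)
            centers = rng.uniform(lo, hi, size=(self.n_samples, 3))
            rots = Rotation.random(self.n_samples, random_state=np.random.RandomState(seed))
            for rot, c in zip(rots, centers):
                placements.append(rot.apply(lig0) + c)
        else:
            raise EngineConfigurationError(f"unknown mock engine mode {self.mode!r}")

        tree = cKDTree(prot)
        scored = sorted(
            (score_mock_pose(prot, placed, tree=tree), k)
            for k, placed in enumerate(placements)
        )
        elements = [e for e, h in zip(ligand.elements, heavy) if h]
        out = []
        for rank, (score, k) in enumerate(scored[: max(self.keep_poses, 1)]):
            out.append(
                ScoredPose(
                    score=score,
                    pose=LigandPose(
                        pose_id=f"{receptor.id}:s{seed}:r{rank}",
                        conformer_id=receptor.id,
                        coords=placements[k],
                        elements=elements,
                    ),
                )
            )
        return out


# ---------------------------------------------------------------------------
# external (Vina-style) engine


def write_pdbqt(structure: Structure) -> str:
    """Minimal rigid-receptor PDBQT (zero partial charges, element as AD type)."""
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                serial += 1
                x, y, z = atom.coord
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
                lines.append(
                    f"ATOM  {serial:>5} {name}{'':1}{res.name:>3} {chain.id:1}"
                    f"{res.number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"    {0.0:6.3f} {atom.element:<2}"
                )
    return "\n".join(lines) + "\n"


def write_ligand_pdbqt(pose: LigandPose) -> str:
    """Rigid-ligand PDBQT block (ROOT/ENDROOT, no torsion tree)."""
    lines = ["ROOT"]
    for i, (el, xyz) in enumerate(zip(pose.elements, pose.coords), start=1):
        x, y, z = xyz
        name = f"{el}{i}"
        lines.append(
            f"ATOM  {i:>5} {name:<4}{'':1}LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    {0.0:6.3f} {el:<2}"
        )
    lines += ["ENDROOT", "TORSDOF 0"]
    return "\n".join(lines) + "\n"


def parse_vina_output(text: str) -> list[tuple[int, float]]:
    """Parse the Vina result table: (mode, affinity kcal/mol), best first.

    Accepts the standard stdout table whose rows look like
    ``   1       -6.0      0.000      0.000``.
    """
    rows: list[tuple[int, float]] = []
    in_table = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("-----"):
            in_table = True
            continue
        if not in_table or not stripped:
            continue
        parts = stripped.split()
        if len(parts) >= 2 and parts[0].isdigit():
            try:
                rows.append((int(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise EngineOutputError(f"unparseable result row: {line!r}") from exc
        elif rows:
            break
    if not rows:
        raise EngineOutputError("no result table found in engine output")
    return rows


@dataclass
class VinaDockingEngine:
    """Adapter for an AutoDock-Vina-compatible executable.

    Receptor preparation (hydrogens, charges) is the user's
    responsibility; coordinates are passed through unmodified.  Failures
    raise distinct errors — the mock engine is never silently substituted.
    """

    executable: str = "vina"
    exhaustiveness: int | None = None
    name: str = "vina"
    deterministic: bool = False

    def dock(self, receptor: Structure, ligand: LigandPose, box: DockingBox,
             seed: int) -> list[ScoredPose]:
        exe = shutil.which(self.executable)
        if exe is None:
            raise EngineConfigurationError(
                f"docking executable not found: {self.executable!r}"
            )
        with tempfile.TemporaryDirectory(prefix="flexidock_") as tmp:
            tmpdir = Path(tmp)
            rec = tmpdir / "receptor.pdbqt"
            lig = tmpdir / "ligand.pdbqt"
            out = tmpdir / "out.pdbqt"
            rec.write_text(write_pdbqt(receptor))
            lig.write_text(write_ligand_pdbqt(ligand))
            cx, cy, cz = box.center
            cmd = [
                exe, "--receptor", str(rec), "--ligand", str(lig),
                "--center_x", f"{cx:.3f}", "--center_y", f"{cy:.3f}",
                "--center_z", f"{cz:.3f}",
                "--size_x", f"{box.edge:.1f}", "--size_y", f"{box.edge:.1f}",
                "--size_z", f"{box.edge:.1f}",
                "--seed", str(seed), "--out", str(out),
            ]
            if self.exhaustiveness is not None:
                cmd += ["--exhaustiveness", str(self.exhaustiveness)]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise EngineRunError(
                    f"engine exited with code {proc.returncode}: {proc.stderr[:500]}"
                )
            rows = parse_vina_output(proc.stdout)
        return [
            ScoredPose(
                score=aff,
                pose=LigandPose(
                    pose_id=f"{receptor.id}:mode{mode}",
                    conformer_id=receptor.id,
                    coords=ligand.coords,
                    elements=list(ligand.elements),
                ),
            )
            for mode, aff in rows
        ]


# ---------------------------------------------------------------------------
# orchestration


def run_seed(base_seed: int, conformer_id: str, repeat: int) -> int:
    """Deterministic per-run seed: (base + crc32('conformer|repeat')) mod 2^31."""
    return (base_seed + zlib.crc32(f"{conformer_id}|{repeat}".encode())) % (2**31)


def ensemble_dock(
    ensemble: list[Structure],
    ligand: LigandPose,
    box_spec: DockingBox | dict[str, DockingBox],
    engine,
    n_repeats: int = 100,
    base_seed: int = 0,
    keep_poses: bool = False,
) -> AffinityTable:
    """Dock one ligand against every conformer with repeats.

    The best (lowest) score of each run is recorded.  Single failed runs
    are skipped with a warning; more than 10% failures aborts.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    records: list[AffinityRecord] = []
    failures: list[tuple[str, int, str]] = []
    total = len(ensemble) * n_repeats
    for receptor in ensemble:
        box = box_spec[receptor.id] if isinstance(box_spec, dict) else box_spec
        for repeat in range(1, n_repeats + 1):
            seed = run_seed(base_seed, receptor.id, repeat)
            try:
                poses = engine.dock(receptor, ligand, box, seed)
                if not poses:
                    raise EngineOutputError("engine returned no poses")
            except (EngineRunError, EngineOutputError) as exc:
                logger.warning("run (%s, %d) failed: %s", receptor.id, repeat, exc)
                failures.append((receptor.id, repeat, str(exc)))
                if len(failures) > 0.10 * total:
                    raise RuntimeError(
                        f"aborting: {len(failures)} of {total} docking runs failed"
                    ) from exc
                continue
            best = min(poses, key=lambda p: p.score)
            records.append(
                AffinityRecord(
                    conformer_id=receptor.id,
                    repeat=repeat,
                    score=best.score,
                    pose=best.pose if keep_poses else None,
                )
            )
    return AffinityTable(records=records, n_repeats=n_repeats, failures=failures)


def affinity_histogram(table: AffinityTable, bin_width: float = 0.1) -> pd.DataFrame:
    """Relative-frequency histogram of all best scores, in percent.

    Bins are aligned to multiples of ``bin_width``; frequencies sum to 100.
    """
    scores = table.scores()
    if scores.size == 0:
        raise ValueError("affinity table is empty")
    lo = np.floor(scores.min() / bin_width) * bin_width
    hi = np.ceil(scores.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(scores, bins=edges)
    freq = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "frequency_pct": freq,
        }
    )
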