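# Methods

This note documents the models, conventions and numerical choices behind
flexidock, and what the synthetic-data generator does and does not
emulate.

## Structures and residue correspondence

PDB input is parsed with gemmi; flexidock then applies three policies
suited to ensemble analysis of crystal structures:

* **first MODEL only** — the workflow targets crystal structures, where
  multiple models are rare and alternatives are not independent
  conformers in the ensemble sense;
* **altloc resolution** — one conformation per residue: the highest
  occupancy wins, ties go to altloc `A`. This keeps every downstream
  quantity deterministic;
* **het/water separation** — waters and het groups never enter the
  polymer chains or C-alpha traces; they are retained in a separate
  block so ligands remain available to interaction analysis.

Residues of two conformers are paired by author number + insertion code
where residue names agree. If fewer than half of the shorter trace pairs
this way (renumbered entries, construct differences), the mapper falls
back to global sequence alignment (identity scoring, affine gaps:
match +1, mismatch −1, open −5, extend −0.5, via Biopython's
`PairwiseAligner`) and pairs aligned identical residues. The method used
is recorded on the correspondence. Because each conformer pair is mapped
on its own common-residue set, cells of the RMSD matrix can rest on
slightly different atom counts; the counts are kept alongside the
matrix.

## Superposition and the mobility Z-score

Pairwise superposition is the Kabsch algorithm: SVD of the covariance
matrix of the centred coordinate sets, with the reflection branch
corrected through the sign of det(V·Uᵀ) so the result is always a proper
rotation (det = +1 within 1e-9). Near-collinear inputs are flagged with
a warning but still solved. The minimized C-alpha RMSD over all pairs
gives the ensemble's RMSD matrix; the maximum-diversity pair is the
arg-max over the strict upper triangle, with ties broken
lexicographically by conformer id so reruns are stable.

Per-residue displacements d_i for the maximum pair use **one global
superposition** over all common C-alphas — not windowed or local fits —
because the question is where a residue sits in the whole-molecule
mobility distribution, not its local flexibility. Standardization uses
the **population** SD (ddof = 0): the profile is a descriptive
standardization of a fixed, fully observed residue set, not an estimate
from a sample. Degenerate profiles (all d_i equal, SD = 0) set all
z-scores to 0 with a warning rather than dividing by zero.

A binding site is called a "low-mobility site" only when **every**
present site residue has z < 0; the fraction below zero is always
reported so callers can apply softer judgements. Site residues missing
from the profile are reported, not fatal.

## Ensemble docking

The orchestration layer is engine-agnostic. A run (conformer c, repeat
r) receives the seed `(base_seed + crc32("c|r")) mod 2^31`; the schedule
is deterministic, documented, and collision-free for all practical
ensemble sizes (verified disjoint for 10 conformers × 100 repeats in the
suite). The **best** (lowest, kcal/mol) score of each run enters the
affinity table — the standard per-run statistic in docking practice.
Aggregation reports per-conformer mean ± sample SD (ddof = 1; the
convention for "mean ± SD" over repeated experiments) and the pooled
distribution as a relative-frequency histogram whose bins are aligned to
multiples of the bin width and whose frequencies sum to 100%.

Single failed runs are recorded and skipped; more than 10% failures
aborts the run, since a heavily censored affinity table silently biases
the mean.

The **mock engine** samples rigid-body placements (uniform centroid
inside the box shrunk by the ligand's bounding radius, uniform random
rotation) from the run's seed and scores each placement with a step
potential over protein–ligand heavy-atom pair distances d: +10 for
d < 2 Å (clash), −0.1 for 2 ≤ d ≤ 4 Å (favourable contact), 0 beyond.
This is deliberately not a physical scoring function: it exists to make
the orchestration, seeding, aggregation and reporting fully testable,
with an exhaustive-grid mode (translations only) that an independent
brute-force scorer can verify exactly. Ligands larger than the box are
rejected.

The **external adapter** writes receptor and ligand in rigid PDBQT,
invokes an AutoDock-Vina-compatible executable with box centre/size and
seed, and parses the standard result table. Receptor preparation
(hydrogens, charges) is the user's responsibility — preparation
pipelines vary too much to hide behind a default. Missing executables,
abnormal exits and unparseable output raise distinct errors; the mock
engine is never silently substituted. Published absolute docking
energies are not reproduction targets for any engine: they depend on
engine version, receptor preparation and the stochastic search.

## Pose comparison

Poses docked to different conformers are compared in the
**receptor-aligned frame**: the rigid fit that superposes conformer B
onto conformer A is applied to pose B, then the heavy-atom RMSD is taken
**without re-fitting the ligand**. This measures displacement of the
binding mode; a ligand-refit variant (flag) measures internal geometry
instead. Per-substructure RMSD uses the same frame, and when the named
groups partition the heavy atoms the overall RMSD satisfies
`overall² = Σ n_g·RMSD_g² / Σ n_g` exactly — an algebraic identity the
suite checks to 1e-9 as a guard against mapping bugs.

Contacts are residues with any heavy-atom pair within the cutoff
(default 4.0 Å, configurable; 2D interaction diagrams in the literature
rarely state their criterion). Hydrogen bonds use donor/acceptor
heavy-atom distance ≤ 3.5 Å and, when an explicit hydrogen is bonded to
the donor (within 1.25 Å), a D–H···A angle ≥ 120°; without hydrogens —
the normal case for crystal structures — the distance-only criterion is
applied and flagged on the result. Protein donors/acceptors are typed by
atom name against standard backbone and side-chain tables; ligand N/O
atoms with unknown hydrogen counts are treated as donor-capable, which
errs toward sensitivity in the flagged distance-only mode.

## Drug-likeness conventions

* **MW**: standard atomic weights summed over all atoms including
  implicit hydrogens.
* **HBD**: N/O heavy atoms bearing ≥ 1 hydrogen; **HBA**: N + O count —
  the original Lipinski conventions (donor counts heavy atoms, not
  hydrogens).
* **Rotatable bonds**: single, non-ring bonds between two non-terminal
  heavy atoms, excluding *amide-like* C–N bonds — C–N single bonds whose
  carbon is double-bonded to O **or** N. Amidines and guanidines share
  the amide's partial double-bond character, so their C–N bonds are not
  freely rotatable; counting them would overstate flexibility. Note
  that common toolkit defaults differ in both directions on such
  molecules (some also exclude aryl–CX₃ bonds), which is why the
  convention is spelled out here and cross-checked against an
  independent implementation only where the definitions coincide.
* **TPSA**: Ertl fragment contributions over N/O environments (via
  RDKit); **logP**: Crippen atomic contributions, with the method tag
  recorded in every profile because predicted logP varies strongly
  across methods — logP is deliberately not pinned to any published
  value.
* Verdicts: Lipinski pass iff MW ≤ 500 ∧ logP ≤ 5 ∧ HBD ≤ 5 ∧ HBA ≤ 10;
  Veber pass iff rotatable ≤ 10 ∧ TPSA ≤ 140 Å². Both are recomputable
  from the stored fields.

The bundled 1A-116 encoding is the tautomer with one =N–aryl, one N–H
and one NH₂ on the guanidine/amidine core
(`NC(Nc1cc(C)cc(C)c1)=Nc1ccccc1C(F)(F)F`, C₁₆H₁₆F₃N₃): this is the
tautomer whose Ertl environments reproduce the published polar surface
area, and its panel (MW 307.32, HBD 2, HBA 3, rotatable 3, TPSA 50.41)
matches the published values. Substructure labels follow the convention
ring A = 2-trifluoromethylphenyl (CF₃ included), ring B =
3,5-dimethylphenyl (methyls included), guanidine = the three N plus
central C; the three groups partition the 22 heavy atoms.

## Synthetic-data generator

`generate_ensemble` emulates the statistical structure that ensemble
analysis assumes in real crystal collections: one chain observed many
times with heterogeneous per-residue mobility, each copy in an arbitrary
frame. The base chain is a self-avoiding random C-alpha walk (3.8 Å
consecutive spacing, ≥ 3.8 Å non-consecutive separation); conformer c is
`base + N(0, (scale_c·σ_i)²)` iid per coordinate, then a random rigid
transform. Isotropic Gaussian displacement is the simplest model with
controllable per-residue mobility; it reproduces the Maxwell expectation
E|Δ| per mobility class (checked in the suite). The optional
per-conformer scale makes the expected maximum-diversity pair known by
construction (the pair maximizing scale_i² + scale_j²).

What it does **not** emulate: correlated/hinge or domain motions,
crystal-contact artefacts, sequence variation between entries, missing
loops, side chains (chains are CA-only, ALA with TRP at the designated
site residue). Passing tests therefore demonstrate that the statistics
and plumbing are correct under the stated noise model — not that any
particular real protein is rigid where the generator says so.

`generate_complex` lays the chain out straight and plants ligand atoms
perpendicular to it, so each planted atom is within its stated distance
of exactly one residue (the neighbouring C-alpha is already
√(3.8² + d²) away); the planted H-bond solves the D–H···A triangle
exactly (donor at the given heavy-atom distance, H at 1.0 Å from the
donor at the given angle). A clearance check (default 4.5 Å) rejects
specs whose geometry would create accidental contacts.

Study-scale choices in the analysis scripts: 10 conformers × 100
residues, core σ 0.15 Å, loop σ 1.0 Å, two conformers at 2× scale —
chosen so the maximum-pair RMSD lands in the low-Ångström range typical
of real ensembles of well-ordered globular proteins. Test and
acceptance runs use smaller ensembles (40–60 residues, 5–6 conformers)
and 100–200 mock-engine samples per run; these sizes keep the full
recovery battery comfortably reproducible on a single CPU while leaving
the measured properties (recovery rates, identities, determinism)
unchanged.

For the σ-recovery check, the mobility profile is graded over six levels
(0.1–2.0 Å): with only two or three levels, rank ties in σ alone bound
the Spearman correlation well below 1, making the statistic
uninformative regardless of implementation quality.

## Known limitations

* The mock engine's step potential has no physical meaning; affinities
  from it are comparable only to themselves.
* H-bond detection without hydrogens cannot distinguish donors from
  acceptors on ambiguous atoms (His, Ser/Thr/Tyr OH); results in
  distance-only mode are flagged accordingly.
* mmCIF input, assemblies/symmetry expansion and flexible-receptor
  docking are out of scope; chain choice for multi-chain entries is the
  user's.
* The residue correspondence assumes globally alignable sequences;
  circular permutants or heavy engineering would defeat both pairing
  strategies.
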