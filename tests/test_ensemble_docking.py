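"""Mock engine, external-engine adapter, orchestration and aggregation."""

import numpy as np
import pytest

from flexidock.ensemble_docking import (
    AffinityRecord,
    EngineConfigurationError,
    EngineOutputError,
    MockDockingEngine,
    VinaDockingEngine,
    affinity_histogram,
    AffinityTable,
    ensemble_dock,
    parse_vina_output,
    run_seed,
    score_mock_pose,
    write_ligand_pdbqt,
    write_pdbqt,
)
from flexidock.interaction_analysis import DockingBox, LigandPose, make_docking_box
from flexidock.synthetic_data import EnsembleSpec, generate_ensemble
from oracles import grid_best_score, step_potential_score


def small_receptors(n=2, seed=4):
    structures, _ = generate_ensemble(
        EnsembleSpec(n_residues=30, n_conformers=n, sigma=0.3, seed=seed)
    )
    return structures


def tri_ligand():
    return LigandPose(
        pose_id="lig", conformer_id="",
        coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]]),
        elements=["C", "C", "N"],
    )


class ConstantEngine:
    """Test double returning a fixed score regardless of input."""

    name = "const"
    deterministic = True

    def __init__(self, score=-6.0):
        self.score = score

    def dock(self, receptor, ligand, box, seed):
        from flexidock.ensemble_docking import ScoredPose

        return [ScoredPose(score=self.score, pose=ligand)]


class SequenceEngine:
    """Test double yielding a fixed score per (conformer, repeat) call order."""

    name = "seq"
    deterministic = True

    def __init__(self, scores):
        self.scores = list(scores)
        self.calls = 0

    def dock(self, receptor, ligand, box, seed):
        from flexidock.ensemble_docking import ScoredPose

        s = self.scores[self.calls % len(self.scores)]
        self.calls += 1
        return [ScoredPose(score=s, pose=ligand)]


class FailingEngine:
    name = "fail"
    deterministic = True

    def __init__(self, fail_every=3):
        self.fail_every = fail_every
        self.calls = 0

    def dock(self, receptor, ligand, box, seed):
        from flexidock.ensemble_docking import ScoredPose

        self.calls += 1
        if self.calls % self.fail_every == 0:
            raise EngineOutputError("synthetic failure")
        return [ScoredPose(score=-5.0, pose=ligand)]


class TestMockEngine:
    def test_same_seed_identical_scores(self):
        (receptor,) = small_receptors(n=1)
        box = make_docking_box(receptor, "A", 15, edge=14.0)
        eng = MockDockingEngine(n_samples=40, keep_poses=5)
        s1 = [p.score for p in eng.dock(receptor, tri_ligand(), box, seed=11)]
        s2 = [p.score for p in eng.dock(receptor, tri_ligand(), box, seed=11)]
        assert s1 == s2

    def test_clash_scores_worse(self):
        (receptor,) = small_receptors(n=1)
        ca = receptor.chains[0].residues[14].atoms["CA"].coord
        lig = tri_ligand()
        clashed = lig.coords + (ca - lig.coords[0]) + np.array([1.5, 0.0, 0.0])
        clear = lig.coords + (ca - lig.coords[0]) + np.array([3.0, 0.0, 0.0])
        prot = np.array([a.coord for c in receptor.chains for r in c.residues
                         for a in r.atoms.values()])
        assert score_mock_pose(prot, clashed) > score_mock_pose(prot, clear)

    def test_grid_mode_matches_brute_force_oracle(self):
        (receptor,) = small_receptors(n=1)
        box = make_docking_box(receptor, "A", 15, edge=8.0)
        eng = MockDockingEngine(mode="grid", grid_step=1.0)
        best = eng.dock(receptor, tri_ligand(), box, seed=0)[0].score
        prot = np.array([a.coord for c in receptor.chains for r in c.residues
                         for a in r.atoms.values()])
        lig = tri_ligand().coords
        radius = np.max(np.linalg.norm(lig - lig.mean(axis=0), axis=1))
        oracle = grid_best_score(prot, lig, box.lo + radius, box.hi - radius, step=1.0)
        assert best == pytest.approx(oracle, abs=1e-9)

    def test_score_matches_plain_loop_scorer(self, rng):
        prot = rng.normal(scale=4.0, size=(25, 3))
        lig = rng.normal(scale=2.0, size=(4, 3))
        assert score_mock_pose(prot, lig) == pytest.approx(
            step_potential_score(prot, lig), abs=1e-9
        )

    def test_ligand_larger_than_box(self):
        (receptor,) = small_receptors(n=1)
        box = DockingBox(center=np.zeros(3), edge=3.0)
        big = LigandPose(pose_id="big", conformer_id="",
                         coords=np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]),
                         elements=["C", "C"])
        with pytest.raises(ValueError, match="exceeds box"):
            MockDockingEngine(n_samples=5).dock(receptor, big, box, seed=0)


class TestOrchestration:
    def test_constant_engine_aggregation(self):
        structures = small_receptors(n=3)
        table = ensemble_dock(structures, tri_ligand(), DockingBox(np.zeros(3), 14.0),
                              ConstantEngine(-6.0), n_repeats=4, base_seed=0)
        per = table.per_conformer()
        assert list(per["mean"]) == [-6.0, -6.0, -6.0]
        assert list(per["sd"]) == [0.0, 0.0, 0.0]
        assert table.pooled_mean == -6.0

    def test_hand_computed_mean_and_sample_sd(self):
        (receptor,) = small_receptors(n=1)
        table = ensemble_dock([receptor], tri_ligand(), DockingBox(np.zeros(3), 14.0),
                              SequenceEngine([-5.0, -6.0, -7.0]), n_repeats=3, base_seed=0)
        per = table.per_conformer()
        assert per["mean"][0] == pytest.approx(-6.0)
        assert per["sd"][0] == pytest.approx(1.0)  # sample SD, ddof=1

    def test_rerun_reproduces_table_exactly(self):
        structures = small_receptors(n=3, seed=8)
        boxes = {s.id: make_docking_box(s, "A", 15, edge=14.0) for s in structures}
        eng = MockDockingEngine(n_samples=30)
        t1 = ensemble_dock(structures, tri_ligand(), boxes, eng, n_repeats=5, base_seed=42)
        t2 = ensemble_dock(structures, tri_ligand(), boxes, eng, n_repeats=5, base_seed=42)
        assert np.array_equal(t1.scores(), t2.scores())

    def test_pooled_scores_equal_per_run_outputs(self):
        structures = small_receptors(n=2)
        scores = [-4.0, -5.5, -6.25, -3.5]
        eng = SequenceEngine(scores)
        table = ensemble_dock(structures, tri_ligand(), DockingBox(np.zeros(3), 14.0),
                              eng, n_repeats=2, base_seed=0)
        assert sorted(table.scores()) == sorted(scores)

    def test_seed_schedule_disjoint(self):
        seeds = {run_seed(7, f"C{c}", r) for c in range(10) for r in range(1, 101)}
        assert len(seeds) == 1000
        assert all(0 <= s < 2**31 for s in seeds)

    def test_isolated_failures_skipped_with_record(self):
        structures = small_receptors(n=1)
        table = ensemble_dock(structures, tri_ligand(), DockingBox(np.zeros(3), 14.0),
                              FailingEngine(fail_every=20), n_repeats=20, base_seed=0)
        assert len(table.failures) == 1
        assert table.pooled_n == 19

    def test_excess_failures_abort(self):
        structures = small_receptors(n=1)
        with pytest.raises(RuntimeError, match="aborting"):
            ensemble_dock(structures, tri_ligand(), DockingBox(np.zeros(3), 14.0),
                          FailingEngine(fail_every=2), n_repeats=20, base_seed=0)


class TestAggregationNumerics:
    def _table(self, rng, n=400):
        scores = rng.normal(-6.0, 0.3, size=n)
        records = [AffinityRecord(conformer_id=f"C{i % 4}", repeat=i // 4 + 1,
                                  score=float(s)) for i, s in enumerate(scores)]
        return AffinityTable(records=records, n_repeats=n // 4)

    def test_streaming_equals_two_pass(self, rng):
        """Welford streaming moments agree with the two-pass computation."""
        table = self._table(rng)
        scores = table.scores()
        mean = 0.0
        m2 = 0.0
        for k, x in enumerate(scores, start=1):
            delta = x - mean
            mean += delta / k
            m2 += delta * (x - mean)
        stream_sd = np.sqrt(m2 / (len(scores) - 1))
        assert table.pooled_mean == pytest.approx(mean, abs=1e-12)
        assert table.pooled_sd == pytest.approx(stream_sd, abs=1e-12)

    def test_histogram_sums_to_100(self, rng):
        hist = affinity_histogram(self._table(rng), bin_width=0.1)
        assert hist["frequency_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_histogram_matches_hand_binning(self, rng):
        table = self._table(rng, n=1000)
        width = 0.25
        hist = affinity_histogram(table, bin_width=width)
        scores = table.scores()
        for _, row in hist.iterrows():
            left, right = row["bin_left"], row["bin_right"]
            is_last = row.name == len(hist) - 1
            if is_last:
                n = np.sum((scores >= left - 1e-12) & (scores <= right + 1e-12))
            else:
                n = np.sum((scores >= left - 1e-12) & (scores < right - 1e-12))
            assert row["frequency_pct"] == pytest.approx(100.0 * n / len(scores), abs=1e-9)

    def test_single_record_single_bin(self):
        table = AffinityTable(
            records=[AffinityRecord(conformer_id="C", repeat=1, score=-6.02)],
            n_repeats=1,
        )
        hist = affinity_histogram(table, bin_width=0.1)
        assert hist["frequency_pct"].max() == pytest.approx(100.0)

    def test_uniform_scores_over_two_bins(self):
        records = [AffinityRecord("C", r + 1, s)
                   for r, s in enumerate([-6.05] * 5 + [-5.95] * 5)]
        hist = affinity_histogram(AffinityTable(records=records, n_repeats=10),
                                  bin_width=0.1)
        nonzero = hist[hist["frequency_pct"] > 0]
        assert list(nonzero["frequency_pct"]) == [50.0, 50.0]


VINA_STDOUT = """\
Detected 4 CPUs
Reading input ... done.
mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       -6.0      0.000      0.000
   2       -5.8      1.234      2.345
   3       -5.1      2.000      4.100
   4       -4.9      2.400      4.600
   5       -4.7      3.100      5.300
   6       -4.4      3.500      5.900
   7       -4.2      4.000      6.300
   8       -4.0      4.400      6.800
   9       -3.9      4.900      7.200
Writing output ... done.
"""


class TestExternalAdapter:
    def test_absent_executable_is_configuration_error(self):
        (receptor,) = small_receptors(n=1)
        eng = VinaDockingEngine(executable="/no/such/vina")
        with pytest.raises(EngineConfigurationError, match="/no/such/vina"):
            eng.dock(receptor, tri_ligand(), DockingBox(np.zeros(3), 14.0), seed=0)

    def test_canned_output_parsed_verbatim(self):
        rows = parse_vina_output(VINA_STDOUT)
        assert len(rows) == 9
        assert rows[0] == (1, -6.0)
        assert rows[-1] == (9, -3.9)
        assert [a for _, a in rows] == sorted(a for _, a in rows)

    def test_unparseable_output_is_error(self):
        with pytest.raises(EngineOutputError):
            parse_vina_output("garbage with no table\n")

    def test_pdbqt_writers_emit_atom_records(self):
        (receptor,) = small_receptors(n=1)
        rec = write_pdbqt(receptor)
        lig = write_ligand_pdbqt(tri_ligand())
        assert rec.count("ATOM") == 30
        assert lig.startswith("ROOT")
        assert "TORSDOF 0" in lig
        x = float(lig.splitlines()[1][30:38])
        assert x == pytest.approx(0.0)
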