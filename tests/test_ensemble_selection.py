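import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import (exhaustive_qt_representatives, naive_complete_linkage_labels,
                     same_partition)
from xlmod.ensemble_selection import (ModelRecord, evaluate_ensemble,
                                      evaluate_model, hierarchical_cut, pick_best,
                                      pick_best_comparative, qt_cluster,
                                      read_score_table, rmsd_matrix,
                                      run_selection_cascade, select_top,
                                      shortest_mean_sasd, write_cluster_table)
from xlmod.restraints import Metric
from xlmod.sasd import sas_distance
from xlmod.structure_model import RigidPose
from xlmod.synthetic_fixtures import make_decoys
from xlmod.virtual_xl import enumerate_virtual_xls


def record(model_id, score, n_satisfied=0, mean_sasd=math.inf, **kw):
    return ModelRecord(model_id=model_id, score=score, n_satisfied=n_satisfied,
                       mean_sasd=mean_sasd, **kw)


@pytest.fixture(scope="module")
def small_ensemble(two_chain):
    xls = enumerate_virtual_xls(two_chain, ["A"], ["B"], spacing=2.0)
    decoys = make_decoys(two_chain, n=10, max_trans=25, max_rot_deg=120, seed=21)
    models = {d.model_id: d.structure for d in decoys}
    scores = {d.model_id: d.score for d in decoys}
    return two_chain, xls, decoys, models, scores


class TestEvaluate:
    def test_prefilter_never_changes_counts(self, small_ensemble):
        """The Euclidean pre-filter is safe because SASD >= Euclidean."""
        _, xls, _, models, scores = small_ensemble
        fast = evaluate_ensemble(models, xls, scores, spacing=2.0, prefilter=True)
        slow = evaluate_ensemble(models, xls, scores, spacing=2.0, prefilter=False)
        for a, b in zip(fast, slow):
            assert a.n_satisfied == b.n_satisfied
            assert a.mean_sasd == pytest.approx(b.mean_sasd)

    def test_satisfied_counts_match_per_link_evaluation(self, small_ensemble):
        two_chain, xls, _, models, scores = small_ensemble
        rec = evaluate_ensemble({"ref": two_chain}, xls, {"ref": 0.0}, spacing=2.0)[0]
        assert rec.n_satisfied == len(xls)  # the bound pose satisfies everything
        # brute-force recompute without any shortcuts, straight from sas_distance
        n = sum(
            1 for xl in xls
            if 0 <= sas_distance(two_chain, xl.spec1, xl.spec2, spacing=2.0).sasd <= 34.0
        )
        assert rec.n_satisfied == n

    def test_distant_pair_skips_sas_and_counts_unsatisfied(self, small_ensemble):
        _, xls, decoys, models, scores = small_ensemble
        far = max(decoys, key=lambda d: d.lrmsd)
        per_xl, n_sat, _ = evaluate_model(models[far.model_id], xls, spacing=2.0)
        for ev in per_xl.values():
            if ev.euclidean is not None and ev.euclidean > 45.0:
                assert ev.sasd == -1.0

    def test_euclidean_metric_counting(self, small_ensemble):
        two_chain, xls, _, _, _ = small_ensemble
        _, n_sat, _ = evaluate_model(two_chain, xls, metric=Metric.EUCLIDEAN,
                                     spacing=2.0)
        assert n_sat == len(xls)


class TestSelectTop:
    def test_keeps_maximal_count(self):
        recs = [record("a", 1.0, 3), record("b", 2.0, 3), record("c", 0.5, 2)]
        assert [r.model_id for r in select_top(recs)] == ["a", "b"]

    def test_caps_at_lowest_scoring(self):
        recs = [record(f"m{i:03d}", float(600 - i), 5) for i in range(600)]
        kept = select_top(recs, max_n=500)
        assert len(kept) == 500
        assert max(r.score for r in kept) == 500.0  # the 100 worst dropped

    def test_score_fallback_when_nothing_satisfies(self):
        recs = [record(f"m{i}", float(i), 0) for i in range(10)]
        kept = select_top(recs, max_n=4)
        assert [r.model_id for r in kept] == ["m0", "m1", "m2", "m3"]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        recs = [record(f"m{i:02d}", float(rng.uniform(-5, 5)),
                       int(rng.integers(0, 4))) for i in range(30)]
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert [r.model_id for r in select_top(recs, 7)] == \
            [r.model_id for r in select_top(shuffled, 7)]

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            select_top([])


class TestShortestMeanSasd:
    def test_small_example(self):
        recs = [record("a", 0, mean_sasd=10.0), record("b", 0, mean_sasd=12.0),
                record("c", 0, mean_sasd=11.0)]
        assert [r.mean_sasd for r in shortest_mean_sasd(recs, n=2)] == [10.0, 11.0]

    def test_n_larger_than_input_is_identity(self):
        recs = [record("a", 0, mean_sasd=3.0), record("b", 0, mean_sasd=1.0)]
        assert len(shortest_mean_sasd(recs, n=10)) == 2

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        recs = [record(f"m{i:04d}", float(rng.normal()),
                       mean_sasd=float(rng.uniform(5, 30))) for i in range(1000)]
        got = [r.model_id for r in shortest_mean_sasd(recs, n=300)]
        oracle = [r.model_id for r in
                  sorted(recs, key=lambda r: (r.mean_sasd, r.score, r.model_id))[:300]]
        assert got == oracle


class TestRmsdMatrix:
    def test_duplicates_give_zero_matrix(self, two_chain):
        models = {"a": two_chain, "b": two_chain.copy(), "c": two_chain.copy()}
        _, mat = rmsd_matrix(models, ligand_only=True,
                             receptor_chains=["A"], ligand_chains=["B"])
        np.testing.assert_allclose(mat, 0.0, atol=1e-9)

    def test_known_translations(self, two_chain):
        def shifted(dx):
            st = two_chain.copy()
            for ch in st.chains:
                if ch.id == "B":
                    for res in ch.residues:
                        for a in res.atoms:
                            a.coord = a.coord + np.array([dx, 0.0, 0.0])
            return st

        models = {"m0": two_chain, "m1": shifted(3.0), "m2": shifted(7.0)}
        ids, mat = rmsd_matrix(models, ligand_only=True,
                               receptor_chains=["A"], ligand_chains=["B"])
        assert mat[ids.index("m0"), ids.index("m1")] == pytest.approx(3.0, abs=1e-9)
        assert mat[ids.index("m0"), ids.index("m2")] == pytest.approx(7.0, abs=1e-9)
        assert mat[ids.index("m1"), ids.index("m2")] == pytest.approx(4.0, abs=1e-9)
        assert np.array_equal(mat, mat.T) and np.all(np.diag(mat) == 0)


class TestHierarchicalCut:
    def test_two_tight_groups(self):
        n = 6
        mat = np.full((n, n), 50.0)
        mat[:3, :3] = 1.0
        mat[3:, 3:] = 1.0
        np.fill_diagonal(mat, 0.0)
        res = hierarchical_cut(mat, height=10.0)
        assert len(res.sizes) == 2 and sorted(res.sizes.values()) == [3, 3]

    def test_everything_below_cut_is_one_cluster(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0, 5, size=(8, 8))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        assert len(hierarchical_cut(mat, height=10.0).sizes) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_reference_on_20_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, size=(20, 2))
        mat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ids = [f"m{i:02d}" for i in range(20)]
        res = hierarchical_cut(mat, height=12.0, ids=ids)
        oracle = naive_complete_linkage_labels(mat, height=12.0)
        assert same_partition(res.labels, oracle, ids)

    def test_non_symmetric_rejected(self):
        mat = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cut(mat, height=1.0)


def pose(angle_deg=0.0, axis=(0, 0, 1.0), trans=(0, 0, 0)):
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, float))
    return RigidPose(rot.as_matrix(), np.asarray(trans, float))


class TestQtCluster:
    def test_identical_poses_form_one_cluster(self):
        poses = {f"m{i}": pose() for i in range(5)}
        scores = {f"m{i}": float(i) for i in range(5)}
        res = qt_cluster(poses, scores)
        assert res.sizes == {1: 5}
        assert res.representatives == ["m0"]  # lowest score wins the tie

    def test_rotation_beyond_threshold_is_dissimilar(self):
        poses = {"a": pose(0.0), "b": pose(10.0)}
        res = qt_cluster(poses, {"a": 0.0, "b": 1.0})
        assert len(res.sizes) == 2

    def test_thresholds_are_strict(self):
        # exactly 3 A apart / exactly 8 deg apart: "smaller than" excludes both
        at_trans = {"a": pose(), "b": pose(trans=(3.0, 0, 0))}
        assert len(qt_cluster(at_trans, {"a": 0, "b": 0}).sizes) == 2
        at_rot = {"a": pose(), "b": pose(8.0)}
        assert len(qt_cluster(at_rot, {"a": 0, "b": 0}).sizes) == 2
        just_inside = {"a": pose(7.9, trans=(0, 0, 0)),
                       "b": pose(0.0, trans=(2.9, 0, 0))}
        assert len(qt_cluster(just_inside, {"a": 0, "b": 0}).sizes) == 1

    def test_matches_exhaustive_oracle_on_30_poses(self):
        rng = np.random.default_rng(7)
        ids = [f"m{i:02d}" for i in range(30)]
        poses, scores = {}, {}
        for mid in ids:
            center = rng.choice([0.0, 20.0, 40.0])
            poses[mid] = pose(float(rng.uniform(0, 12)),
                              trans=center + rng.uniform(-2, 2, size=3))
            scores[mid] = float(rng.normal())
        res = qt_cluster(poses, scores, n_clusters=30)
        n = len(ids)
        similar = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                td = np.linalg.norm(poses[ids[i]].translation
                                    - poses[ids[j]].translation)
                ang = poses[ids[i]].angle_to(poses[ids[j]])
                similar[i, j] = td < 3.0 and ang < 8.0
        assert res.representatives == exhaustive_qt_representatives(
            similar, ids, scores)

    def test_sizes_cover_all_models(self):
        rng = np.random.default_rng(8)
        poses = {f"m{i}": pose(float(rng.uniform(0, 90)),
                               trans=rng.uniform(-20, 20, 3)) for i in range(12)}
        scores = {k: 0.0 for k in poses}
        res = qt_cluster(poses, scores)
        assert sum(res.sizes.values()) == 12
        for rep in res.representatives:
            assert rep in res.labels


class TestPickBest:
    def test_lowest_score_in_largest_cluster(self):
        from xlmod.ensemble_selection import ClusterResult
        labels = {"a": 1, "b": 1, "c": 1, "d": 1, "e": 1, "f": 2, "g": 2}
        cr = ClusterResult(labels=labels, sizes={1: 5, 2: 2}, representatives=["a"])
        recs = [record(m, s) for m, s in
                [("a", 3.0), ("b", 1.5), ("c", 2.0), ("d", 9.0), ("e", 4.0),
                 ("f", -10.0), ("g", -9.0)]]
        assert pick_best(cr, recs).model_id == "b"

    def test_singletons_fall_back_to_template_rmsd(self):
        from xlmod.ensemble_selection import ClusterResult
        cr = ClusterResult(labels={"a": 1, "b": 2}, sizes={1: 1, 2: 1},
                           representatives=["a", "b"])
        recs = [record("a", 0.0, rmsd_to_template=5.0),
                record("b", 9.0, rmsd_to_template=2.0)]
        assert pick_best(cr, recs).model_id == "b"

    def test_matches_brute_force_scan(self):
        from xlmod.ensemble_selection import ClusterResult
        rng = np.random.default_rng(9)
        ids = [f"m{i:02d}" for i in range(25)]
        labels = {m: int(rng.integers(1, 5)) for m in ids}
        sizes = {}
        for c in labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        recs = [record(m, float(rng.normal())) for m in ids]
        cr = ClusterResult(labels=labels, sizes=sizes, representatives=[])
        got = pick_best(cr, recs)
        biggest = max(sizes.values())
        candidates = [
            r for r in recs
            if sizes[labels[r.model_id]] == biggest
        ]
        # brute-force: among largest clusters, break ties by mean score
        by_cluster = {}
        for r in recs:
            by_cluster.setdefault(labels[r.model_id], []).append(r)
        best_cluster = min(
            (c for c, members in by_cluster.items() if len(members) == biggest),
            key=lambda c: (float(np.mean([r.score for r in by_cluster[c]])), c))
        expect = min(by_cluster[best_cluster], key=lambda r: (r.score, r.model_id))
        assert got.model_id == expect.model_id

    def test_comparative_election(self):
        recs = [record("a", 5.0, 3, rmsd_to_template=1.0),
                record("b", 1.0, 3, rmsd_to_template=2.0),
                record("c", 0.0, 2, rmsd_to_template=0.1)]
        assert pick_best_comparative(recs).model_id == "a"


class TestCascadeAndTables:
    def test_cascade_is_deterministic(self, small_ensemble):
        _, xls, _, models, scores = small_ensemble
        runs = [
            run_selection_cascade(models, xls, scores, receptor_chains=["A"],
                                  ligand_chains=["B"], bsa_threshold=None,
                                  cut_height=20.0, spacing=2.0)
            for _ in range(2)
        ]
        assert runs[0][0].model_id == runs[1][0].model_id
        assert runs[0][2].labels == runs[1][2].labels
        assert [r.mean_sasd for r in runs[0][1]] == [r.mean_sasd for r in runs[1][1]]

    def test_bsa_filter_restricts_to_real_interfaces(self, small_ensemble):
        _, xls, decoys, models, scores = small_ensemble
        best, kept, _ = run_selection_cascade(
            models, xls, scores, receptor_chains=["A"], ligand_chains=["B"],
            bsa_threshold=50.0, cut_height=20.0, spacing=2.0)
        assert all(r.bsa is None or r.bsa >= 50.0 for r in kept)

    def test_read_score_table_two_column(self):
        assert read_score_table("m1\t-3.5\nm2\t1.25\n") == {"m1": -3.5, "m2": 1.25}

    def test_read_score_table_rosetta_style(self):
        text = ("score rms description\n"
                "-120.5 4.2 model_0001\n"
                "-98.1 9.9 model_0002\n")
        assert read_score_table(text) == {"model_0001": -120.5, "model_0002": -98.1}

    def test_cluster_table_roundtrip(self):
        from xlmod.ensemble_selection import ClusterResult
        cr = ClusterResult(labels={"b": 2, "a": 1}, sizes={1: 1, 2: 1},
                           representatives=["a", "b"])
        assert write_cluster_table(cr) == "a\t1\nb\t2\n"
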