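"""Profile clustering, feature agglomeration, forest protocol, attribution."""

import numpy as np
import pandas as pd
import pytest

from fibrilscan import (
    ProfileMatrix,
    ResidueProfile,
    TrainProtocol,
    agglomerate_features,
    common_residue_intersection,
    decompose_prediction,
    distance_matrix,
    export_dendrogram,
    profile_matrix_from_scans,
    subtype_to_parent,
    train_forest,
    ward_cluster,
)
from fibrilscan.classify import LinkageTree
from fibrilscan.energetics import scan_result_from_frame
from fibrilscan.synthetic import generate_profiles, planted_class_profile_spec


def _profile(sid, values):
    return ResidueProfile(structure_id=sid, values=values)


def _matrix(data, labels=None, index=None):
    values = pd.DataFrame(data)
    values.index = pd.MultiIndex.from_tuples(
        index or [(f"s{i}", 0) for i in range(len(values))],
        names=["structure_id", "replicate"])
    sids = values.index.get_level_values(0)
    return ProfileMatrix(values=values,
                         labels=labels or {s: s for s in sids})


def _scans_from_spec(spec):
    tables, labels = generate_profiles(spec)
    return [scan_result_from_frame(df) for df in tables.values()], labels


class TestIntersection:
    def test_overlapping_ranges(self):
        a = _profile("a", {i: 1.0 for i in range(301, 381)})
        b = _profile("b", {i: 2.0 for i in range(244, 381)})
        m = common_residue_intersection([a, b])
        assert m.residues == list(range(301, 381))

    def test_na_column_dropped_for_all(self):
        a = _profile("a", {1: 1.0, 2: None, 3: 3.0})
        b = _profile("b", {1: 1.0, 2: 2.0, 3: 3.0})
        m = common_residue_intersection([a, b])
        assert m.residues == [1, 3]

    def test_identical_sets_keep_all_columns(self):
        a = _profile("a", {1: 1.0, 2: 2.0})
        b = _profile("b", {1: 0.0, 2: 5.0})
        assert common_residue_intersection([a, b]).residues == [1, 2]

    def test_empty_intersection_rejected(self):
        a = _profile("a", {1: 1.0, 2: 1.0})
        b = _profile("b", {3: 1.0, 4: 1.0})
        with pytest.raises(ValueError):
            common_residue_intersection([a, b])


class TestDistanceMatrix:
    def test_identical_profiles_give_zero(self):
        m = _matrix([[1.0, 2.0], [1.0, 2.0]])
        d = distance_matrix(m)
        assert d.values == pytest.approx(np.zeros((2, 2)))

    def test_pythagoras(self):
        m = _matrix([[0.0, 0.0], [3.0, 4.0]])
        assert distance_matrix(m).values[0, 1] == pytest.approx(5.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(5, 4)))
        d = distance_matrix(m).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


def _naive_ward(X):
    """Recompute-from-scratch Ward oracle (Lance-Williams-free)."""
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = X[clusters[i]], X[clusters[j]]
                na, nb = len(a), len(b)
                d2 = ((a.mean(0) - b.mean(0)) ** 2).sum()
                cost = np.sqrt(2.0 * na * nb / (na + nb) * d2)
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        merges.append((sorted(map(tuple, [sorted(clusters[i]),
                                          sorted(clusters[j])])), cost))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + \
            [clusters[i] + clusters[j]]
    return merges


class TestWard:
    def test_duplicated_points_merge_first_at_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        tree = ward_cluster(X)
        assert tree.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}

    def test_matches_naive_oracle_on_small_data(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            X = rng.normal(size=(n, 3))
            tree = ward_cluster(X)
            oracle = _naive_ward(X)
            got_heights = sorted(tree.merges[:, 2])
            want_heights = sorted(c for _, c in oracle)
            assert got_heights == pytest.approx(want_heights, abs=1e-9)

    def test_heights_monotone(self):
        rng = np.random.default_rng(8)
        tree = ward_cluster(rng.normal(size=(12, 5)))
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    def test_planted_clusters_recovered(self):
        """Two 10σ-separated Gaussian blobs split perfectly, 100 seeds."""
        from scipy.cluster.hierarchy import fcluster
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, size=(6, 2))
            b = rng.normal(10.0, 1.0, size=(6, 2))
            X = np.vstack([a, b])
            tree = ward_cluster(X)
            labels = fcluster(tree.merges, t=2, criterion="maxclust")
            same = labels[:6]
            other = labels[6:]
            assert len(set(same)) == 1 and len(set(other)) == 1
            assert same[0] != other[0]


class TestAgglomeration:
    def test_k_equals_n_is_identity(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(6, 5)))
        fc, red = agglomerate_features(m, k=5)
        assert sorted(map(len, (fc.members(c) for c in range(5)))) == [1] * 5
        got = np.sort(red.values.values, axis=1)
        want = np.sort(m.values.values, axis=1)
        assert np.allclose(got, want)

    def test_k1_is_row_mean(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(4, 6)))
        _, red = agglomerate_features(m, k=1)
        assert np.allclose(red.values.values[:, 0], m.values.values.mean(1))

    def test_duplicate_columns_co_cluster(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 4))
        data = np.column_stack([base, base[:, 0]])  # col 4 duplicates col 0
        m = ProfileMatrix(
            values=pd.DataFrame(data, columns=[10, 20, 30, 40, 50],
                                index=pd.MultiIndex.from_tuples(
                                    [(f"s{i}", 0) for i in range(8)],
                                    names=["structure_id", "replicate"])),
            labels={f"s{i}": f"s{i}" for i in range(8)})
        fc, _ = agglomerate_features(m, k=4)
        assert fc.residue_to_cluster[10] == fc.residue_to_cluster[50]

    def test_invalid_k_rejected(self):
        m = _matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            agglomerate_features(m, k=0)
        with pytest.raises(ValueError):
            agglomerate_features(m, k=5)

    def test_column_permutation_invariance(self):
        """Agglomeration + classification ignore input column order."""
        spec, _ = planted_class_profile_spec(n_classes=3, n_residues=15,
                                             n_replicates=6, rng_seed=5)
        scans, labels = _scans_from_spec(spec)
        m = profile_matrix_from_scans(scans, labels)
        perm = m.values[list(np.random.default_rng(0).permutation(
            m.values.columns))]
        m2 = ProfileMatrix(values=perm[sorted(perm.columns)],
                           labels=m.labels)
        fc1, _ = agglomerate_features(m, k=6)
        fc2, _ = agglomerate_features(m2, k=6)
        part1 = {frozenset(fc1.members(c)) for c in range(6)}
        part2 = {frozenset(fc2.members(c)) for c in range(6)}
        assert part1 == part2


class TestSubtypeMapping:
    @pytest.mark.parametrize("sid,parent", [
        ("GGT_T1", "GGT"), ("GGT_T3", "GGT"), ("AD-PHF", "AD"),
        ("AD-SF", "AD"), ("CBD_T2", "CBD"), ("PSP", "PSP"),
        ("GPT_T2a", "GPT"), ("NEWFOLD_T1", "NEWFOLD"),
    ])
    def test_parent_mapping(self, sid, parent):
        assert subtype_to_parent(sid) == parent


class TestForest:
    def test_zero_noise_is_perfectly_separable(self):
        spec, _ = planted_class_profile_spec(n_classes=3, n_residues=15,
                                             noise_sigma=0.0,
                                             n_replicates=12, rng_seed=0)
        scans, labels = _scans_from_spec(spec)
        m = profile_matrix_from_scans(scans, labels)
        fc, red = agglomerate_features(m, k=10)
        proto = TrainProtocol(n_train=4, n_test=8, n_restarts=3, rng_seed=0)
        report = train_forest(red, proto, fc)
        assert report.test_accuracy == 1.0

    def test_deterministic_under_seed(self):
        spec, _ = planted_class_profile_spec(n_classes=2, n_residues=12,
                                             n_replicates=10, rng_seed=3)
        scans, labels = _scans_from_spec(spec)
        m = profile_matrix_from_scans(scans, labels)
        _, red = agglomerate_features(m, k=8)
        proto = TrainProtocol(n_train=3, n_test=7, n_restarts=5, rng_seed=9)
        r1 = train_forest(red, proto)
        r2 = train_forest(red, proto)
        assert r1.test_accuracy == r2.test_accuracy
        assert r1.best_restart == r2.best_restart
        assert r1.contributions.equals(r2.contributions)

    def test_insufficient_replicates_guidance(self):
        spec, _ = planted_class_profile_spec(n_classes=2, n_residues=12,
                                             n_replicates=5, rng_seed=0)
        scans, labels = _scans_from_spec(spec)
        m = profile_matrix_from_scans(scans, labels)
        with pytest.raises(ValueError, match="n_train"):
            train_forest(m, TrainProtocol(n_train=9, n_test=26, n_restarts=1))


@pytest.fixture(scope="module")
def trained():
    spec, _ = planted_class_profile_spec(
        n_classes=3, n_residues=15, n_replicates=12, rng_seed=1)
    scans, labels = _scans_from_spec(spec)
    m = profile_matrix_from_scans(scans, labels)
    fc, red = agglomerate_features(m, k=10)
    proto = TrainProtocol(n_train=4, n_test=8, n_restarts=5, rng_seed=1)
    return train_forest(red, proto, fc), red


class TestDecomposition:

    def test_identity_for_every_sample(self, trained):
        report, red = trained
        for _, row in red.values.iterrows():
            bias, contrib = decompose_prediction(report, row.values)
            pred = report.forest.predict_proba(
                row.values.reshape(1, -1))[0]
            assert np.abs(bias + contrib.sum(0) - pred).max() < 1e-10

    def test_depth_one_tree_hand_case(self):
        from sklearn.ensemble import RandomForestClassifier
        X = np.array([[0.0, 5.0], [1.0, 5.0], [10.0, 5.0], [11.0, 5.0]])
        y = np.array(["a", "a", "b", "b"])
        forest = RandomForestClassifier(n_estimators=1, max_depth=1,
                                        bootstrap=False, random_state=0)
        forest.fit(X, y)
        tree = forest.estimators_[0].tree_
        assert tree.feature[0] == 0  # splits on the informative feature
        bias, contrib = decompose_prediction(forest, np.array([0.0, 5.0]))
        leaf_prob = np.array([1.0, 0.0])
        root_prob = np.array([0.5, 0.5])
        assert bias == pytest.approx(root_prob)
        assert contrib[0] == pytest.approx(leaf_prob - root_prob)
        assert contrib[1] == pytest.approx(np.zeros(2))

    def test_constant_feature_contributes_nothing(self, trained):
        report, red = trained
        # any feature never split on must have exactly zero contribution;
        # verify through a constant-augmented forest
        X = red.values.values
        Xc = np.column_stack([X, np.full(len(X), 3.14)])
        from sklearn.ensemble import RandomForestClassifier
        forest = RandomForestClassifier(n_estimators=20, random_state=0)
        forest.fit(Xc, red.row_labels())
        _, contrib = decompose_prediction(forest, Xc[0])
        assert np.all(contrib[-1] == 0.0)


class TestDendrogram:
    def test_two_leaf_newick(self, tmp_path):
        merges = np.array([[0.0, 1.0, 2.5, 2.0]])
        text = export_dendrogram(LinkageTree(merges, ["A", "B"]),
                                 tmp_path / "t.nwk")
        assert text == "(A:2.5,B:2.5);"

    def test_round_trip_preserves_heights(self, tmp_path):
        import skbio
        rng = np.random.default_rng(4)
        tree = ward_cluster(rng.normal(size=(6, 3)))
        path = tmp_path / "tree.nwk"
        export_dendrogram(tree, path)
        parsed = skbio.TreeNode.read(str(path))
        assert {t.name for t in parsed.tips()} == set(tree.leaf_ids)
        # root-to-tip distance equals the final merge height for every tip
        final = tree.merges[-1, 2]
        for tip in parsed.tips():
            assert tip.distance(parsed) == pytest.approx(final, abs=1e-9)
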