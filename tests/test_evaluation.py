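import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemnet import evaluation as ev
from chemnet import models as mdl
from chemnet import network as net
from chemnet.errors import InputError


def _frame(sizes: dict) -> pd.DataFrame:
    rows = []
    for cluster, n in sizes.items():
        for i in range(n):
            rows.append({"id": f"{cluster}{i}", "cluster": cluster})
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_holdout_and_fold_arithmetic(self):
        splits = ev.make_splits(_frame({"A": 60, "B": 40}), 0.1, 10, seed=0)
        assert len(splits.test_ids) == 10
        assert all(len(ids) == 9 for ids in splits.folds.values())

    def test_partition_properties(self):
        frame = _frame({"A": 57, "B": 43})
        splits = ev.make_splits(frame, 0.1, 10, seed=3)
        fold_sets = [set(ids) for ids in splits.folds.values()]
        for i, a in enumerate(fold_sets):
            for b in fold_sets[i + 1:]:
                assert not (a & b)
            assert not (a & set(splits.test_ids))
        union = set(splits.test_ids).union(*fold_sets)
        assert union == set(frame["id"])
        sizes = sorted(len(s) for s in fold_sets)
        assert sizes[-1] - sizes[0] <= 1

    def test_stratification_proportions(self):
        frame = _frame({"A": 60, "B": 40})
        splits = ev.make_splits(frame, 0.1, 10, seed=1)
        held = frame[frame["id"].isin(splits.test_ids)]
        counts = held["cluster"].value_counts()
        assert abs(counts.get("A", 0) - 6) <= 1
        assert abs(counts.get("B", 0) - 4) <= 1

    def test_too_few_samples_raises(self):
        with pytest.raises(InputError):
            ev.make_splits(_frame({"A": 5}), 0.1, 10)

    def test_small_class_warning_fallback(self, caplog):
        frame = _frame({"A": 95, "B": 5})
        with caplog.at_level("WARNING"):
            splits = ev.make_splits(frame, 0.1, 10, seed=0)
        assert "fewer members than folds" in caplog.text
        assert len(splits.all_ids()) == 100

    def test_determinism(self):
        frame = _frame({"A": 30, "B": 30})
        s1 = ev.make_splits(frame, 0.1, 5, seed=4)
        s2 = ev.make_splits(frame, 0.1, 5, seed=4)
        assert s1.test_ids == s2.test_ids
        assert s1.folds == s2.folds


class TestMakeTVT:
    def test_80_10_10(self):
        splits = ev.make_tvt(_frame({"A": 60, "B": 40}), seed=0)
        assert len(splits.train_ids) == 80
        assert len(splits.val_ids) == 10
        assert len(splits.test_ids) == 10
        counts = pd.Series(
            [i[0] for i in splits.test_ids]
        ).value_counts()
        assert abs(counts.get("A", 0) - 6) <= 1
        assert abs(counts.get("B", 0) - 4) <= 1

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InputError):
            ev.make_tvt(_frame({"A": 10}), fractions=(0.5, 0.2, 0.2))


class TestF1Scores:
    def test_perfect(self):
        macro, micro, _ = ev.f1_scores(["a", "b", "a"], ["a", "b", "a"])
        assert macro == 1.0 and micro == 1.0

    def test_degenerate_one_class_predictor(self):
        # balanced 2-class set of 10, all predicted 'a':
        # class a: P=0.5 R=1 -> F1=2/3; class b: F1=0 -> macro=1/3
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 10
        macro, micro, per_class = ev.f1_scores(y_true, y_pred)
        assert macro == pytest.approx(1 / 3)
        assert per_class["a"] == pytest.approx(2 / 3)
        assert per_class["b"] == 0.0
        assert micro == pytest.approx(0.5)

    def test_all_wrong(self):
        macro, micro, _ = ev.f1_scores(["a", "b"], ["b", "a"])
        assert macro == 0.0 and micro == 0.0

    def test_against_sklearn(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        macro, micro, _ = ev.f1_scores(y_true, y_pred)
        assert macro == pytest.approx(f1_score(y_true, y_pred, average="macro"))
        assert micro == pytest.approx(f1_score(y_true, y_pred, average="micro"))

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            ev.f1_scores([1, 2], [1])


class TestRandomizationTest:
    def test_identical_scores_p_one(self):
        assert ev.randomization_test([0.5] * 10, [0.5] * 10) == 1.0

    def test_exhaustive_all_positive(self):
        # 10 folds, constant +0.1 difference: only the two all-same sign
        # patterns reach |mean| >= 0.1 -> p = 2/1024
        a = [0.8] * 10
        b = [0.7] * 10
        assert ev.randomization_test(a, b) == pytest.approx(2 / 1024)

    def test_monte_carlo_path(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.8, 0.01, 20)
        b = a + 0.05
        p = ev.randomization_test(a, b, n_permutations=2000, seed=1)
        assert 0 < p < 0.01

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            ev.randomization_test([1, 2], [1])

    def test_null_calibration(self):
        """Type-I error at alpha=0.05 within the binomial 95% CI over 200
        null replicates."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.8, 0.05, 10)
            b = rng.normal(0.8, 0.05, 10)
            if ev.randomization_test(a, b) <= 0.05:
                rejections += 1
        rate = rejections / n_rep
        low, high = stats.binom.interval(0.95, n_rep, 0.05)
        assert low / n_rep <= rate <= high / n_rep


class TestSelectClusterSubset:
    def _clustering_with_near_pair(self):
        # 6 singleton-ish clusters; clusters of a/b are close (0.05), the
        # rest mutually far
        chems = ["a", "b", "c", "d", "e", "f"]
        m = np.array(
            [
                [0.0, 0.05, 0.9, 0.8, 0.7, 0.95],
                [0.05, 0.0, 0.9, 0.8, 0.7, 0.95],
                [0.9, 0.9, 0.0, 0.6, 0.75, 0.9],
                [0.8, 0.8, 0.6, 0.0, 0.85, 0.9],
                [0.7, 0.7, 0.75, 0.85, 0.0, 0.9],
                [0.95, 0.95, 0.9, 0.9, 0.9, 0.0],
            ]
        )
        dist = net.DistanceMatrix(chems, m)
        return net.hierarchical_cluster(dist, 0.06)

    def test_near_pair_included(self):
        clustering = self._clustering_with_near_pair()
        assert len(clustering.cluster_ids) == 5  # a+b merged
        subset = ev.select_cluster_subset(clustering, 4, seed=0)
        assert len(subset) == 4

    def test_all_clusters_when_n_equals_total(self):
        clustering = self._clustering_with_near_pair()
        subset = ev.select_cluster_subset(clustering, 5, seed=0)
        assert subset == clustering.cluster_ids

    def test_determinism(self):
        clustering = self._clustering_with_near_pair()
        assert ev.select_cluster_subset(clustering, 4, seed=3) == \
            ev.select_cluster_subset(clustering, 4, seed=3)

    def test_too_few_raises(self):
        clustering = self._clustering_with_near_pair()
        with pytest.raises(InputError):
            ev.select_cluster_subset(clustering, 10, seed=0)


class TestLeakageGuard:
    def test_augmented_sources_detected(self):
        train = pd.DataFrame(
            [
                {"id": "x1#aug1", "smiles": "CCO", "cluster": "A", "source_id": "x1"},
                {"id": "x2", "smiles": "CCC", "cluster": "A", "source_id": "x2"},
            ]
        )
        with pytest.raises(AssertionError):
            ev.assert_no_leakage(train, ["x1"])
        ev.assert_no_leakage(train, ["x9"])  # disjoint: fine


@pytest.fixture(scope="module")
def small_report(labeled_frame):
    frame = labeled_frame
    splits = ev.make_splits(frame, 0.2, 3, seed=0)
    configs = [
        ("dnn_a", mdl.desk_config("dnn", epochs=15, seed=0)),
        ("dnn_b", mdl.desk_config("dnn", epochs=15, seed=0)),
    ]
    return ev.evaluate_architectures(frame, configs, splits, seed=0)


class TestEvaluateArchitectures:
    def test_identical_configs_p_near_one(self, small_report):
        # identical configs give identical fold scores -> p = 1
        assert small_report.pairwise_p[("dnn_a", "dnn_b")] == 1.0

    def test_fold_bookkeeping(self, small_report):
        for name in ("dnn_a", "dnn_b"):
            assert len(small_report.per_fold[name]) == 3
            assert not small_report.failed_folds[name]
        assert small_report.means["dnn_a"] > 0.8

    def test_strong_vs_label_shuffled(self, labeled_frame):
        frame = labeled_frame.copy()
        shuffled = frame.copy()
        rng = np.random.default_rng(0)
        shuffled["cluster"] = rng.permutation(shuffled["cluster"].to_numpy())
        # >=8 folds: the two-sided sign-flip floor 2/2^n must sit below 0.05
        splits = ev.make_splits(frame, 0.2, 8, seed=0)
        config = mdl.desk_config("dnn", epochs=15, seed=0)
        real = ev.evaluate_architectures(frame, [("real", config)], splits, seed=0)
        fake = ev.evaluate_architectures(shuffled, [("fake", config)], splits, seed=0)
        p = ev.randomization_test(
            real.per_fold["real"], fake.per_fold["fake"], seed=0
        )
        assert p < 0.05


@pytest.fixture(scope="module", name="setup")
def predict_annotate_setup(default_fixture, labeled_frame):
    spec, graph, truth, library = default_fixture
    profiles = net.build_profiles(graph)
    dist = net.compute_distance_matrix(profiles)
    clustering = net.hierarchical_cluster(dist, 0.5)
    frame = labeled_frame.copy()
    from chemnet.encoding import encode_dataset

    encoded = encode_dataset(
        list(frame["id"]), list(frame["smiles"]), list(frame["cluster"]),
        "fingerprint",
    )
    model = mdl.train_classifier(
        encoded, mdl.desk_config("dnn", epochs=20, seed=0)
    )
    # relabel clustering to planted labels (recovery is exact on the fixture)
    # so the classifier's label set matches the clustering's cluster ids
    relabeled = {
        chem: truth.chemical_cluster[chem] for chem in clustering.assignment
    }
    clustering = net.Clustering(
        threshold=clustering.threshold,
        assignment=relabeled,
        linkage_matrix=clustering.linkage_matrix,
        leaves=clustering.leaves,
    )
    q = net.annotate_cluster(clustering, graph, 700)
    l = net.annotate_cluster(clustering, graph, 400)
    return spec, model, clustering, (q, l), library


class TestPredictAndAnnotate:
    def test_topk_sorted_and_bounded(self, setup):
        spec, model, clustering, annots, library = setup
        compounds = [library[c] for c in sorted(library)[:5]]
        report = ev.predict_and_annotate(model, compounds, clustering, annots, 3)
        for entry in report.predictions:
            assert entry["ok"]
            probs = [p for _, p in entry["top"]]
            assert probs == sorted(probs, reverse=True)
            assert sum(probs) <= 1.0 + 1e-9

    def test_same_cluster_distance_zero(self, setup):
        spec, model, clustering, annots, library = setup
        chems = sorted(library)
        same_cluster = [c for c in chems if c.startswith("C000")][:2]
        compounds = [library[c] for c in same_cluster]
        report = ev.predict_and_annotate(model, compounds, clustering, annots, 1)
        table = report.cluster_distance_table
        assert table is not None
        assert table.iloc[0, 1] == 0.0
        assert np.allclose(table.values, table.values.T)
        assert np.all(np.diag(table.values) == 0)

    def test_motif_compound_predicted_with_monotone_annotation(self, setup):
        spec, model, clustering, annots, library = setup
        # an undecorated motif molecule of cluster 1
        compound = spec.motif_per_cluster[1]
        report = ev.predict_and_annotate(model, [compound], clustering, annots, 3)
        entry = report.predictions[0]
        assert entry["ok"]
        top_cluster = entry["top"][0][0]
        assert top_cluster == 1
        ann = entry["annotations"][top_cluster]
        assert set(ann["Q"]) <= set(ann["L"])

    def test_unparseable_compound_error_entry(self, setup):
        spec, model, clustering, annots, library = setup
        good = library[sorted(library)[0]]
        report = ev.predict_and_annotate(
            model, ["C1CC", good], clustering, annots, 2
        )
        assert not report.predictions[0]["ok"]
        assert report.predictions[1]["ok"]
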