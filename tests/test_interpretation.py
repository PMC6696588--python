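import re

import numpy as np
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from probeal import interpretation as itp


class TestZscaleWeights:
    def test_hand_arithmetic(self):
        fw = itp.zscale_weights(np.array([[1.0, 2.0, 3.0]]))
        assert fw.matrix[0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_constant_row_is_zero(self):
        fw = itp.zscale_weights(np.array([[5.0, 5.0, 5.0]]))
        assert fw.matrix[0].tolist() == [0.0, 0.0, 0.0]

    def test_rows_mean_zero_sd_one(self, rng):
        raw = rng.random((6, 40))
        fw = itp.zscale_weights(raw)
        assert np.allclose(fw.matrix.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(fw.matrix.std(axis=1), 1.0)

    def test_frame_round_trip(self, tmp_path):
        fw = itp.zscale_weights(
            np.array([[1.0, 2.0], [3.0, 1.0]]),
            iterations=(0, 5),
            feature_names=("a", "b"),
        )
        path = tmp_path / "w.tsv"
        fw.to_csv(path)
        assert path.read_text().startswith("iteration\ta\tb")


def fit_small_forest(n_trees=8, seed=0, informative=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(120, 3))
    if informative is None:
        y = (X[:, 1] > 0).astype(int)
    else:
        y = (X[:, informative] > 0).astype(int)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return forest, X, y


class TestRecordWeights:
    def test_informative_feature_has_max_weight(self):
        forest, _, _ = fit_small_forest(informative=1)
        w = itp.record_weights(forest)
        assert int(np.argmax(w)) == 1

    def test_unused_feature_zero(self):
        rng = np.random.default_rng(0)
        X = np.zeros((80, 3))
        X[:, 0] = rng.normal(size=80)  # features 1 and 2 constant
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        w = itp.record_weights(forest, method="usage")
        assert w[1] == 0.0 and w[2] == 0.0

    def test_usage_matches_manual_tree_walk(self):
        forest, _, _ = fit_small_forest()
        counts = np.zeros(3)

        def walk(tree, node):
            if tree.children_left[node] == -1:
                return
            counts[tree.feature[node]] += 1
            walk(tree, tree.children_left[node])
            walk(tree, tree.children_right[node])

        for est in forest.estimators_:
            walk(est.tree_, 0)
        expected = counts / counts.sum()
        assert np.allclose(itp.usage_count_weights(forest), expected)

    def test_unfitted_errors(self):
        with pytest.raises(ValueError, match="not fitted"):
            itp.record_weights(RandomForestClassifier())


NODE_RE = re.compile(r"^\s*n(\d+) \[label=\"(.*)\", fillcolor=", re.M)
EDGE_RE = re.compile(r"^\s*n(\d+) -> n(\d+)", re.M)


class TestExportTree:
    def test_stump_has_three_nodes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        dot = itp.export_tree(tree, ["f0", "f1"])
        assert len(NODE_RE.findall(dot)) == 3
        assert len(EDGE_RE.findall(dot)) == 2

    def test_dot_structure_parses(self):
        forest, _, _ = fit_small_forest()
        dot = itp.export_tree(
            forest.estimators_[0], ["f0", "f1", "f2"], external_mcc=0.5, external_f1=0.6
        )
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
        assert dot.count("{") == dot.count("}")
        assert "MCC=0.50" in dot and "F1=0.60" in dot
        node_ids = {int(m[0]) for m in NODE_RE.findall(dot)}
        for a, b in EDGE_RE.findall(dot):
            assert int(a) in node_ids and int(b) in node_ids
        assert len(node_ids) % 2 == 1  # binary tree: odd node count

    def test_sample_counts_non_increasing_down_paths(self):
        forest, _, _ = fit_small_forest(n_trees=3)
        tree = forest.estimators_[0]
        dot = itp.export_tree(tree, ["f0", "f1", "f2"])
        samples = {
            int(m[0]): int(re.search(r"samples=(\d+)", m[1]).group(1))
            for m in NODE_RE.findall(dot)
        }
        for a, b in EDGE_RE.findall(dot):
            assert samples[int(b)] <= samples[int(a)]

    def test_unfitted_errors(self):
        with pytest.raises(ValueError):
            itp.export_tree(DecisionTreeClassifier(), ["f0"])


class TestRootFraction:
    def test_only_target_features_informative(self):
        rng = np.random.default_rng(1)
        X = np.concatenate(
            [np.zeros((100, 2)), rng.normal(size=(100, 2))], axis=1
        )
        y = (X[:, 3] > 0).astype(int)
        forests = [
            RandomForestClassifier(n_estimators=10, random_state=s).fit(X, y)
            for s in range(3)
        ]
        est = itp.root_fraction(forests, block_boundary=2)
        assert est.mean == 1.0

    def test_constant_target_block(self):
        rng = np.random.default_rng(1)
        X = np.concatenate(
            [rng.normal(size=(100, 2)), np.zeros((100, 2))], axis=1
        )
        y = (X[:, 0] > 0).astype(int)
        forests = [
            RandomForestClassifier(n_estimators=10, random_state=s).fit(X, y)
            for s in range(3)
        ]
        assert itp.root_fraction(forests, block_boundary=2).mean == 0.0

    def test_ci_matches_t_interval_arithmetic(self):
        forests = [fit_small_forest(seed=s)[0] for s in range(5)]
        est = itp.root_fraction(forests, block_boundary=1)
        fr = np.array(est.fractions)
        sem = fr.std(ddof=1) / np.sqrt(5)
        tcrit = stats.t.ppf(0.975, 4)
        assert est.ci95[0] == pytest.approx(fr.mean() - tcrit * sem)
        assert est.ci95[1] == pytest.approx(fr.mean() + tcrit * sem)
        assert est.ci95[0] <= est.mean <= est.ci95[1]

    def test_single_forest_point_estimate_only(self):
        forest, _, _ = fit_small_forest()
        est = itp.root_fraction([forest], block_boundary=1)
        assert est.ci95 is None and est.n_forests == 1

    def test_invariant_to_tree_order(self):
        forest, _, _ = fit_small_forest()
        a = itp.root_fraction([forest], 1).mean
        forest.estimators_ = forest.estimators_[::-1]
        assert itp.root_fraction([forest], 1).mean == a


class TestMotifUniqueness:
    def test_disjoint_sequences(self):
        idx = itp.motif_uniqueness({"a": "AAA", "b": "CCC"}, 3)
        assert idx == {"AAA": {"a"}, "CCC": {"b"}}

    def test_identical_sequences_share_everything(self):
        idx = itp.motif_uniqueness({"a": "MKSLP", "b": "MKSLP"}, 3)
        assert all(carriers == {"a", "b"} for carriers in idx.values())
        assert itp.unique_motifs({"a": "MKSLP", "b": "MKSLP"}, 3) == {}

    def test_planted_motifs_recovered(self, small_dataset):
        unique = itp.unique_motifs(small_dataset.sequences, 3)
        for tid, motif in small_dataset.truth.planted_motifs.items():
            assert unique.get(motif) == tid

    def test_group_motifs_shared_within_group(self, small_dataset):
        truth = small_dataset.truth
        idx = itp.motif_uniqueness(small_dataset.sequences, 3)
        for g, motif in truth.group_motifs.items():
            members = {t for t, gg in truth.group_of.items() if gg == g}
            assert idx[motif] == members


def test_weight_heatmap_writes_file(tmp_path, short_run, small_matrices):
    fw = itp.zscale_weights(
        short_run.weight_matrix(),
        iterations=short_run.weight_iterations,
        feature_names=small_matrices.feature_names,
        block_boundary=small_matrices.block_boundary,
    )
    out = tmp_path / "weights.png"
    itp.plot_weight_heatmap(fw, str(out))
    assert out.stat().st_size > 0
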