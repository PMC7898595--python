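"""PCA, subset enumeration, dendrograms and two-cluster partition scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

import tcrkmer as t


def _frame(data: np.ndarray, prefix: str = "s") -> pd.DataFrame:
    return pd.DataFrame(
        data,
        index=[f"{prefix}{i}" for i in range(data.shape[0])],
        columns=[f"f{j}" for j in range(data.shape[1])],
    )


class TestFitPCA:
    def test_identical_rows_get_identical_scores(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 30))
        X[5] = X[2]
        space = t.fit_pca(_frame(X), max_pc=10)
        assert np.allclose(space.scores.iloc[5], space.scores.iloc[2])

    def test_explained_variance_is_non_increasing(self):
        rng = np.random.default_rng(1)
        space = t.fit_pca(_frame(rng.random((15, 40))), max_pc=10)
        assert (np.diff(space.explained_variance) <= 1e-12).all()

    def test_full_reconstruction_roundtrip(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 40))
        space = t.fit_pca(_frame(X), max_pc=10)
        reconstructed = (
            space.scores.to_numpy() @ space.loadings.to_numpy().T
            + space.mean.to_numpy()
        )
        assert np.allclose(reconstructed, X, atol=1e-8)

    def test_too_few_samples_is_a_hard_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="1..10"):
            t.fit_pca(_frame(rng.random((10, 40))), max_pc=10)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        space = t.fit_pca(_frame(rng.random((12, 25))), max_pc=10)
        L = space.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_projection_matches_training_scores(self):
        rng = np.random.default_rng(5)
        X = _frame(rng.random((13, 20)))
        space = t.fit_pca(X, max_pc=10)
        assert np.allclose(
            space.project(X).to_numpy(), space.scores.to_numpy(), atol=1e-8
        )


class TestEnumeratePCSubsets:
    def test_ten_components_give_1023_subsets(self):
        subsets = t.enumerate_pc_subsets(10)
        assert len(subsets) == 1023
        assert len(set(subsets)) == 1023

    @pytest.mark.parametrize("max_pc,count", [(1, 1), (3, 7)])
    def test_small_counts(self, max_pc, count):
        assert len(t.enumerate_pc_subsets(max_pc)) == count

    def test_deterministic_order_by_size_then_lexicographic(self):
        subsets = t.enumerate_pc_subsets(3)
        assert subsets == [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3)]


class TestCluster:
    def test_dendrogram_has_n_minus_one_merges(self):
        rng = np.random.default_rng(6)
        space = t.fit_pca(_frame(rng.random((12, 20))), max_pc=10)
        dendro = t.cluster(space, (1, 2))
        assert dendro.Z.shape == (11, 4)

    def test_top_split_separates_two_blobs(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.1, (6, 5)), rng.normal(10, 0.1, (6, 5))])
        dendro = t.cluster_matrix(_frame(X))
        n = dendro.n
        child = int(dendro.Z[-1, 0])  # one child of the root merge
        left = {dendro.leaves[child]} if child < n else set(
            dendro.members(child - n)
        )
        assert left in ({f"s{i}" for i in range(6)},
                        {f"s{i}" for i in range(6, 12)})

    def test_collinear_equidistant_points_merge_deterministically(self):
        # points 0, 1, 2 on a line: d(0,1)=d(1,2)=1 tie; the lowest-index
        # pair merges first, then complete linkage joins point 2 at d=2
        df = _frame(np.array([[0.0], [1.0], [2.0]]))
        dendro = t.cluster_matrix(df)
        assert dendro.members(0) == ("s0", "s1")
        assert dendro.Z[0, 2] == pytest.approx(1.0)
        assert dendro.Z[1, 2] == pytest.approx(2.0)

    def test_subset_beyond_available_components_errors(self):
        rng = np.random.default_rng(8)
        space = t.fit_pca(_frame(rng.random((12, 20))), max_pc=10)
        with pytest.raises(ValueError, match="available"):
            t.cluster(space, (1, 12))

    def test_all_pc_clustering_equals_feature_space_clustering(self):
        # keeping every component, PCA is an isometry: same merge heights
        rng = np.random.default_rng(9)
        X = _frame(rng.random((12, 30)))
        space = t.fit_pca(X, max_pc=10)
        dendro_pc = t.cluster(space, tuple(range(1, space.n_components + 1)))
        dendro_raw = t.cluster_matrix(X)
        assert np.allclose(dendro_pc.Z[:, 2], dendro_raw.Z[:, 2], atol=1e-8)

    def test_newick_export_contains_all_leaves(self):
        df = _frame(np.array([[0.0], [1.0], [5.0]]))
        newick = t.cluster_matrix(df).to_newick()
        assert newick.endswith(";")
        for leaf in ("s0", "s1", "s2"):
            assert leaf in newick


class TestSeparation:
    def _manual_dendrogram(self):
        # 4 leaves: (0,1)@2 -> node 4; (2,3)@1 -> node 5; (4,5)@5 root
        Z = np.array(
            [[0, 1, 2.0, 2], [2, 3, 1.0, 2], [4, 5, 5.0, 4]], dtype=float
        )
        return t.Dendrogram(Z=Z, leaves=("a", "b", "c", "d"))

    def test_direct_subtraction(self):
        dendro = self._manual_dendrogram()
        assert t.separation(dendro, 0) == pytest.approx(3.0)  # 5 - 2
        assert t.separation(dendro, 1) == pytest.approx(4.0)  # 5 - 1
        assert t.separation(dendro, 2) == pytest.approx(0.0)  # root

    def test_monotone_linkage_gives_nonnegative_separation(self):
        rng = np.random.default_rng(10)
        dendro = t.cluster_matrix(_frame(rng.random((10, 4))))
        assert all(t.separation(dendro, i) >= 0 for i in range(dendro.n - 1))

    def test_blob_separating_node_has_maximal_separation(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.2, (5, 3)), rng.normal(8, 0.2, (5, 3))])
        labels = {f"s{i}": "case" if i < 5 else "control" for i in range(10)}
        dendro = t.cluster_matrix(_frame(X))
        perfect = [
            i
            for i in range(dendro.n - 1)
            if _partition_accuracy(dendro, i, labels) == 1.0
        ]
        seps = {i: t.separation(dendro, i) for i in range(dendro.n - 1)}
        best = t.best_partition(dendro, labels)
        assert best.accuracy == 1.0
        assert seps[best.node_index] == max(seps[i] for i in perfect)


def _partition_accuracy(dendro, node_index, labels):
    members = set(dendro.members(node_index))
    others = set(dendro.leaves) - members
    correct = 0
    for cluster_set in (members, others):
        if not cluster_set:
            continue
        n_case = sum(labels.get(s) == "case" for s in cluster_set)
        n_control = sum(labels.get(s) == "control" for s in cluster_set)
        if n_case == 0 and n_control == 0:
            continue
        majority = "case" if n_case >= n_control else "control"
        correct += sum(labels.get(s) == majority for s in cluster_set
                       if labels.get(s) in ("case", "control"))
    n = sum(1 for l in labels.values() if l in ("case", "control"))
    return correct / n


def brute_force_best_partition(dendro, labels):
    """Independent exhaustive scorer re-deriving member sets recursively."""
    n = dendro.n
    Z = dendro.Z

    def members(node):
        if node < n:
            return {dendro.leaves[node]}
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        return members(left) | members(right)

    def parent_height(idx):
        node_id = n + idx
        for j in range(n - 1):
            if int(Z[j, 0]) == node_id or int(Z[j, 1]) == node_id:
                return Z[j, 2]
        return Z[idx, 2]

    def majority(group):
        n_case = sum(labels.get(s) == "case" for s in group)
        n_control = sum(labels.get(s) == "control" for s in group)
        if n_case == 0 and n_control == 0:
            return None
        return "case" if n_case >= n_control else "control"

    best_key, best_idx, best_metrics = None, None, None
    for idx in range(n - 1):
        A = members(n + idx)
        B = set(dendro.leaves) - A
        pred = {}
        for group in (A, B):
            lab = majority(group)
            if lab is not None:
                pred.update({s: lab for s in group})
        cases = [s for s, l in labels.items() if l == "case"]
        controls = [s for s, l in labels.items() if l == "control"]
        sens = sum(pred.get(s) == "case" for s in cases) / len(cases)
        spec = sum(pred.get(s) == "control" for s in controls) / len(controls)
        acc = (
            sum(pred.get(s) == "case" for s in cases)
            + sum(pred.get(s) == "control" for s in controls)
        ) / (len(cases) + len(controls))
        sep = parent_height(idx) - Z[idx, 2]
        key = (acc, sens, sep, -idx)
        if best_key is None or key > best_key:
            best_key, best_idx = key, idx
            best_metrics = (acc, sens, spec, sep)
    return best_idx, best_metrics


class TestBestPartition:
    def test_perfectly_separated_labels(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(9, 0.1, (4, 2))])
        labels = {f"s{i}": "case" if i < 4 else "control" for i in range(8)}
        result = t.best_partition(t.cluster_matrix(_frame(X)), labels)
        assert (result.accuracy, result.sensitivity, result.specificity) == (1, 1, 1)

    def test_hand_scored_partition_on_fixed_tree(self):
        # 8 samples, 4 cases (s0-s3) / 4 controls (s4-s7); s3 sits inside
        # the control block, so no merge separates the classes perfectly.
        # The best merge isolates {s0,s1,s2}: 3 of 4 cases and 0 controls,
        # the complement majority-labels control and misses s3:
        # accuracy 7/8, sensitivity 3/4, specificity 4/4
        X = np.array(
            [[0.0], [0.1], [0.2], [5.55], [5.0], [5.5], [5.6], [5.7]]
        )
        labels = {f"s{i}": "case" if i < 4 else "control" for i in range(8)}
        result = t.best_partition(t.cluster_matrix(_frame(X)), labels)
        assert set(result.members) == {"s0", "s1", "s2"}
        assert result.accuracy == pytest.approx(7 / 8)
        assert result.sensitivity == pytest.approx(3 / 4)
        assert result.specificity == pytest.approx(1.0)

    def test_matches_brute_force_on_random_dendrograms(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            X = rng.random((n, 3))
            dendro = t.cluster_matrix(_frame(X))
            labels = {}
            while len(set(labels.values())) < 2:
                labels = {
                    f"s{i}": rng.choice(["case", "control"]) for i in range(n)
                }
            ours = t.best_partition(dendro, labels)
            idx, (acc, sens, spec, sep) = brute_force_best_partition(dendro, labels)
            assert ours.node_index == idx
            assert ours.accuracy == pytest.approx(acc)
            assert ours.sensitivity == pytest.approx(sens)
            assert ours.specificity == pytest.approx(spec)
            assert ours.separation == pytest.approx(sep)

    def test_label_swap_swaps_sensitivity_and_specificity(self):
        rng = np.random.default_rng(14)
        X = rng.random((10, 3))
        labels = {f"s{i}": "case" if i % 3 else "control" for i in range(10)}
        swapped = {
            s: "control" if l == "case" else "case" for s, l in labels.items()
        }
        dendro = t.cluster_matrix(_frame(X))
        a = t.best_partition(dendro, labels)
        b = t.best_partition(dendro, swapped)
        assert a.accuracy == pytest.approx(b.accuracy)
        # re-scoring a's own split under swapped labels exchanges the metrics
        from tcrkmer.cluster import score_partition

        _, acc, sens, spec, _ = score_partition(a.members, a.others, swapped)
        assert acc == pytest.approx(a.accuracy)
        assert sens == pytest.approx(a.specificity)
        assert spec == pytest.approx(a.sensitivity)

    def test_root_partition_bounds_accuracy_from_below(self):
        rng = np.random.default_rng(15)
        X = rng.random((9, 2))
        labels = {f"s{i}": "case" if i < 6 else "control" for i in range(9)}
        result = t.best_partition(t.cluster_matrix(_frame(X)), labels)
        assert result.accuracy >= 6 / 9  # root merge = everyone labelled majority

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(16)
        dendro = t.cluster_matrix(_frame(rng.random((5, 2))))
        with pytest.raises(ValueError, match="case and .*control"):
            t.best_partition(dendro, {f"s{i}": "case" for i in range(5)})
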