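"""PCA, PC-subset enumeration, hierarchical clustering and partition scoring.

The cohort frequency matrix is reduced by column-mean-centred PCA (no
variance scaling: frequencies already share a scale, and scaling would
inflate rare-k-mer noise).  Samples are clustered agglomeratively (complete
linkage, Euclidean distance, by default) on a chosen subset of the leading
principal components.  Every merge of the resulting dendrogram defines a
candidate two-cluster partition — the cluster created at the merge versus
all remaining samples.  Each cluster is labelled by the majority true class
of its members and the partition is scored by accuracy, with ties broken by
sensitivity, then by the separation of the merge (the vertical gap between
the merge and its parent merge), then by lowest merge index.

A deterministic sign convention (the largest-magnitude loading of each
component is made positive) keeps scores, dendrograms and downstream
selections reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA


@dataclass
class PCSpace:
    """Fitted PCA: per-sample scores, loadings and explained variance."""

    scores: pd.DataFrame  # samples x PC1..PCm
    loadings: pd.DataFrame  # features x PC1..PCm
    explained_variance: np.ndarray
    mean: pd.Series  # column means used for centring
    scale: pd.Series | None = None  # per-column std when variance scaling is on

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def project(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Project new frequency rows (aligned to the fitted columns)."""
        centred = rows.to_numpy(dtype=float) - self.mean.to_numpy()
        if self.scale is not None:
            centred = centred / self.scale.to_numpy()
        scores = centred @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=rows.index, columns=self.scores.columns)


def fit_pca(
    matrix: pd.DataFrame,
    max_pc: int = 10,
    scale: bool = False,
) -> PCSpace:
    """Column-mean-centred PCA of a samples x features frequency matrix.

    Requires at least ``max_pc + 1`` samples so that components 1..max_pc
    exist (PCA of n samples yields at most n - 1 components).  Components are
    ordered by explained variance and sign-fixed so the largest-magnitude
    loading of each component is positive.
    """
    n_samples, n_features = matrix.shape
    if n_samples < max_pc + 1:
        raise ValueError(
            f"PCA needs >= {max_pc + 1} samples so that principal components "
            f"1..{max_pc} exist (n samples yield at most n-1 components); "
            f"got {n_samples}"
        )
    X = matrix.to_numpy(dtype=float)
    col_mean = X.mean(axis=0)
    col_scale = None
    if scale:
        col_scale = X.std(axis=0)
        col_scale[col_scale == 0] = 1.0
        X = (X - col_mean) / col_scale
    n_components = min(n_samples - 1, n_features)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)  # PCA centres columns internally
    components = pca.components_  # (m, features)
    # deterministic sign: largest-|loading| positive per component
    for j in range(components.shape[0]):
        i_max = int(np.argmax(np.abs(components[j])))
        if components[j, i_max] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCSpace(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pc_names),
        loadings=pd.DataFrame(components.T, index=matrix.columns, columns=pc_names),
        explained_variance=pca.explained_variance_.copy(),
        mean=pd.Series(col_mean, index=matrix.columns),
        scale=None if col_scale is None else pd.Series(col_scale, index=matrix.columns),
    )


def enumerate_pc_subsets(max_pc: int = 10) -> list[tuple[int, ...]]:
    """All non-empty subsets of PCs 1..max_pc, by size then lexicographically.

    For max_pc = 10 this is the 1023 combinations searched exhaustively.
    """
    if max_pc < 1:
        raise ValueError("max_pc must be >= 1")
    subsets: list[tuple[int, ...]] = []
    for size in range(1, max_pc + 1):
        subsets.extend(combinations(range(1, max_pc + 1), size))
    return subsets


@dataclass
class Dendrogram:
    """Agglomerative clustering result: scipy merge matrix plus leaf ids."""

    Z: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaves: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.leaves)

    def members(self, node_index: int) -> tuple[str, ...]:
        """Leaf sample ids under merge ``node_index`` (0..n-2)."""
        n = self.n
        stack = [n + node_index]
        out: list[int] = []
        while stack:
            node = stack.pop()
            if node < n:
                out.append(node)
            else:
                row = self.Z[node - n]
                stack.append(int(row[0]))
                stack.append(int(row[1]))
        return tuple(self.leaves[i] for i in sorted(out))

    def to_newick(self) -> str:
        """Newick export with branch lengths derived from merge heights."""
        n = self.n
        heights = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.leaves[node]
            row = self.Z[node - n]
            h = float(row[2])
            parts = []
            for child in (int(row[0]), int(row[1])):
                child_h = 0.0 if child < n else float(self.Z[child - n][2])
                parts.append(f"{render(child)}:{h - child_h:g}")
            return "(" + ",".join(parts) + ")"

        return render(2 * n - 2) + ";"


def cluster_matrix(
    data: pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Complete/average/ward agglomerative clustering of rows (Euclidean)."""
    if len(data) < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = sch.linkage(data.to_numpy(dtype=float), method=linkage, metric="euclidean")
    return Dendrogram(Z=Z, leaves=tuple(str(i) for i in data.index))


def cluster(
    space: PCSpace, subset: Sequence[int], linkage: str = "complete"
) -> Dendrogram:
    """Cluster samples on the selected PC score columns."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("PC subset must be non-empty")
    missing = [i for i in subset if i < 1 or i > space.n_components]
    if missing:
        raise ValueError(
            f"PC indices {missing} exceed the {space.n_components} available components"
        )
    cols = [f"PC{i}" for i in subset]
    return cluster_matrix(space.scores[cols], linkage=linkage)


def separation(dendro: Dendrogram, node_index: int) -> float:
    """Vertical gap between a merge and its parent merge.

    The height at which the cluster created at ``node_index`` is absorbed
    into its parent, minus the merge's own height; 0 for the root.  With a
    monotone linkage this is non-negative.
    """
    n = dendro.n
    node_id = n + node_index
    height = float(dendro.Z[node_index, 2])
    for j in range(node_index + 1, n - 1):
        if int(dendro.Z[j, 0]) == node_id or int(dendro.Z[j, 1]) == node_id:
            return float(dendro.Z[j, 2]) - height
    return 0.0  # root


@dataclass
class PartitionResult:
    """A scored two-cluster partition of the cohort dendrogram."""

    node_index: int
    members: tuple[str, ...]  # cluster created at the merge
    others: tuple[str, ...]  # every remaining sample
    cluster_labels: tuple[str | None, str | None]  # (members label, others label)
    accuracy: float
    sensitivity: float
    specificity: float
    separation: float
    subset: tuple[int, ...] | None = None
    predictions: dict[str, str] = field(default_factory=dict)


def _majority(samples: Sequence[str], labels: Mapping[str, str]) -> str | None:
    """Majority class among labelled members; ties resolve to 'case'; None if unlabelled."""
    n_case = sum(1 for s in samples if labels.get(s) == "case")
    n_control = sum(1 for s in samples if labels.get(s) == "control")
    if n_case == 0 and n_control == 0:
        return None
    return "case" if n_case >= n_control else "control"


def score_partition(
    members: Sequence[str],
    others: Sequence[str],
    labels: Mapping[str, str],
) -> tuple[tuple[str | None, str | None], float, float, float, dict[str, str]]:
    """Label the two clusters by majority and score against the true labels.

    Sensitivity is the fraction of case samples correctly labelled,
    specificity the fraction of control samples, accuracy the fraction of
    all labelled samples.  Samples without a case/control label are ignored.
    """
    label_a = _majority(members, labels)
    label_b = _majority(others, labels)
    predictions: dict[str, str] = {}
    for s in members:
        if label_a is not None:
            predictions[s] = label_a
    for s in others:
        if label_b is not None:
            predictions[s] = label_b
    n_case = n_control = correct_case = correct_control = 0
    for s, true in labels.items():
        if true == "case":
            n_case += 1
            correct_case += predictions.get(s) == "case"
        elif true == "control":
            n_control += 1
            correct_control += predictions.get(s) == "control"
    n = n_case + n_control
    accuracy = (correct_case + correct_control) / n if n else float("nan")
    sensitivity = correct_case / n_case if n_case else float("nan")
    specificity = correct_control / n_control if n_control else float("nan")
    return (label_a, label_b), accuracy, sensitivity, specificity, predictions


def best_partition(
    dendro: Dendrogram, labels: Mapping[str, str]
) -> PartitionResult:
    """Exhaustively score every merge-defined two-cluster partition.

    Every merge (including the root, whose partition is the degenerate
    everyone-in-one-cluster split) is evaluated as {members under the merge}
    versus {all other samples}.  The optimal partition maximises accuracy,
    then sensitivity, then separation; residual exact ties go to the lowest
    merge index, making the result deterministic.
    """
    labelled = {s: l for s, l in labels.items() if l in ("case", "control")}
    classes = set(labelled.values())
    if "case" not in classes or "control" not in classes:
        raise ValueError("best_partition needs at least one case and one control label")
    best: PartitionResult | None = None
    best_key: tuple | None = None
    all_leaves = set(dendro.leaves)
    for node_index in range(dendro.n - 1):
        members = dendro.members(node_index)
        others = tuple(s for s in dendro.leaves if s not in set(members))
        assert set(members) | set(others) == all_leaves
        cluster_labels, acc, sens, spec, preds = score_partition(
            members, others, labelled
        )
        sep = separation(dendro, node_index)
        key = (acc, np.nan_to_num(sens), sep, -node_index)
        if best_key is None or key > best_key:
            best_key = key
            best = PartitionResult(
                node_index=node_index,
                members=members,
                others=others,
                cluster_labels=cluster_labels,
                accuracy=acc,
                sensitivity=sens,
                specificity=spec,
                separation=sep,
                predictions=preds,
            )
    assert best is not None
    return best
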