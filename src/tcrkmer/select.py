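"""Parameter search and validation for the repertoire classifier.

Three parameters are searched: the input type (positional k-mers,
non-positional k-mers, full-length CDR3s), the k-mer length (4-9 by
default), and the subset of principal components 1-10 used for clustering
(all 1023 non-empty subsets).  For each (input type, k) the frequency matrix
is built once and the PCA fitted once; every PC subset is then clustered and
its best two-cluster partition scored.  The winning parameter sets are those
with maximal training accuracy; among them the one with the greatest
separation between the two clusters is selected (residual ties go to the
earliest parameter set in the deterministic grid order).

Leave-one-out cross-validation removes each sample in turn, re-runs the full
grid search on the remaining n-1 samples, then re-introduces the held-out
sample: its features are restricted to the training feature union (unseen
features dropped, no renormalisation), it is projected into the training
PCA, all n samples are re-clustered with the selected parameters, clusters
are labelled by majority of *training* labels only, and the held-out
prediction is its cluster's label.  Nothing about the held-out sample
influences feature union, PCA fit or parameter selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cluster import (
    Dendrogram,
    PartitionResult,
    PCSpace,
    best_partition,
    cluster,
    cluster_matrix,
    enumerate_pc_subsets,
    fit_pca,
)
from .featurize import FeatureSpec, KmerFeaturizer, build_matrix
from .io import Cohort, Repertoire


class UnrepresentableSampleError(ValueError):
    """A new sample shares no features with the training cohort."""


@dataclass(frozen=True)
class ParameterSet:
    """A full parameter choice: featurisation spec plus PC subset."""

    spec: FeatureSpec
    subset: tuple[int, ...]

    def __str__(self) -> str:
        return f"{self.spec} PCs {','.join(map(str, self.subset))}"


@dataclass
class GridResult:
    """All scored parameter sets, the accuracy winners, and the selection."""

    results: list[tuple[ParameterSet, PartitionResult]]
    winners: list[ParameterSet]
    selected: ParameterSet
    best: PartitionResult
    n_subsets_per_cell: dict[str, int] = field(default_factory=dict)

    def accuracy_of(self, params: ParameterSet) -> float:
        for p, r in self.results:
            if p == params:
                return r.accuracy
        raise KeyError(str(params))


def default_grid(ks: Sequence[int] = range(4, 10), include_full_cdr3: bool = True) -> list[FeatureSpec]:
    """The default featurisation grid: positional and plain k-mers at each k,
    plus full-length CDR3s."""
    specs = [FeatureSpec("positional_kmer", k) for k in ks]
    specs += [FeatureSpec("kmer", k) for k in ks]
    if include_full_cdr3:
        specs.append(FeatureSpec("full_cdr3"))
    return specs


def _check_labelled(cohort: Cohort, min_n: int) -> dict[str, str]:
    labels = {s: l for s, l in cohort.labels.items() if l in ("case", "control")}
    if len(labels) < min_n:
        raise ValueError(
            f"need >= {min_n} labelled samples (PCs 1..{min_n - 1} must exist), "
            f"got {len(labels)}"
        )
    if len(set(labels.values())) < 2:
        raise ValueError("both case and control labels must be present")
    return labels


def grid_search(
    cohort: Cohort,
    specs: Sequence[FeatureSpec] | None = None,
    max_pc: int = 10,
    linkage: str = "complete",
) -> GridResult:
    """Exhaustive search over featurisation specs and PC subsets.

    Winners are the parameter sets with maximal best-partition accuracy;
    the selected set is the winner with the greatest separation, then the
    earliest in grid order.  A spec under which some sample yields no
    features (e.g. k longer than all its CDR3s) is skipped with a warning.
    """
    labels = _check_labelled(cohort, max_pc + 1)
    if specs is None:
        specs = default_grid()
    results: list[tuple[ParameterSet, PartitionResult]] = []
    n_subsets_per_cell: dict[str, int] = {}
    for spec in specs:
        try:
            matrix = build_matrix(cohort, spec)
        except ValueError as exc:
            warnings.warn(f"skipping {spec}: {exc}")
            continue
        space = fit_pca(matrix, max_pc=max_pc)
        avail = min(max_pc, space.n_components)
        subsets = enumerate_pc_subsets(avail)
        n_subsets_per_cell[str(spec)] = len(subsets)
        for subset in subsets:
            dendro = cluster(space, subset, linkage=linkage)
            partition = best_partition(dendro, labels)
            partition.subset = subset
            results.append((ParameterSet(spec, subset), partition))
    if not results:
        raise ValueError("every grid cell failed featurisation")
    best_acc = max(r.accuracy for _, r in results)
    winners = [p for p, r in results if r.accuracy == best_acc]
    selected, best = None, None
    for p, r in results:
        if r.accuracy == best_acc and (best is None or r.separation > best.separation):
            selected, best = p, r
    return GridResult(
        results=results,
        winners=winners,
        selected=selected,
        best=best,
        n_subsets_per_cell=n_subsets_per_cell,
    )


# ---------------------------------------------------------------------------
# Re-introduction of a held-out / new sample
# ---------------------------------------------------------------------------

def _predict_with_training(
    training: Cohort,
    sample: Repertoire,
    params: ParameterSet,
    linkage: str = "complete",
    max_pc: int = 10,
    reintroduction: str = "project",
) -> str:
    """Co-cluster one sample with a training cohort and read off its label.

    ``project`` (default, leakage-free): feature union and PCA come from the
    training samples only and the new sample's row is projected.  ``refit``:
    the feature union and PCA include the new sample (for comparison only).
    """
    train_reps = list(training)
    labels = {s: l for s, l in training.labels.items() if l in ("case", "control")}
    if reintroduction == "project":
        feat = KmerFeaturizer(params.spec.input_type, params.spec.k).fit(train_reps)
        X_train = feat.transform(train_reps)
        space = fit_pca(X_train, max_pc=max_pc)
        x_new = feat.transform([sample])
        if not np.any(x_new.to_numpy()):
            raise UnrepresentableSampleError(
                f"sample {sample.sample_id!r} shares no features with the cohort "
                f"under {params.spec}"
            )
        s_new = space.project(x_new)
        scores = pd.concat([space.scores, s_new])
    elif reintroduction == "refit":
        joint = Cohort(train_reps + [sample], locus=training.locus)
        matrix = build_matrix(joint, params.spec)
        space = fit_pca(matrix, max_pc=max_pc)
        scores = space.scores
    else:
        raise ValueError(f"unknown reintroduction mode {reintroduction!r}")

    cols = [f"PC{i}" for i in params.subset]
    dendro = cluster_matrix(scores[cols], linkage=linkage)
    partition = best_partition(dendro, labels)
    in_members = sample.sample_id in partition.members
    own_cluster, other_cluster = (
        (partition.members, partition.others) if in_members else (partition.others, partition.members)
    )
    own_label = partition.cluster_labels[0 if in_members else 1]
    if own_label is not None:
        return own_label
    # The sample's cluster holds no labelled training sample (e.g. it is a
    # singleton): fall back to the nearer labelled cluster centroid in the
    # selected PC subspace.
    sub = scores[cols]
    point = sub.loc[sample.sample_id].to_numpy()
    best_label, best_dist = None, np.inf
    for members, lab in (
        (own_cluster, own_label),
        (other_cluster, partition.cluster_labels[1 if in_members else 0]),
    ):
        train_members = [s for s in members if s in labels]
        if not train_members or lab is None:
            continue
        centroid = sub.loc[train_members].to_numpy().mean(axis=0)
        d = float(np.linalg.norm(point - centroid))
        if d < best_dist:
            best_label, best_dist = lab, d
    if best_label is None:
        raise ValueError(
            f"cannot label sample {sample.sample_id!r}: no labelled cluster found"
        )
    return best_label


def classify_new(
    cohort: Cohort,
    new_sample: Repertoire,
    params: ParameterSet,
    linkage: str = "complete",
    max_pc: int = 10,
) -> str:
    """Classify a new sample against a labelled cohort with fixed parameters.

    The sample is featurised on the cohort's feature union, projected into
    the cohort PCA, co-clustered, and assigned the majority label of its
    cluster — the procedure used for the gluten-free-diet samples.
    """
    return _predict_with_training(
        cohort, new_sample, params, linkage=linkage, max_pc=max_pc
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    sample_id: str
    true_label: str
    predicted_label: str | None
    params: ParameterSet | None


@dataclass
class CVResult:
    """Per-fold held-out predictions and aggregate testing metrics."""

    folds: list[FoldResult]

    def _counts(self) -> tuple[int, int, int, int]:
        n_case = n_control = correct_case = correct_control = 0
        for f in self.folds:
            if f.predicted_label is None:
                continue
            if f.true_label == "case":
                n_case += 1
                correct_case += f.predicted_label == "case"
            elif f.true_label == "control":
                n_control += 1
                correct_control += f.predicted_label == "control"
        return n_case, n_control, correct_case, correct_control

    @property
    def accuracy(self) -> float:
        n_case, n_control, cc, cn = self._counts()
        n = n_case + n_control
        return (cc + cn) / n if n else float("nan")

    @property
    def sensitivity(self) -> float:
        n_case, _, cc, _ = self._counts()
        return cc / n_case if n_case else float("nan")

    @property
    def specificity(self) -> float:
        _, n_control, _, cn = self._counts()
        return cn / n_control if n_control else float("nan")


def loocv(
    cohort: Cohort,
    specs: Sequence[FeatureSpec] | None = None,
    max_pc: int = 10,
    linkage: str = "complete",
    reintroduction: str = "project",
) -> CVResult:
    """Leave-one-out cross-validation of the full selection pipeline.

    For each sample the grid search runs on the other n-1 samples and the
    held-out sample is re-introduced with the training-selected parameters;
    testing accuracy/sensitivity/specificity aggregate the held-out
    predictions.  A fold whose training grid fails is reported as
    unpredictable and excluded with a warning.
    """
    labels = _check_labelled(cohort, max_pc + 2)
    folds: list[FoldResult] = []
    for rep in cohort:
        if rep.label not in ("case", "control"):
            continue
        training = cohort.without(rep.sample_id)
        train_labels = set(
            l for l in training.labels.values() if l in ("case", "control")
        )
        if len(train_labels) < 2:
            raise ValueError(
                f"degenerate LOOCV: removing {rep.sample_id!r} leaves a single class"
            )
        try:
            grid = grid_search(training, specs=specs, max_pc=max_pc, linkage=linkage)
            predicted = _predict_with_training(
                training,
                rep,
                grid.selected,
                linkage=linkage,
                max_pc=max_pc,
                reintroduction=reintroduction,
            )
            folds.append(FoldResult(rep.sample_id, rep.label, predicted, grid.selected))
        except (ValueError, UnrepresentableSampleError) as exc:
            warnings.warn(
                f"LOOCV fold for {rep.sample_id!r} unpredictable and excluded: {exc}"
            )
            folds.append(FoldResult(rep.sample_id, rep.label, None, None))
    return CVResult(folds=folds)


# ---------------------------------------------------------------------------
# Sklearn-style estimator
# ---------------------------------------------------------------------------

class RepertoireClassifier(ClassifierMixin, BaseEstimator):
    """Cohort-level repertoire classifier with exhaustive parameter search.

    ``fit`` takes a list of :class:`~tcrkmer.io.Repertoire` (or a
    :class:`~tcrkmer.io.Cohort`) and optionally a label array ``y``
    ("case"/"control"; defaults to each repertoire's own label), runs the
    grid search, and stores the selected parameters and training metrics.
    ``predict`` classifies new repertoires one at a time against the fitted
    cohort using the selected parameters.

    Parameters
    ----------
    ks : sequence of int
        k-mer lengths searched (default 4-9).
    include_full_cdr3 : bool
        Whether full-length CDR3 featurisation joins the grid.
    max_pc : int
        PC subsets are drawn from components 1..max_pc (default 10,
        i.e. 1023 subsets).
    linkage : str
        Agglomerative linkage (complete, average or ward; Euclidean).
    """

    def __init__(
        self,
        ks: Sequence[int] = (4, 5, 6, 7, 8, 9),
        include_full_cdr3: bool = True,
        max_pc: int = 10,
        linkage: str = "complete",
    ):
        self.ks = ks
        self.include_full_cdr3 = include_full_cdr3
        self.max_pc = max_pc
        self.linkage = linkage

    def _as_cohort(self, X: Iterable[Repertoire], y=None) -> Cohort:
        reps = list(X.repertoires) if isinstance(X, Cohort) else list(X)
        locus = reps[0].locus if reps else "TRG"
        cohort = Cohort(list(reps), locus=locus)
        if y is not None:
            cohort = cohort.relabel(
                {r.sample_id: str(lab) for r, lab in zip(reps, y)}
            )
        return cohort

    def fit(self, X: Iterable[Repertoire], y=None) -> "RepertoireClassifier":
        cohort = self._as_cohort(X, y)
        grid = grid_search(
            cohort,
            specs=default_grid(self.ks, self.include_full_cdr3),
            max_pc=self.max_pc,
            linkage=self.linkage,
        )
        self.cohort_ = cohort
        self.grid_result_ = grid
        self.best_params_ = grid.selected
        self.training_accuracy_ = grid.best.accuracy
        self.training_sensitivity_ = grid.best.sensitivity
        self.training_specificity_ = grid.best.specificity
        self.classes_ = np.array(["case", "control"])
        return self

    def predict(self, X: Iterable[Repertoire]) -> np.ndarray:
        if not hasattr(self, "best_params_"):
            raise ValueError("RepertoireClassifier is not fitted")
        out = [
            classify_new(
                self.cohort_,
                rep,
                self.best_params_,
                linkage=self.linkage,
                max_pc=self.max_pc,
            )
            for rep in X
        ]
        return np.array(out)
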