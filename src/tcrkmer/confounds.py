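"""Negative-control analyses: could something simpler drive the classifier?

Four checks probe whether the k-mer classification merely reflects coarser
properties of the repertoires:

* V/J segment usage — samples are clustered (complete linkage, Euclidean)
  on per-segment z-scores of usage frequencies; if usage separated the
  classes, the k-mer result would be suspect.
* CDR3 length — samples are clustered on their count-weighted CDR3 length
  distributions.
* Read-depth — every sample is randomly downsampled without replacement to
  the cohort-minimum total read count (multivariate hypergeometric over
  clonotypes) before re-running the pipeline.
* Clonal abundance — every clonotype count is collapsed to 1
  (presence/absence weighting) before re-running the pipeline.

The downsample/collapse transforms return ordinary cohorts, so the identical
classification path is reused; they are transforms, not forks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Dendrogram, PartitionResult, best_partition, cluster_matrix
from .io import Clonotype, Cohort, Repertoire, merge_clonotypes


@dataclass
class ConfoundResult:
    """A confound check: the feature table, its dendrogram, and the best
    two-cluster partition (None when the cohort lacks both labels)."""

    table: pd.DataFrame
    zscores: pd.DataFrame | None
    dendrogram: Dendrogram
    partition: PartitionResult | None


def segment_usage(cohort: Cohort, segment: str = "v") -> pd.DataFrame:
    """Count-weighted per-sample segment usage frequencies (rows sum to 1)."""
    attr = "v_call" if segment == "v" else "j_call"
    missing = [
        rep.sample_id
        for rep in cohort
        if any(not getattr(c, attr) for c in rep.clonotypes)
    ]
    if missing:
        raise ValueError(
            f"missing {segment.upper()} segment calls in sample(s): {missing}"
        )
    rows = {}
    for rep in cohort:
        counts: dict[str, int] = {}
        for c in rep.clonotypes:
            counts[getattr(c, attr)] = counts.get(getattr(c, attr), 0) + c.count
        total = sum(counts.values())
        rows[rep.sample_id] = {seg: n / total for seg, n in counts.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df[sorted(df.columns)]
    df.index.name = "sample"
    return df


def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (population denominator); constant columns -> 0."""
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=0)
    z = (df - mean).div(std.replace(0.0, np.nan), axis=1)
    return z.fillna(0.0)


def vj_usage_cluster(cohort: Cohort, linkage: str = "complete") -> ConfoundResult:
    """Cluster samples on z-scored V and J usage and score the best split.

    Usage frequencies of the V and J segment classes each sum to 1 per
    sample; z-scores express each segment's frequency as standard deviations
    from its cohort mean.  On repertoires whose V/J assignment is independent
    of diagnosis this clustering should classify no better than chance.
    """
    usage = pd.concat(
        [segment_usage(cohort, "v"), segment_usage(cohort, "j")], axis=1
    )
    z = zscore_columns(usage)
    dendro = cluster_matrix(z, linkage=linkage)
    partition = _maybe_partition(dendro, cohort)
    return ConfoundResult(table=usage, zscores=z, dendrogram=dendro, partition=partition)


def cdr3_length_analysis(cohort: Cohort, linkage: str = "complete") -> ConfoundResult:
    """Cluster samples on count-weighted CDR3 length distributions."""
    rows = {}
    for rep in cohort:
        counts: dict[int, int] = {}
        for c in rep.clonotypes:
            counts[len(c.cdr3_aa)] = counts.get(len(c.cdr3_aa), 0) + c.count
        total = sum(counts.values())
        rows[rep.sample_id] = {L: n / total for L, n in counts.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table[sorted(table.columns)]
    table.index.name = "sample"
    dendro = cluster_matrix(table, linkage=linkage)
    partition = _maybe_partition(dendro, cohort)
    return ConfoundResult(table=table, zscores=None, dendrogram=dendro, partition=partition)


def _maybe_partition(dendro: Dendrogram, cohort: Cohort) -> PartitionResult | None:
    labels = {s: l for s, l in cohort.labels.items() if l in ("case", "control")}
    if len(set(labels.values())) < 2:
        return None
    return best_partition(dendro, labels)


def downsample_to_min(
    cohort: Cohort,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    floor: int = 100,
    with_replacement: bool = False,
) -> Cohort:
    """Randomly downsample every sample to the cohort-minimum read count.

    Reads are exchangeable units within their clonotype, so sampling without
    replacement is multivariate hypergeometric over clonotype counts
    (``with_replacement=True`` switches to multinomial).  Clonotypes drawn
    zero times are dropped.  Deterministic under ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    min_total = min(rep.total_count for rep in cohort)
    if min_total < floor:
        warnings.warn(
            f"cohort-minimum read count {min_total} is below the floor {floor}; "
            "downsampled repertoires may be unstable"
        )
    reps = []
    for rep in cohort:
        clonos = merge_clonotypes(rep.clonotypes)
        counts = np.array([c.count for c in clonos])
        if counts.sum() == min_total:
            new_counts = counts
        elif with_replacement:
            new_counts = rng.multinomial(min_total, counts / counts.sum())
        else:
            new_counts = rng.multivariate_hypergeometric(counts, min_total)
        new_clonos = [
            replace(c, count=int(n)) for c, n in zip(clonos, new_counts) if n > 0
        ]
        reps.append(replace(rep, clonotypes=new_clonos))
    return Cohort(reps, locus=cohort.locus)


def collapse_clonotypes(cohort: Cohort) -> Cohort:
    """Set every clonotype count to 1 (presence/absence weighting).

    Downstream featurisation then weights samples by clonotype richness
    rather than read abundance.  Idempotent.
    """
    reps = []
    for rep in cohort:
        clonos = [replace(c, count=1) for c in merge_clonotypes(rep.clonotypes)]
        reps.append(replace(rep, clonotypes=clonos))
    return Cohort(reps, locus=cohort.locus)


def plot_usage_heatmap(zscores: pd.DataFrame, path: str | Path) -> None:
    """Write a simple segment-usage z-score heatmap (samples x segments)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * zscores.shape[1]), max(3, 0.3 * zscores.shape[0]))
    )
    im = ax.imshow(zscores.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(zscores.shape[1]))
    ax.set_xticklabels(zscores.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(zscores.shape[0]))
    ax.set_yticklabels(zscores.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="SD from mean")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
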