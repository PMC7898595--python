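"""CDR3 k-mer featurisation and per-sample frequency matrices.

Each CDR3 amino-acid sequence is decomposed into overlapping k-mers (step 1),
optionally annotated by which third of the CDR3 the k-mer derives from
(start / middle / end), or kept whole as a single full-length feature.  A
k-mer that recurs at a different position is then a distinct feature:
``("CALGE", start)`` is not ``("CALGE", end)``.  Feature counts are weighted
by clonotype read count and L1-normalised within each sample; the per-sample
frequency vectors are assembled into one cohort matrix over the feature
union.

Positional thirds: a CDR3 of length L is split at ceil(L/3) and ceil(2L/3);
a window is assigned the third containing its FIRST residue, which is
unambiguous for windows straddling a boundary.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AA_PATTERN, Cohort, Repertoire

INPUT_TYPES = ("positional_kmer", "kmer", "full_cdr3")
POSITIONS = ("start", "middle", "end", "none")


class Feature(NamedTuple):
    """A feature: an amino-acid string plus its positional annotation."""

    sequence: str
    position: str  # start | middle | end | none


@dataclass(frozen=True)
class FeatureSpec:
    """Featurisation parameters: input type and k-mer length.

    ``k`` is ignored (and may be None) for ``full_cdr3``.
    """

    input_type: str
    k: int | None = None

    def __post_init__(self) -> None:
        if self.input_type not in INPUT_TYPES:
            raise ValueError(
                f"input_type must be one of {INPUT_TYPES}, got {self.input_type!r}"
            )
        if self.input_type != "full_cdr3":
            if self.k is None or self.k < 1:
                raise ValueError(f"{self.input_type} requires k >= 1, got {self.k}")

    def __str__(self) -> str:
        if self.input_type == "full_cdr3":
            return "full_cdr3"
        return f"{self.input_type}(k={self.k})"


def third_boundaries(length: int) -> tuple[int, int]:
    """1-based boundaries: positions <= b1 are 'start', <= b2 'middle', else 'end'."""
    return math.ceil(length / 3), math.ceil(2 * length / 3)


def kmerize(cdr3_aa: str, spec: FeatureSpec) -> Counter:
    """Decompose one CDR3 into a multiset of features.

    For the k-mer input types, all ``len - k + 1`` overlapping windows are
    emitted; a CDR3 shorter than k yields the empty multiset (the caller
    reports such sequences in QC).  For ``full_cdr3`` the single feature
    ``(cdr3_aa, "none")`` is emitted.
    """
    if not cdr3_aa or not AA_PATTERN.match(cdr3_aa):
        raise ValueError(f"invalid amino-acid sequence {cdr3_aa!r}")
    features: Counter = Counter()
    if spec.input_type == "full_cdr3":
        features[Feature(cdr3_aa, "none")] = 1
        return features
    k = spec.k
    length = len(cdr3_aa)
    if length < k:
        return features
    b1, b2 = third_boundaries(length)
    for i in range(length - k + 1):
        window = cdr3_aa[i : i + k]
        if spec.input_type == "positional_kmer":
            pos1 = i + 1  # 1-based position of the window's first residue
            if pos1 <= b1:
                position = "start"
            elif pos1 <= b2:
                position = "middle"
            else:
                position = "end"
        else:
            position = "none"
        features[Feature(window, position)] += 1
    return features


def feature_counts(rep: Repertoire, spec: FeatureSpec) -> Counter:
    """Unnormalised feature counts, weighted by clonotype read count."""
    counts: Counter = Counter()
    for clono in rep.functional_clonotypes():
        for feature, n in kmerize(clono.cdr3_aa, spec).items():
            counts[feature] += n * clono.count
    return counts


def feature_frequencies(rep: Repertoire, spec: FeatureSpec) -> dict[Feature, float]:
    """Per-sample L1-normalised feature frequencies.

    Each clonotype contributes its feature multiset weighted by read count;
    frequencies sum to 1 within the sample.  A sample in which no clonotype
    is long enough for the requested k is unusable and raises ``ValueError``.
    """
    counts = feature_counts(rep, spec)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"sample {rep.sample_id!r}: no clonotype yields any feature under {spec}"
        )
    return {f: n / total for f, n in counts.items()}


def build_matrix(cohort: Cohort, spec: FeatureSpec) -> pd.DataFrame:
    """Cohort frequency matrix: samples x union-of-features.

    Columns are the feature union across samples, in lexicographic order of
    ``(sequence, position)``; absent features are 0 and every row sums to 1.
    """
    per_sample: dict[str, dict[Feature, float]] = {}
    for rep in cohort:
        try:
            per_sample[rep.sample_id] = feature_frequencies(rep, spec)
        except ValueError as exc:
            raise ValueError(f"featurisation failed for sample {rep.sample_id!r}: {exc}") from exc
    features = sorted({f for freqs in per_sample.values() for f in freqs})
    data = np.zeros((len(cohort), len(features)))
    index = {f: j for j, f in enumerate(features)}
    for i, rep in enumerate(cohort):
        for f, v in per_sample[rep.sample_id].items():
            data[i, index[f]] = v
    return pd.DataFrame(
        data,
        index=pd.Index(cohort.sample_ids, name="sample"),
        columns=pd.MultiIndex.from_tuples(features, names=["sequence", "position"]),
    )


def feature_space_size(spec: FeatureSpec) -> int:
    """Number of possible features: 20^k k-mers, times 3 if positional."""
    if spec.input_type == "full_cdr3":
        raise ValueError("feature space is unbounded for full_cdr3")
    base = 20 ** spec.k
    return 3 * base if spec.input_type == "positional_kmer" else base


class KmerFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from repertoires to frequency rows.

    ``fit`` records the feature union over the training repertoires;
    ``transform`` maps repertoires onto that union.  Features a transformed
    sample carries that were unseen in training are dropped *without*
    renormalising the row, so transformed rows of new samples may sum to less
    than 1 — the retained frequencies keep their within-sample meaning.

    Parameters
    ----------
    input_type : {"positional_kmer", "kmer", "full_cdr3"}
    k : int or None
        k-mer length; ignored for ``full_cdr3``.
    """

    def __init__(self, input_type: str = "positional_kmer", k: int | None = 5):
        self.input_type = input_type
        self.k = k

    @property
    def spec(self) -> FeatureSpec:
        return FeatureSpec(self.input_type, self.k)

    def fit(self, X: Iterable[Repertoire], y=None) -> "KmerFeaturizer":
        reps = list(X)
        if not reps:
            raise ValueError("cannot fit on zero repertoires")
        union: set[Feature] = set()
        for rep in reps:
            union.update(feature_frequencies(rep, self.spec))
        self.feature_names_ = sorted(union)
        self.n_features_in_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[Repertoire]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            raise ValueError("KmerFeaturizer is not fitted")
        reps = list(X)
        index = {f: j for j, f in enumerate(self.feature_names_)}
        data = np.zeros((len(reps), len(self.feature_names_)))
        for i, rep in enumerate(reps):
            freqs = feature_frequencies(rep, self.spec)
            for f, v in freqs.items():
                j = index.get(f)
                if j is not None:
                    data[i, j] = v
        return pd.DataFrame(
            data,
            index=pd.Index([r.sample_id for r in reps], name="sample"),
            columns=pd.MultiIndex.from_tuples(
                self.feature_names_, names=["sequence", "position"]
            ),
        )
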