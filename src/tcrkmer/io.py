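"""Reading, validation and filtering of bulk TCR repertoire data.

Raw data arrive either as FASTQ reads plus a table of external V(D)J
annotations (CDR3 span, segment calls, functionality, e.g. exported from
IMGT/HighV-QUEST), or directly as per-sample clonotype tables.  This module
turns both into clean :class:`Repertoire` / :class:`Cohort` objects holding
functional CDR3 amino-acid clonotypes with read counts and V/J calls.

Conventions
-----------
* CDR3 amino-acid strings include the conserved flanking residues as emitted
  by IMGT (typically a leading cysteine).
* CDR3 nucleotide spans in annotation tables are 1-based inclusive.
* Clonotype identity for merging is ``(cdr3_aa, v_call, j_call)``: CDR3 alone
  would conflate convergent rearrangements, and segment calls are needed for
  the V/J usage confound analysis.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_PATTERN = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
DNA_PATTERN = re.compile(r"^[ACGTRYSWKMBDHVN]+$", re.IGNORECASE)

NATIVE_COLUMNS = ("sample", "cdr3_aa", "count", "v_call", "j_call", "functional")
AIRR_COLUMNS = ("junction_aa", "duplicate_count", "v_call", "j_call", "productive")

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}
_FALSE_STRINGS = {"f", "false", "0", "no", "n"}


class NoQualityDataError(ValueError):
    """Raised when a quality-dependent stage receives reads without scores."""


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read, optionally with per-base Phred scores."""

    read_id: str
    nucleotide_seq: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.nucleotide_seq:
            raise ValueError(f"read {self.read_id!r}: empty nucleotide sequence")
        if not DNA_PATTERN.match(self.nucleotide_seq):
            raise ValueError(f"read {self.read_id!r}: non-IUPAC DNA characters")
        if self.quality is not None and len(self.quality) != len(self.nucleotide_seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.nucleotide_seq)}"
            )

    @property
    def mean_quality(self) -> float:
        if self.quality is None:
            raise NoQualityDataError(f"read {self.read_id!r} has no quality scores")
        return float(np.mean(self.quality))


@dataclass(frozen=True)
class Clonotype:
    """A unique CDR3 amino-acid sequence with V/J calls and read count."""

    cdr3_aa: str
    count: int
    v_call: str = ""
    j_call: str = ""
    functional: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"clonotype {self.cdr3_aa!r}: count must be >= 1")
        if self.functional and not AA_PATTERN.match(self.cdr3_aa):
            raise ValueError(
                f"clonotype {self.cdr3_aa!r}: functional CDR3 must use the 20 "
                "standard amino-acid letters"
            )


@dataclass
class Repertoire:
    """One sample's clonotype set with metadata."""

    sample_id: str
    clonotypes: list[Clonotype]
    locus: str = "TRG"
    label: str = "unknown"  # case | control | unknown

    def __post_init__(self) -> None:
        if self.label not in ("case", "control", "unknown"):
            raise ValueError(f"sample {self.sample_id!r}: bad label {self.label!r}")

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def functional_clonotypes(self) -> list[Clonotype]:
        return [c for c in self.clonotypes if c.functional]


@dataclass
class Cohort:
    """An ordered collection of repertoires sharing a locus."""

    repertoires: list[Repertoire]
    locus: str = "TRG"

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.repertoires]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        for r in self.repertoires:
            if r.locus != self.locus:
                raise ValueError(
                    f"sample {r.sample_id!r} locus {r.locus!r} != cohort {self.locus!r}"
                )

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    def __getitem__(self, sample_id: str) -> Repertoire:
        for r in self.repertoires:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.repertoires]

    @property
    def labels(self) -> dict[str, str]:
        return {r.sample_id: r.label for r in self.repertoires}

    def without(self, sample_id: str) -> "Cohort":
        kept = [r for r in self.repertoires if r.sample_id != sample_id]
        if len(kept) == len(self.repertoires):
            raise KeyError(sample_id)
        return Cohort(kept, locus=self.locus)

    def relabel(self, labels: Mapping[str, str]) -> "Cohort":
        """Return a cohort with labels replaced according to ``labels``."""
        reps = [
            replace(r, label=labels.get(r.sample_id, r.label)) for r in self.repertoires
        ]
        return Cohort(reps, locus=self.locus)


@dataclass
class QCReport:
    """Counters of records dropped or flagged during ingestion."""

    counters: dict[str, int] = field(default_factory=dict)

    def bump(self, key: str, by: int = 1) -> None:
        self.counters[key] = self.counters.get(key, 0) + by

    def get(self, key: str) -> int:
        return self.counters.get(key, 0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counters, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Quality filtering
# ---------------------------------------------------------------------------

def quality_threshold(
    reads: Sequence[ReadRecord], quartile: str = "lower"
) -> float:
    """Per-sample base-quality threshold.

    The threshold is the 25th percentile (``quartile="lower"``, default) or
    75th percentile (``"upper"``) of the per-read *mean* base quality,
    computed with linear interpolation.  The lower quartile is the default
    reading of "below the third quartile (lower 25%)", whose two halves
    contradict each other; both are supported.
    """
    if not reads:
        raise ValueError("cannot compute a quality threshold on zero reads")
    if any(r.quality is None for r in reads):
        raise NoQualityDataError(
            "no quality data: one or more reads lack Phred scores"
        )
    if len(reads) < 4:
        raise ValueError("quartile threshold needs at least 4 reads")
    means = np.array([r.mean_quality for r in reads])
    q = 25.0 if quartile == "lower" else 75.0
    if quartile not in ("lower", "upper"):
        raise ValueError(f"quartile must be 'lower' or 'upper', got {quartile!r}")
    return float(np.percentile(means, q))


def quality_filter(
    reads: Sequence[ReadRecord],
    *,
    quartile: str = "lower",
    max_low_fraction: float = 0.10,
    threshold: float | None = None,
) -> list[ReadRecord]:
    """Remove low-quality reads.

    A read is low quality when *more than* ``max_low_fraction`` of its bases
    have a Phred score *strictly below* the per-sample threshold T (see
    :func:`quality_threshold`).  Both inequalities are strict, matching the
    wording "more than 10% of nucleotides achieving a quality score below".
    T is computed once, on the raw read set, so the filter is idempotent;
    pass ``threshold`` explicitly to reuse a precomputed T.
    """
    if not reads:
        raise ValueError("quality_filter: empty input")
    if threshold is None:
        threshold = quality_threshold(reads, quartile=quartile)
    if any(r.quality is None for r in reads):
        raise NoQualityDataError("no quality data: one or more reads lack Phred scores")
    kept: list[ReadRecord] = []
    for r in reads:
        q = np.asarray(r.quality)
        low_fraction = float(np.mean(q < threshold))
        if low_fraction <= max_low_fraction:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def merge_clonotypes(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    """Merge clonotypes with identical (cdr3_aa, v_call, j_call), summing counts."""
    merged: dict[tuple[str, str, str], int] = {}
    order: list[tuple[str, str, str]] = []
    for c in clonotypes:
        key = (c.cdr3_aa, c.v_call, c.j_call)
        if key not in merged:
            order.append(key)
            merged[key] = 0
        merged[key] += c.count
    return [
        Clonotype(cdr3_aa=k[0], count=merged[k], v_call=k[1], j_call=k[2])
        for k in order
    ]


def _annotation_lookup(annotations) -> Mapping[str, Mapping]:
    if isinstance(annotations, pd.DataFrame):
        return {
            str(row["read_id"]): row for _, row in annotations.iterrows()
        }
    return annotations


def translate_and_filter(
    reads: Sequence[ReadRecord],
    annotations,
) -> tuple[list[Clonotype], QCReport]:
    """Translate annotated CDR3 spans and drop non-functional sequences.

    ``annotations`` maps read_id -> mapping with keys ``cdr3_start``,
    ``cdr3_end`` (1-based inclusive), ``functional``, ``v_call``, ``j_call``;
    a DataFrame with a ``read_id`` column is also accepted.  Functional reads
    are translated with the standard genetic code; reads whose span is not a
    multiple of three are rejected with a warning, and translations containing
    a stop codon are treated as non-functional.  Identical
    (cdr3_aa, v_call, j_call) are merged with summed counts.
    """
    lookup = _annotation_lookup(annotations)
    qc = QCReport()
    out: list[Clonotype] = []
    for r in reads:
        try:
            ann = lookup[r.read_id]
        except KeyError:
            raise KeyError(f"no annotation for read {r.read_id!r}") from None
        if not _parse_bool(ann["functional"]):
            qc.bump("non_functional")
            continue
        start, end = int(ann["cdr3_start"]), int(ann["cdr3_end"])
        span = r.nucleotide_seq[start - 1 : end]
        if len(span) % 3 != 0:
            warnings.warn(
                f"read {r.read_id!r}: CDR3 span length {len(span)} not divisible "
                "by 3 on a functional read; rejected"
            )
            qc.bump("bad_span")
            continue
        aa = str(Seq(span).translate())
        if "*" in aa:
            qc.bump("internal_stop")
            continue
        out.append(
            Clonotype(
                cdr3_aa=aa,
                count=1,
                v_call=str(ann["v_call"]),
                j_call=str(ann["j_call"]),
            )
        )
    return merge_clonotypes(out), qc


# ---------------------------------------------------------------------------
# Clonotype tables
# ---------------------------------------------------------------------------

def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _detect_dialect(columns: Sequence[str]) -> str:
    cols = set(columns)
    if {"sample", "cdr3_aa", "count"} <= cols:
        return "native"
    if {"junction_aa", "duplicate_count", "productive"} <= cols:
        return "airr"
    raise ValueError(
        "cannot detect table dialect: need native columns "
        f"{NATIVE_COLUMNS} or AIRR columns {AIRR_COLUMNS}; got {sorted(cols)}"
    )


def read_clonotype_table(
    path: str | Path,
    dialect: str = "auto",
    labels: Mapping[str, str] | None = None,
    locus: str | None = None,
) -> tuple[Cohort, QCReport]:
    """Read a tab-delimited clonotype table into a validated :class:`Cohort`.

    Two column dialects are accepted: the native one
    (``sample, cdr3_aa, count, v_call, j_call, functional``) and the AIRR
    Rearrangement one (``junction_aa, duplicate_count, v_call, j_call,
    productive`` with the sample in ``repertoire_id`` or ``sample``).
    Non-functional rows and rows failing clonotype invariants are dropped and
    counted in the QC report; a sample left empty after filtering is a hard
    error.  Optional ``label`` and ``locus`` columns are honoured; ``labels``
    (a sample -> label manifest) overrides the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)
    if dialect == "native":
        required = ["sample", "cdr3_aa", "count", "v_call", "j_call", "functional"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        rename = {}
    elif dialect == "airr":
        required = ["junction_aa", "duplicate_count", "v_call", "j_call", "productive"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required AIRR column(s): {missing}")
        sample_col = "repertoire_id" if "repertoire_id" in df.columns else "sample"
        if sample_col not in df.columns:
            raise ValueError("missing required column(s): ['repertoire_id']")
        rename = {
            sample_col: "sample",
            "junction_aa": "cdr3_aa",
            "duplicate_count": "count",
            "productive": "functional",
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = df.rename(columns=rename)

    qc = QCReport()
    samples: dict[str, list[Clonotype]] = {}
    sample_meta: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        sid = str(row["sample"])
        if sid not in samples:
            samples[sid] = []
            sample_meta[sid] = {
                "label": str(row["label"]) if "label" in df.columns else "unknown",
                "locus": str(row["locus"]) if "locus" in df.columns else None,
            }
            order.append(sid)
        try:
            if not _parse_bool(row["functional"]):
                qc.bump("non_functional")
                continue
            clono = Clonotype(
                cdr3_aa=str(row["cdr3_aa"]),
                count=int(row["count"]),
                v_call=str(row["v_call"]) if pd.notna(row["v_call"]) else "",
                j_call=str(row["j_call"]) if pd.notna(row["j_call"]) else "",
            )
        except (ValueError, TypeError):
            qc.bump("invalid_rows")
            continue
        samples[sid].append(clono)

    row_locus = next(
        (m["locus"] for m in sample_meta.values() if m["locus"]), None
    )
    cohort_locus = locus or row_locus or "TRG"
    reps = []
    for sid in order:
        clonos = merge_clonotypes(samples[sid])
        if not clonos:
            raise ValueError(f"sample {sid!r} has no functional clonotypes after filtering")
        label = sample_meta[sid]["label"]
        if labels is not None:
            label = labels.get(sid, label)
        if label not in ("case", "control", "unknown"):
            label = "unknown"
        reps.append(
            Repertoire(sample_id=sid, clonotypes=clonos, locus=cohort_locus, label=label)
        )
    return Cohort(reps, locus=cohort_locus), qc


def write_clonotype_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the native tab-delimited dialect (deterministic)."""
    rows = []
    for rep in cohort:
        for c in rep.clonotypes:
            rows.append(
                {
                    "sample": rep.sample_id,
                    "cdr3_aa": c.cdr3_aa,
                    "count": c.count,
                    "v_call": c.v_call,
                    "j_call": c.j_call,
                    "functional": "T" if c.functional else "F",
                    "label": rep.label,
                    "locus": rep.locus,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read Phred+33 FASTQ into :class:`ReadRecord` objects."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(
                read_id=rec.id,
                nucleotide_seq=str(rec.seq),
                quality=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        if r.quality is None:
            raise NoQualityDataError(f"read {r.read_id!r} has no quality scores")
        rec = SeqRecord(Seq(r.nucleotide_seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
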