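"""Synthetic repertoire cohorts with the structure the classifier exploits.

The generator emulates a duodenal biopsy TCR sequencing cohort: each sample
is a set of CDR3 amino-acid clonotypes (IMGT-style, cysteine-flanked, 8-25
residues) with Zipf-distributed read counts and V/J calls drawn
independently of diagnosis.  Two disease signals can be planted, mirroring
the biology the classifier is believed to detect:

* a shared short motif carried, at a configured CDR3 third, by a configured
  fraction of case reads — many related receptors sharing a non-germline
  motif across patients.  By default the *same* motif appears at a different
  third in controls at equal prevalence, so the signal is purely positional
  (the overall k-mer content of cases and controls matches, only the
  placement differs); set ``control_placement=None`` for a signal visible to
  non-positional k-mers as well.
* an optional set of shared "semi-invariant" clonotypes present in every
  control and depleted in cases — loss of an innate-like population.

Motifs replace residues rather than inserting, so CDR3 length distributions
stay label-independent; motif carriers in *both* classes are drawn from
CDR3s of length >= 3k+5 so their third assignment is unambiguous, again
identically in both classes.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import Clonotype, Cohort, ReadRecord, Repertoire, merge_clonotypes

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_V_SEGMENTS = tuple(f"TRGV{i}" for i in (2, 3, 4, 5, 8, 9, 10, 11))
DEFAULT_J_SEGMENTS = ("TRGJ1", "TRGJ2", "TRGJP1", "TRGJP2")


@dataclass(frozen=True)
class Motif:
    """A shared amino-acid motif planted in case samples.

    ``prevalence`` is the fraction of a case sample's reads carried by
    motif-bearing clonotypes.  ``control_placement`` places the same motif at
    a different third in control samples at the same prevalence (purely
    positional signal); ``None`` leaves controls motif-free.
    """

    sequence: str = "WSGYE"
    placement: str = "start"  # third in case samples
    prevalence: float = 0.9
    control_placement: str | None = "end"

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("motif prevalence must lie in [0, 1]")
        if self.placement not in ("start", "middle", "end"):
            raise ValueError(f"bad placement {self.placement!r}")
        if self.control_placement is not None and self.control_placement not in (
            "start",
            "middle",
            "end",
        ):
            raise ValueError(f"bad control_placement {self.control_placement!r}")


@dataclass(frozen=True)
class DepletionClone:
    """A shared clonotype present in controls and depleted in cases."""

    cdr3_aa: str
    v_call: str
    j_call: str
    frequency: float  # fraction of a control sample's reads


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the smaller of the two cohort designs the method was
    built for (11 cases vs 11 controls) at a modest sequencing depth, with a
    single strongly prevalent positional motif as the disease signal and no
    depletion set.
    """

    n_case: int = 11
    n_control: int = 11
    reads_per_sample: int = 1000
    clonotypes_per_sample: int = 150
    cdr3_lengths: tuple[int, ...] = tuple(range(8, 26))
    cdr3_length_weights: tuple[float, ...] | None = None  # default: peak near 14
    motifs: tuple[Motif, ...] = (Motif(),)
    carriers_per_motif: int = 10
    depletion_set: tuple[DepletionClone, ...] = ()
    depletion_factor: float = 0.1  # case frequency multiplier for depletion clones
    zipf_exponent: float = 1.2
    v_segments: tuple[str, ...] = DEFAULT_V_SEGMENTS
    j_segments: tuple[str, ...] = DEFAULT_J_SEGMENTS
    locus: str = "TRG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        max_len = max(self.cdr3_lengths)
        for m in self.motifs:
            if len(m.sequence) > max_len:
                raise ValueError(
                    f"motif {m.sequence!r} longer than the maximum CDR3 length {max_len}"
                )
            if 3 * len(m.sequence) + 5 > max_len and m.prevalence > 0:
                raise ValueError(
                    f"motif {m.sequence!r}: carrier CDR3s need length >= "
                    f"{3 * len(m.sequence) + 5} for unambiguous third placement"
                )


DEFAULT_DEPLETION_SET = (
    DepletionClone("CALWEVQELGKKIKVF", "TRGV4", "TRGJ1", 0.03),
    DepletionClone("CALWEVRELGKKIKVF", "TRGV4", "TRGJ1", 0.03),
    DepletionClone("CALWEAHYYKKLF", "TRGV4", "TRGJP1", 0.02),
)


def _length_weights(config: GeneratorConfig) -> np.ndarray:
    if config.cdr3_length_weights is not None:
        w = np.asarray(config.cdr3_length_weights, dtype=float)
        if len(w) != len(config.cdr3_lengths):
            raise ValueError("cdr3_length_weights must match cdr3_lengths")
    else:
        lengths = np.asarray(config.cdr3_lengths, dtype=float)
        w = np.exp(-((lengths - 14.0) ** 2) / (2 * 3.0**2))
    return w / w.sum()


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    inner = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
    return "C" + inner + "F"


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks**-exponent
    return p / p.sum()


def _embed_motif(cdr3: str, motif: str, placement: str) -> str:
    """Replace residues so the motif's first residue falls in the requested third."""
    L, k = len(cdr3), len(motif)
    b1 = math.ceil(L / 3)
    b2 = math.ceil(2 * L / 3)
    if placement == "start":
        pos1 = 2  # preserve the leading cysteine
    elif placement == "middle":
        pos1 = b1 + 1
    else:
        pos1 = L - k  # preserve the trailing residue
        if pos1 <= b2:
            raise ValueError(f"CDR3 length {L} too short for an end-placed {k}-mer")
    i = pos1 - 1
    return cdr3[:i] + motif + cdr3[i + k :]


def _make_sample(
    sample_id: str,
    label: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Repertoire:
    lengths = np.asarray(config.cdr3_lengths)
    weights = _length_weights(config)
    reads = config.reads_per_sample

    clonotypes: list[Clonotype] = []
    used = 0

    # shared semi-invariant clonotypes, depleted in cases
    for clone in config.depletion_set:
        f = clone.frequency * (config.depletion_factor if label == "case" else 1.0)
        n = int(round(reads * f))
        if n > 0:
            clonotypes.append(
                Clonotype(clone.cdr3_aa, n, clone.v_call, clone.j_call)
            )
            used += n

    # motif-bearing clonotypes (private backbones, shared motif)
    for motif in config.motifs:
        placement = motif.placement if label == "case" else motif.control_placement
        if placement is None or motif.prevalence == 0:
            continue
        n_motif_reads = int(round(reads * motif.prevalence))
        if n_motif_reads == 0:
            continue
        k = len(motif.sequence)
        ok = lengths >= 3 * k + 5  # any third can hold the motif unambiguously
        carrier_weights = weights * ok
        carrier_weights = carrier_weights / carrier_weights.sum()
        n_carriers = min(config.carriers_per_motif, n_motif_reads)
        counts = rng.multinomial(
            n_motif_reads, _zipf_probs(n_carriers, config.zipf_exponent)
        )
        for count in counts:
            if count == 0:
                continue
            L = int(rng.choice(lengths, p=carrier_weights))
            cdr3 = _embed_motif(_random_cdr3(rng, L), motif.sequence, placement)
            clonotypes.append(
                Clonotype(
                    cdr3,
                    int(count),
                    str(rng.choice(config.v_segments)),
                    str(rng.choice(config.j_segments)),
                )
            )
            used += int(count)

    # private background clonotypes
    n_background = max(1, config.clonotypes_per_sample - len(clonotypes))
    background_reads = max(0, reads - used)
    if background_reads > 0:
        counts = rng.multinomial(
            background_reads, _zipf_probs(n_background, config.zipf_exponent)
        )
        for count in counts:
            if count == 0:
                continue
            L = int(rng.choice(lengths, p=weights))
            clonotypes.append(
                Clonotype(
                    _random_cdr3(rng, L),
                    int(count),
                    str(rng.choice(config.v_segments)),
                    str(rng.choice(config.j_segments)),
                )
            )
    return Repertoire(
        sample_id=sample_id,
        clonotypes=merge_clonotypes(clonotypes),
        locus=config.locus,
        label=label,
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a labelled synthetic cohort, reproducible from the seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_case + config.n_control
    )
    reps = []
    for i in range(config.n_case):
        rng = np.random.default_rng(seeds[i])
        reps.append(_make_sample(f"case_{i + 1:02d}", "case", config, rng))
    for i in range(config.n_control):
        rng = np.random.default_rng(seeds[config.n_case + i])
        reps.append(_make_sample(f"ctrl_{i + 1:02d}", "control", config, rng))
    return Cohort(reps, locus=config.locus)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A label-free configuration: no motif, no depletion set.

    Cases and controls are then statistically exchangeable, which calibrates
    the pipeline's chance-level behaviour.
    """
    defaults = dict(motifs=(), depletion_set=(), seed=seed)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


# ---------------------------------------------------------------------------
# Synthetic reads (exercises the quality-filter stage)
# ---------------------------------------------------------------------------

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODONS_BY_AA.values():
    codons.sort()


def generate_reads(
    rep: Repertoire,
    seed: int = 0,
    low_quality_fraction: float = 0.2,
    low_base_fraction: float = 0.15,
    good_quality: int = 38,
    bad_quality: int = 10,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Reverse-translate a repertoire into reads with a two-tier quality model.

    Each clonotype emits one read per count, reverse-translated with uniform
    codon choice.  A fraction ``low_quality_fraction`` of reads is marked low
    quality: ``low_base_fraction`` of their bases (> the 10% rule) receive
    ``bad_quality`` scores, the rest ``good_quality``; good reads carry
    ``good_quality`` everywhere.  Returns the reads and an annotation table
    (read_id, cdr3_start, cdr3_end 1-based inclusive, functional, v_call,
    j_call) whose span covers the whole read.
    """
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []
    annotations: list[dict] = []
    i = 0
    for clono in rep.clonotypes:
        for _ in range(clono.count):
            nt = "".join(
                str(rng.choice(_CODONS_BY_AA[aa])) for aa in clono.cdr3_aa
            )
            read_id = f"{rep.sample_id}_r{i:06d}"
            i += 1
            reads.append(ReadRecord(read_id, nt, quality=None))
            annotations.append(
                {
                    "read_id": read_id,
                    "cdr3_start": 1,
                    "cdr3_end": len(nt),
                    "functional": True,
                    "v_call": clono.v_call,
                    "j_call": clono.j_call,
                }
            )
    n_bad = int(round(low_quality_fraction * len(reads)))
    bad_idx = set(rng.choice(len(reads), size=n_bad, replace=False).tolist())
    finished: list[ReadRecord] = []
    for j, r in enumerate(reads):
        L = len(r.nucleotide_seq)
        quality = np.full(L, good_quality, dtype=int)
        if j in bad_idx:
            n_low = math.ceil(low_base_fraction * L)
            low_pos = rng.choice(L, size=n_low, replace=False)
            quality[low_pos] = bad_quality
        finished.append(
            ReadRecord(r.read_id, r.nucleotide_seq, quality=tuple(int(q) for q in quality))
        )
    return finished, pd.DataFrame(annotations)
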