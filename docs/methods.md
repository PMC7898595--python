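# Methods

## Model and assumptions

The classifier assumes that disease-associated repertoires share many
*related* CDR3 amino-acid sequences — receptors that differ in backbone but
share short motifs — while the remaining repertoire is private to each
sample. Under that assumption, the frequency of short overlapping k-mers is
a denser, more transferable representation than whole clonotypes: a public
motif contributes the same feature in every carrier, however the flanking
residues vary. Positional annotation (which third of the CDR3 a k-mer
starts in) adds specificity when motif placement, not just content, carries
the signal.

Classification is deliberately clustering-shaped rather than a supervised
decision rule: samples are embedded, clustered, and the dendrogram is cut
into two clusters whose identity comes from the majority of known
diagnoses. The supervision enters only through parameter selection
(input type, k, PC subset) and cluster labelling, which keeps the method
honest about what the repertoire itself separates.

## Pipeline and numerical choices

1. **Ingestion** (`tcrkmer.io`). Reads may be quality-filtered: a read is
   removed when more than 10% of its bases score strictly below the
   per-sample threshold T, the 25th percentile (linear interpolation) of
   per-read mean base quality. T is computed once on the raw read set, so
   the filter is idempotent; the 75th percentile is available via
   `quartile="upper"` because the two readings of the source convention
   conflict. Functional annotated CDR3 spans (1-based inclusive, standard
   genetic code) are translated; non-functional reads, spans not divisible
   by three, and translations containing stop codons are dropped and
   counted in a QC report. Clonotype identity is (CDR3 aa, V call, J call):
   CDR3 alone would conflate convergent rearrangements, and segment calls
   are needed for the usage confound check. Clonotype tables are accepted
   in a native TSV dialect and the AIRR Rearrangement dialect.

2. **Featurisation** (`tcrkmer.featurize`). All len−k+1 overlapping windows
   per CDR3; a CDR3 shorter than k contributes nothing (QC-reported, not an
   error). Thirds split a CDR3 of length L at ceil(L/3) and ceil(2L/3); a
   window belongs to the third containing its first residue, an unambiguous
   rule for straddling windows. Feature counts are weighted by clonotype
   read count (the collapsing control covers the unweighted alternative)
   and L1-normalised per sample. Column order is lexicographic in
   (sequence, position), making matrices byte-reproducible. By
   construction, summing positional frequencies over the three thirds
   reproduces the non-positional frequencies exactly.

3. **Reduction and clustering** (`tcrkmer.cluster`). PCA is column-centred
   and unscaled — features already share the frequency scale, and variance
   scaling would inflate rare-k-mer noise (scaling is available by flag).
   At least max_pc+1 samples are required so components 1..max_pc exist.
   Signs are fixed (largest-magnitude loading positive) for backend
   reproducibility. Clustering is agglomerative with Euclidean distance;
   complete linkage is the default (average and Ward by flag) as the one
   linkage the source methodology states explicitly, for its V/J usage
   heatmap. Separation of a merge is the height of its parent merge minus
   its own height ("branch" separation); the alternative reading of the
   separation statistic as a density-based reachability distance was not
   adopted because it contradicts the vertical-gap description, and the
   flag name `branch` records the choice.

4. **Partition scoring** (`tcrkmer.cluster.best_partition`). Every merge,
   including the root, defines a candidate partition {members under the
   merge} vs {everyone else}. Majority labelling ties inside a cluster
   resolve to "case" (favouring sensitivity); metric ties across partitions
   resolve by accuracy, then sensitivity, then separation, then lowest
   merge index. Because the root partition labels the whole cohort by its
   majority class, training accuracy is bounded below by the max-class
   fraction.

5. **Selection and validation** (`tcrkmer.select`). The default grid is
   positional and plain k-mers for k = 4–9 plus full-length CDR3s, crossed
   with all 1023 subsets of PCs 1–10. Winners maximise training accuracy;
   the selected set maximises separation among winners, then falls back to
   grid order. LOOCV re-introduces the held-out sample leakage-free: its
   features are restricted to the training union (unseen features dropped
   *without* renormalising, so retained frequencies keep their meaning),
   it is projected into the training-fitted PCA, all n samples are
   re-clustered, and clusters are labelled by training labels only. If the
   held-out sample ends up in a cluster with no labelled member (a
   singleton), it takes the label of the nearer labelled-cluster centroid
   in the selected PC subspace. A `refit` mode, in which the feature union
   and PCA include the held-out sample, exists only for comparison.
   `classify_new` applies the same mechanics with previously selected
   parameters, mirroring the one-at-a-time classification of new biopsies.

6. **Confound checks** (`tcrkmer.confounds`). V/J usage (count-weighted,
   z-scored per segment with the population denominator, constant columns
   zeroed) and CDR3 length distributions are clustered with the same
   linkage and scored with the same partition machinery. Depth is
   controlled by downsampling every sample without replacement to the
   cohort-minimum total count (multivariate hypergeometric over clonotype
   counts; with-replacement by flag), clonal abundance by collapsing all
   counts to 1. Both transforms return ordinary cohorts and re-enter the
   identical classification path.

## Synthetic data generator

`tcrkmer.simulate` generates cohorts of labelled repertoires. Defaults
describe the study design the package is tested under: 11 cases and 11
controls, 1000 reads per sample, about 150 clonotypes per sample with
Zipf(1.2) clone sizes, CDR3 lengths 8–25 peaked near 14 (Gaussian weights,
sd 3), V/J calls uniform over eight V and four J segments independently of
label, and one shared 5-residue motif carried by clonotypes accounting for
90% of case reads at the CDR3 start.

By default the same motif appears in *controls* at the CDR3 end at equal
prevalence. This makes the planted signal purely positional: the total
k-mer content of the two classes matches and only the placement differs, so
the parameter search must prefer positional annotation for a reason rather
than by tie-break. Setting `control_placement=None` plants a motif visible
to both annotations. Motif carriers in both classes are drawn from CDR3s of
length ≥ 3k+5 so the start/end thirds can hold the motif unambiguously;
because the rule applies to both classes, length distributions stay
label-independent and the length confound check remains a true negative
control. Motifs replace residues rather than inserting, for the same
reason. An optional depletion set plants shared clonotypes at full
frequency in controls and at a configurable fraction in cases.

`generate_reads` reverse-translates a repertoire (uniform codon choice) and
emits per-base Phred scores from a two-tier model: good reads score 38 at
every base; a configured fraction of reads carries 15% of bases at 10, so
they fail the 10% rule whatever the sample threshold while good reads never
do.

What the generator does not model: real V(D)J recombination (no germline
segments, insertions or deletions), sequencing error in the nucleotide
sequence, FFPE fragmentation beyond the quality mixture, HLA structure, or
inter-patient depth variation (all samples share one read budget unless
configured otherwise). Passing tests therefore demonstrate that the
pipeline recovers the *kind* of structure it targets — shared positional
motifs and depleted public clones against a private Zipf background — not
that real biopsy cohorts separate.

## Problem sizes used in tests

The test-suite and the acceptance script run the pipeline at n = 22
samples, 1000 reads/sample, with the reduced grid k ∈ {4, 5} over PC
subsets of components 1–6; larger k and the PCs 1–10 search behave
identically and are covered at unit scale (the subset enumeration and
feature-space arithmetic are exact for k up to 9). Oracle comparisons use
200 random repertoires of up to 50 clonotypes and 100 random dendrograms of
up to 12 leaves; the downsampling distribution check aggregates 200 seeds.

## Known limitations

* Training accuracy from best-partition search is selection-biased: under
  label-independent data it sits well above the max-class fraction
  (≈ 0.7–0.8 at n = 22 over the reduced grid). Chance levels should always
  be judged by permuted-label LOOCV or by permutation nulls on a fixed
  dendrogram, as the negative-control tests do.
* With n samples PCA yields at most n−1 components, so cohorts need at
  least 11 labelled samples (12 for LOOCV) for the PCs 1–10 search.
* The two-cluster cut assumes a single dominant diagnostic axis; cohorts
  with strong secondary structure (batch, tissue) may split on it instead —
  the confound checks detect only the confounds they model.
* Frequencies of a projected new sample are not renormalised after dropping
  unseen features, a conservative choice that slightly shrinks such samples
  toward the origin of the training space.
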