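# Methods

This note documents the models, rules and numerical choices behind polyqc,
and what the synthetic test bed does and does not establish about real data.

## k-mer spectra copy-number QC

Canonical k-mers (lexicographic minimum of a word and its reverse
complement; k odd so the two can never tie) are counted exactly. For
k ≤ 31 each k-mer is packed into 64 bits (A=0, C=1, G=2, T=3, two bits per
base), so integer order equals lexicographic order and counting reduces to
`np.unique`; 31 < k ≤ 63 falls back to a string dictionary. Windows with
non-ACGT symbols are skipped. Exactness (no probabilistic sketches) is a
deliberate choice: desk-scale genomes do not need them and exact counts
admit brute-force oracle tests.

The spectra-cn matrix `M[m, c]` counts distinct k-mers with read
multiplicity m and assembly copy number c; column c_max (default 10) is
open-ended, row 0 holds assembly-only content (the artifact row). Two
conservation laws are asserted on every run: each row m ≥ 1 sums to the
read spectrum at m, and the entries at c ≥ 1 sum to the assembly's distinct
k-mer count.

**Error threshold.** The boundary between the sequencing-error peak and
genuine content is the first local minimum of the 3-point-smoothed
spectrum. The window of 3 is the minimal smoothing that suppresses
single-bin noise. If the spectrum does not descend from multiplicity 1
(error-free reads) or has no interior minimum (monotone histogram), the
configured default (2) is returned with a logged warning. The threshold is
auto-detected rather than fixed because the canonical published value
(multiplicity 12 for a 33× wheat run) is dataset-specific.

**Summary statistics.** `missing` = Σ_{m ≥ t} M[m, 0];
`artifact` = Σ_{c ≥ 1} M[0, c]; `completeness` = 1 − missing / Σ_{m ≥ t}
(defined as 1 with a warning when the denominator is empty).
`duplicated` counts k-mers at c ≥ 2 whose multiplicity sits in the
expected-single-copy band, which by default is [t, 1.5 × main peak) — the
band is a package choice (no published definition exists); k-mers from
repeats and conserved homoeologous regions sit above it and are not counted
as duplication artefacts.

## Redundancy filter

Scaffolds are processed in decreasing length (ties by id, for determinism).
Scaffolds at or above the length gate (default 500 bp) are always kept —
the filter targets *short, redundant* sequence only. A shorter scaffold is
removed iff ≥ `redundancy_threshold` (default 0.95) of its distinct k-mers
(k = 31) already occur in the retained set. An optional absolute length
tier below which scaffolds are dropped outright is off by default. The
report carries each removal's redundant fraction, N50 before/after
(standard definition, verified against brute force) and the number of
distinct k-mers present only in removed scaffolds. At threshold 1.0 no
unique k-mer can be lost, and the filter is idempotent because a kept
scaffold's redundant fraction against its predecessors never changes.

## Genetic-map anchoring

Markers are matched as exact, full-length, strand-aware substrings; markers
hitting more than `max_hits` (default 2) scaffolds are excluded as
multi-locus. Classification order: one bin → class 1; several bins of one
chromosome → 2; several chromosomes of one homoeologous group → 3 (group
conflicts take precedence over generic conflicts); otherwise → 4. Tags:
a class-1 scaffold absent from the prior chromosome-arm table → 5; class-1
or class-2 scaffolds whose prior arm names a different chromosome → 6 or 7.
Both the base class and the final tag are reported, because published
counts list them separately; the 5/6 tags are fractions of uniquely
anchored scaffolds and the 7 tag of ambiguously anchored ones, while
classes 1–4 are fractions of all scaffolds. When no prior-arm table exists
at all the tags are disabled (otherwise every class-1 scaffold would be
tagged 5). cM bins compare exactly (they are categorical labels in
POPSEQ-style maps, not measurements with a tolerance).

## Triad expression analysis

TPM follows the standard definition (reads per kilobase, rescaled so each
sample sums to 10⁶). A triad is *expressed* in a condition when at least
one member's replicate-mean tpm reaches the 2-tpm floor; an expressed triad
is *unbalanced* when the maximum member mean strictly exceeds
`ratio_threshold` (default 2) times the minimum. The ratio rule is the
package's choice of balance criterion and is configurable; each condition
is assessed on its stress replicate means plus one pooled control
assessment.

Stress calls use fold changes on replicate means with a pseudocount of 0.5
added to both means (guarding zero expression without a test statistic,
since the thresholds are stated on fold change): strictly greater than
2 → UP, strictly less than 0.5 → DOWN, otherwise FLAT — a fold change of
exactly 2.0 or 0.5 is FLAT. The triad pattern is a pure function of the
three calls: no DE member → not-DE; DE members in both directions →
opposite; otherwise 1-DE / 2-DE-same / 3-DE-same by count. The taxonomy is
exhaustive and mutually exclusive over the 27 call triples (enumerated in
tests).

Hotspots are genetic bins whose median gene tpm in a tissue strictly
exceeds 20. Translocation detection: a triad with all three members
anchored is an outlier when exactly one member's chromosome lies outside
the homoeologous group shared by the other two (triads whose three members
disagree entirely are not called — one outlier must be identifiable).
Outliers are grouped by (outlier's bin, homoeologously expected
chromosome); groups with ≥ 3 supporting triads are reported, largest first.

## Gene confidence, annotation overlap, splicing, NMD

A gene is LC when its homolog coverage is below 0.60, when it lacks any
wheat transcript support, or when it is repeat associated (an input flag —
repeat annotation is out of scope); all applicable reasons are reported in
that order. HC genes get P1 at coverage ≥ 0.80 and T1 (full-length PacBio)
or else T2 (full RNA-seq support). Transfer filtering keeps alignments with
coverage ≥ 0.90 *and* identity ≥ 0.95, both inclusive.

Annotation overlap is strand-aware (antisense overlap counts as missing:
antisense loci are annotated separately from the coding comparison).
*Identical* means equal intron chains; *contained* means the reference
chain occurs as a contiguous sub-chain of a query transcript within its
span (monoexonic references are contained when they fit inside one query
exon); any other same-strand overlap is *structurally different*. A query
gene overlapped by two or more reference genes is flagged as a putative
fusion. Fractions count reference genes, not transcripts.

Splicing events compare an alternative isoform to the representative:
IR — an exon spans an intron of the other transcript; ES — an internal
exon absent from the other transcript, which runs a single intron across it
with shared outer boundaries; MXE — two non-overlapping internal exons,
each exclusive to one transcript, with shared flanking-intron outer
boundaries; A5SS/A3SS — intron pairs sharing exactly one boundary, labelled
in mRNA orientation (the genomic-left intron end is the donor on '+', the
acceptor on '−'). A shared-one-boundary pair is *not* called A5/A3 when a
complete exon of either transcript lies inside the differing region — that
configuration is ES or MXE and would otherwise be double-counted. One
transcript pair may legitimately yield several events; a transcript
compared with itself yields none.

NMD: a transcript is flagged when the 3' end of its CDS lies strictly more
than 50 nt (configurable) upstream of the last exon–exon junction in mRNA
coordinates — the standard distance rule. Monoexonic transcripts are never
flagged; transcripts without CDS are not evaluable and return False.

## Synthetic data generator

The generator emulates the structure the pipeline analyses, not any real
genome's content. Defaults: 210 triads over 3 subgenomes × 7 chromosome
groups (~2 Mb); genes of four 198-bp exons (CDS in frame, GT/AG introns of
120 bp) copied from one ancestral sequence per subgenome with independent
per-base substitutions at the divergence rate (default 0.03, so any two
homoeologs differ at ≈ 2d(1−d) + ⅔d² of sites — Binomial counts by
construction); intergenic spacers carry insertions from a per-seed library
of five random 1–5 kb repeat elements, each flanked by identical 5-bp
target-site duplications, filling 15% of the genome. The repeat library is
generated de novo per seed rather than taken from a curated database: the
structural role (multi-copy k-mer content, TSD-flanked insertions) is what
matters for testing. All output is byte-deterministic for a fixed seed.

Reads are substitution-only (the k-mer QC stage is substitution-sensitive;
indels would add no test power) with source coordinates in read names so
error rates are verifiable without alignment. Fragment starts are drawn
with one read length of overhang beyond the chromosome ends and clamped to
the boundary, so terminal k-mer windows receive full coverage — on
megabase-scale test chromosomes, taper-off at ends would otherwise dominate
the artifact/missing statistics that the QC stage is meant to isolate.

The genetic map samples one unique 51-bp marker per gene (uniqueness
checked genome-wide against both strands; at divergence 0 homoeologs are
identical and marker generation correctly fails). Chromosomes are cut into
per-bin scaffolds, making every marker-bearing scaffold uniquely
anchorable in the noise-free setting. A planted translocation mimics a
rearrangement segregating in the mapping population: the affected block
keeps its physical position (its markers still match there) while its
markers are recorded in a novel bin on another chromosome — exactly the
situation that produces outlier triads when the map is built on different
germplasm than the assembly.

Expression counts are negative binomial (variance μ + αμ², default
dispersion α = 0.1, dispersion 0 yields rounded means) around lognormal
triad baselines (median ≈ 150 counts) with bounded member jitter
(0.8–1.25×, so max/min < 2 keeps unplanted triads balanced). Pattern and
event mixes are apportioned by largest remainder, so planted proportions
are exact and only assignment order and directions are random. Planted
stress folds default to 3.0× (UP) and 0.3× (DOWN): comfortably beyond the
2×/0.5× call boundaries so the planted truth remains recoverable at
realistic overdispersion, per the generator's stated purpose of
unambiguous calls; boundary behaviour is studied by overriding the folds.
Planted constitutive imbalance multiplies one member by 4×. Note that a
planted stress response itself unbalances a triad in that condition — as
in real data — so constitutive balance labels are recovered exactly only
under a flat (all not-DE) pattern mix; tests use that setting.

## What passing tests show — and what they do not

The synthetic bed establishes correctness of the computations: exact
agreement with brute-force oracles, conservation laws, recovery of planted
truth in noise-free settings, and recovery within binomial sampling bounds
at realistic dispersion. It does not emulate sequencing quality profiles,
indels, GC bias, mate-pair structure, realistic repeat phylogenies, or the
library-size and batch structure of real RNA-seq experiments, so passing
tests demonstrate algorithmic correctness, not robustness to those
artefacts. Problem sizes in tests and in the acceptance script (genomes of
130–500 kb, 30× coverage, 500 triads, ~100 genes for event mixes) are the
package's desk-scale defaults, chosen to leave non-trivial k-mer
multiplicity structure while every stage completes in seconds.

## Numerical and degenerate-input choices

* Canonical order ties cannot occur (k odd); even k is rejected.
* Scaffold-length ties in the redundancy filter break lexicographically.
* A scaffold shorter than k contributes no k-mers (logged) and is kept.
* Completeness over an empty denominator is 1.0 with a warning.
* classify_balance boundary (max exactly = threshold × min) is balanced;
  call boundaries (exactly 2×/0.5×) are FLAT; the NMD boundary (exactly
  50 nt) is not flagged; transfer bounds (exactly 0.90/0.95) are kept —
  strict vs inclusive follows the wording of each rule.
* Fewer than 2 replicates warns and proceeds on single-sample means;
  a condition without control samples is an error.
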