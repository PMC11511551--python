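# Methods

This note documents the models and conventions ssrkit implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was genuinely
open.

## SSR detection

A perfect SSR is a maximal run of a primitive motif (one not itself a
repetition of a shorter word) of length 1–6 nt. Detection scans each
period independently, extending a run while `s[j] == s[j-k]`, and reports
only complete motif copies: a run of 13 bases with period 2 is reported
as six repeats over 12 bases. Coordinates are 1-based inclusive
throughout, matching the MISA convention most downstream tools expect.

Default thresholds: dinucleotide motifs ≥ 6 repeats; tri- through
hexanucleotide motifs ≥ 5. Mononucleotide runs are excluded by default
(threshold 10 when enabled) because homopolymers are dominated by
sequencing artefacts and are rarely used as markers; both settings are
configurable per motif length.

Rules where conventions diverge between tools:

- **Shortest-period rule.** A run whose motif is reducible (ATAT) is
  reported only at the shortest period (AT), preventing double counting.
- **Cross-period overlaps.** When maximal runs of different periods
  overlap, the longer span wins; on a span tie the shorter period wins;
  remaining ties go to the leftmost start. This makes output
  deterministic and order-independent.
- **Phase.** The motif is reported as the first k-mer of the run, and
  motif classes pair a motif only with its reverse complement — cyclic
  rotations are distinct classes (GA/TC ≠ AG/CT), as in genome-survey
  motif tables.
- **Ambiguity codes.** IUPAC codes are legal input but never inside a
  reported run; a run is truncated at the first ambiguous base.

Compound SSRs chain consecutive perfect runs whose gap is ≤ `max_linker`
(default 100 nt, **inclusive**; chaining is transitive). Summaries count
a compound locus once (`n_total = standalone perfect + compounds`) and
separately report the tally of all perfect runs including compound
members (`n_motifs`), since published totals of "SSR loci" and "motifs"
differ exactly by this distinction.

The miner is validated against an exhaustive sliding-window oracle
(every position × period tested by direct slice comparison) on random
and adversarial sequences, and against planted ground truth.

## Region assignment

From a GFF3 annotation, each transcript contributes exon intervals;
introns are the gaps between consecutive exons of the same transcript;
5'/3' UTR features, when present, take precedence over the exon category
for the bases they cover (a UTR base is also an exon base in GFF3, and a
six-way partition needs a winner — UTR was chosen because UTR SSRs are
reported as a distinct biological class). Categories are unioned across
transcripts and genes. An SSR overlapping ≥ 1 bp of a category counts as
overlapping it; a span overlapping two or more final categories is
`multi_mapped`; anything outside every gene span is `intergenic`; spans
on sequences absent from the annotation are `unplaced` and counted
separately. Strand is ignored — region identity here is
strand-independent. Both the precedence rule and the ≥ 1 bp overlap
threshold are stated choices, not universal conventions.

## Primer screening

The screening contract is four inclusive ranges applied to both primers
plus the product: length 18–25 nt, Tm 57–62 °C, product 120–400 bp, GC
40–60 %. Melting temperature defaults to nearest-neighbor thermodynamics
(Allawi & SantaLucia 1997 unified parameters, 50 mM Na⁺, 25 nM each
strand, entropic salt correction — Biopython's `Tm_NN` defaults, echoed
into output metadata); the Wallace 2(A+T)+4(G+C) rule is available as a
fallback for quick estimates. Full primer optimization (penalty
weighting, dimer/hairpin structure) is deliberately out of scope: the
module validates and enumerates constraint-satisfying candidates, which
is the part of the assay design that carries over between tools.

The TP-M13 tail stored as the default is the 19-letter sequence
`TGTAAAAACGACGGCCAGT` used verbatim by the assay this toolkit targets
(despite being conventionally described as an "18 bp" tail); the
canonical 18-nt M13(−21) sequence `TGTAAAACGACGGCCAGT` is available as
`M13_TAIL_CANONICAL`. Tailing is guarded against double application and
adds exactly the tail length to the expected fragment size, which
matters when binning raw sizes.

## Allele binning

True microsatellite alleles differ by whole motif copies, so raw
capillary sizes are snapped to the ladder `reference + k·motif_length`.
A size is assigned to the nearest rung when its offset is strictly less
than half the motif length; a size exactly halfway between rungs is
flagged ambiguous and never silently assigned — at that point the data,
not the software, is undecided.

## Diversity statistics

For allele frequencies *p₁…p_k* estimated from 2n gene copies (each
non-missing diploid call contributes two copies; n is the per-locus
count of non-missing individuals):

- Ne = 1/Σp², I = −Σp ln p (natural log),
- He = [2n/(2n−1)]·(1−Σp²) (Nei 1978 unbiased),
- PIC = 1 − Σp² − Σ_{i<j} 2pᵢ²pⱼ² (Botstein), computed as
  1 − Σp² − [(Σp²)² − Σp⁴],
- Ho = heterozygous fraction of non-missing individuals.

These are the POPGENE/PowerMarker conventions; the anchor validation is
that deterministic panels with exact allele counts (14,10), (8,6,6,2,2),
(22,2) over 24 copies reproduce the corresponding published marker rows
— all four statistics simultaneously — to 4 decimals. Legacy software
often reports mean homozygosity under the label "Ho"; the
`ho_complement_of_he` property (1 − He) reproduces that column so
published tables can be matched, while `ho` is the true observed
heterozygosity.

Hs is the average over populations and loci of within-population gene
diversity 1 − Σp²; since the estimator convention in legacy reports is
ambiguous, both the plain and the 2n/(2n−1)-corrected variants are
exposed (`unbiased=` flag), with the plain form as default. Populations
of size one are excluded with a warning. Rounding to 4 decimals
(round-half-even) happens only at report time.

## Clustering

Band matrices are binary over (locus, fragment-size) columns; a sample's
bands at a locus are the union of its two alleles, so an A/A homozygote
and an A/B heterozygote share the A band. Similarity is simple matching,
(a+d)/(a+b+c+d): **shared absences count as matches**. This is the
defining difference from Jaccard and it changes results — with many rare
bands SM inflates similarity between samples that merely both lack them.
It is used here because it is the standard coefficient for this assay
type.

UPGMA operates internally on distance 1−S with size-weighted average
linkage and reports fusion levels on the similarity scale. Ties in the
minimum distance are broken by the smallest (row, column) cluster index
pair after an initial lexicographic sort of sample labels, making output
deterministic across platforms; on tie-free input the tree equals
reference average-linkage implementations exactly (topology and
heights), which the tests assert against an independent implementation.
Newick export places leaves at depth h/2 of each fusion distance h, so
cophenetic distances read off the tree equal the fusion levels. The
cophenetic correlation is the Pearson r between upper-triangle entries
of the tree-implied and observed similarity matrices; it requires ≥ 3
leaves and returns 1 for exactly ultrametric input.

## Core-marker search

Discrimination compares band patterns (not diploid genotypes) by
default, matching how fingerprints are read off a trace; a
strict-genotype mode is available, and can separate pairs the band view
cannot. A missing call makes every comparison involving that sample
indeterminate, so the affected subsets count as non-discriminating —
the conservative choice for an identification assay. The search
enumerates subsets in increasing size, skipping supersets of
already-found sets (which enforces minimality) and pre-filtering with
per-marker separated-pair sets; it is validated against unpruned brute
force. Results are sorted by size then label.

## Synthetic fixtures

`generate_genome` assembles planted repeat runs between spacers
rejection-sampled until they contain no qualifying run at the active
thresholds; junctions are additionally guarded (a spacer may not begin
with the preceding motif's first base, and the base before a plant is
flipped if it would extend the run leftward), and the assembled sequence
is audited by an internal exhaustive scan with retry. The planted truth
table is therefore exact: mining it back is a fixed point. Gene models
are single-transcript, forward-strand, with UTRs inside the terminal
exons, and can embed an SSR mid-region to create region-assignment truth.

`generate_panel` draws diploid genotypes allele-by-allele under
Hardy–Weinberg proportions within each population; fragment sizes are
`reference + index·motif_length`. A deterministic count-placement mode
lays out exact allele counts (pairing copy i with copy i+n) for tests
that need integer count vectors rather than samples.

What the generators do **not** emulate: mutation (no stepwise or other
SSR evolution model), linkage between loci, null alleles, stutter or
size-calling error, population structure beyond independent frequency
vectors, and real genomic base composition (spacers are i.i.d. with a
GC knob). Passing tests therefore demonstrate algorithmic correctness on
idealized data, not robustness to the measurement artefacts of real
capillary genotyping.

## Problem sizes in the test suite

The validation suite runs entirely at desk scale, chosen so the whole
suite completes in seconds: miner-oracle equivalence uses > 100 random
sequences of 0.8–3 kb plus adversarial constructions up to ~18 kb;
clustering comparisons use 50 random 8×8 matrices; core-set search uses
12-sample × 12-marker panels with subsets up to size 3; estimator checks
use 1000 replicate panels of 500 individuals. Genome-scale mining
results depend on multi-gigabase inputs and are represented by the
density arithmetic and the property-based checks above.

## Known limitations

- Only perfect repeats are detected; mismatch-tolerant (imperfect) SSRs
  are out of scope.
- Region assignment ignores strand and unions transcripts; an
  isoform-aware assignment could classify differently.
- The primer module screens candidates; it does not rank them or check
  secondary structure.
- SM similarity and UPGMA are reproduced as the assay's standard
  workflow; neither is a model-based estimate of genetic distance, and
  no bootstrap support is computed.
- The core-set search is exhaustive up to `max_size` and intended for
  panels of tens of markers, not hundreds.
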