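# ssrkit

A Python toolkit for the genome-to-fingerprint microsatellite (SSR)
workflow used in plant cultivar and provenance identification: mine
perfect and compound SSRs from a genome, classify motifs, place loci in
genic regions, screen primer constraints, compute co-dominant diversity
statistics, cluster samples by band similarity, and search for minimal
core-marker sets that give every sample a unique DNA fingerprint.

It is aimed at marker developers working with species — bamboos are the
motivating case — where morphology cannot separate closely related
materials and co-dominant SSR panels read by capillary electrophoresis
are the practical assay.

## What it computes

**Mining.** A perfect SSR is a maximal uninterrupted tandem run of a
1–6 nt motif meeting per-motif-length repeat thresholds (defaults:
dinucleotides ≥ 6 repeats, tri- to hexanucleotides ≥ 5). Runs separated
by ≤ 100 nt are chained into compound SSRs. Motifs are reported in first
phase and grouped with their reverse complement (GA/TC stays distinct
from AG/CT); a run divisible into a shorter period is reported at the
shortest period only.

**Diversity statistics** for a locus with allele frequencies
*p₁ … p_k* over *n* diploid individuals:

- Na = *k*, the observed number of alleles
- Ne = 1 / Σpᵢ² (effective number of alleles)
- I = −Σ pᵢ ln pᵢ (Shannon's information index)
- Ho = fraction of heterozygous individuals
- He = [2n / (2n − 1)] · (1 − Σpᵢ²) (Nei's unbiased expected heterozygosity)
- PIC = 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ² (Botstein's polymorphic information content)
- Hs = mean within-population gene diversity 1 − Σpᵢ²

**Clustering and fingerprinting.** Genotypes flatten to a binary band
matrix; pairwise similarity is the simple-matching coefficient
(a + d)/(a + b + c + d), which counts shared absences; trees are UPGMA
and validated by the cophenetic correlation *r*. A *core primer set* is
a minimal marker subset whose combined band patterns distinguish every
pair of samples; the search is exhaustive over subset sizes with
superset pruning and is verified against unpruned brute force.

A synthetic-fixtures module generates genomes with planted SSRs (spacers
rejection-sampled to be repeat-free, so the planted table is exact ground
truth), matching GFF3 annotations, and Hardy–Weinberg or exact-count
genotype panels — every capability is testable offline.

## Worked example

`examples/02_diversity_stats.py` builds a deterministic 12-sample panel
whose three loci carry exact allele counts (14,10), (8,6,6,2,2) and
(22,2) over 24 gene copies, then runs the full genotype → frequency →
statistics path:

```
locus     Na      Ne       I      He     PIC
SSR52      2  1.9459  0.6792  0.5072  0.3680
SSR522     5  4.0000  1.4735  0.7826  0.7078
SSR41      2  1.1803  0.2868  0.1594  0.1411
total alleles: 9; mean PIC 0.4056
PIC classes: {'low(<0.25)': 1, 'moderate': 1, 'high(>0.5)': 1}
```

SSR522 (five alleles, fairly even frequencies) is a highly informative
marker (PIC > 0.5); SSR41 is nearly fixed (22 of 24 copies are one
allele), so it contributes almost nothing to discrimination
(PIC < 0.25). The other examples mine a planted genome
(`01_mine_ssrs.py`), cluster a simulated panel and print the Newick tree
with its cophenetic *r* (`03_cluster_samples.py`), and enumerate minimal
core-marker sets on an engineered fingerprint panel
(`04_core_markers.py`).

A thin CLI mirrors the library:

```sh
ssr mine --fasta genome.fa --out mined/
ssr stats --genotypes panel.tsv --pops pops.tsv --out stats/
ssr cluster --genotypes panel.tsv --out tree.nwk
ssr fingerprint --genotypes panel.tsv --max-core-size 3 --out fp/
ssr run --config run.toml --out results/
```

## Layout

- `src/ssrkit/mining.py` — perfect/compound SSR detection, motif classes, summaries
- `src/ssrkit/regions.py` — GFF3-based region assignment (5'UTR/3'UTR/exon/intron/intergenic/multi-mapped)
- `src/ssrkit/primers.py` — flank extraction, constraint screening, Tm, TP-M13 tailing
- `src/ssrkit/popgen.py` — allele binning, frequencies, Na/Ne/I/Ho/He/PIC/Hs
- `src/ssrkit/clustering.py` — band matrices, SM similarity, UPGMA, cophenetic r
- `src/ssrkit/fingerprint.py` — fingerprint profiles, core-set search
- `src/ssrkit/simulate.py` — synthetic genomes and genotype panels
- `src/ssrkit/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats, config, end-to-end runner
- `docs/methods.md` — models, estimators, numerical choices, limitations
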