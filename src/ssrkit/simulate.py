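"""Synthetic fixtures: genomes with planted SSRs and genotype panels.

Everything downstream is testable without external downloads: genomes are
assembled from planted repeat runs separated by spacers that are
rejection-sampled until repeat-free at the active mining thresholds, so
the planted truth table is exact ground truth (no accidental SSRs, no
boundary extensions).  Gene models with exon/intron/UTR layout can embed
SSRs in a chosen region, producing a matching GFF3 with known region
truth.  Genotype panels are drawn under Hardy-Weinberg proportions from
specified allele-frequency vectors, or built by deterministic count
placement when exact allele counts are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mining import MiningConfig, PerfectSSR, _is_primitive
from .popgen import GenotypeMatrix, Locus

__all__ = [
    "PlantedSSR",
    "CompoundPlant",
    "GenePlant",
    "PlantSpec",
    "GenomeFixture",
    "generate_genome",
    "LocusSpec",
    "PanelSpec",
    "generate_panel",
]


# ---------------------------------------------------------------------------
# Genome fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSSR:
    """One perfect repeat to embed: ``motif`` tandemly repeated ``repeats`` times."""

    motif: str
    repeats: int

    @property
    def sequence(self) -> str:
        return self.motif * self.repeats

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeats


@dataclass(frozen=True)
class CompoundPlant:
    """Several perfect repeats joined by linkers of the given lengths (nt)."""

    members: tuple[PlantedSSR, ...]
    linkers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.linkers) != len(self.members) - 1:
            raise ValueError("need one linker length per junction")


@dataclass(frozen=True)
class GenePlant:
    """A single-transcript gene model on the forward strand.

    The transcript is laid out as 5'UTR, exons alternating with introns,
    then 3'UTR; the UTRs are part of the first and last exon respectively
    (GFF3 convention).  ``ssr_in`` optionally embeds one SSR in the middle
    of a region: one of ``five_prime_UTR``, ``three_prime_UTR``, ``exon``
    (the coding part of exon 1), or ``intron`` (intron 1).
    """

    utr5_length: int = 60
    utr3_length: int = 60
    exon_lengths: tuple[int, ...] = (150, 150)
    intron_lengths: tuple[int, ...] = (120,)
    ssr_in: str | None = None
    ssr: PlantedSSR | None = None

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron between each pair of exons")
        if (self.ssr_in is None) != (self.ssr is None):
            raise ValueError("ssr_in and ssr must be given together")
        if self.ssr_in is not None and self.ssr_in not in {
            "five_prime_UTR", "three_prime_UTR", "exon", "intron",
        }:
            raise ValueError(f"unknown region {self.ssr_in!r}")


@dataclass
class PlantSpec:
    """Layout of one synthetic sequence: elements separated by clean spacers."""

    seq_id: str = "chr1"
    elements: Sequence[PlantedSSR | CompoundPlant | GenePlant] = ()
    spacer_length: int = 300
    spacer_gc: float = 0.45
    seed: int = 0


@dataclass
class GenomeFixture:
    """A generated genome with its exact planted truth."""

    sequences: dict[str, str]
    truth: list[dict]        # seq_id, start, end, motif, repeats, region, compound_id
    gff3: str

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fasta(self, width: int = 70) -> str:
        out = []
        for name, seq in self.sequences.items():
            out.append(f">{name}")
            out.extend(seq[i : i + width] for i in range(0, len(seq), width))
        return "\n".join(out) + "\n"

    def truth_ssrs(self) -> list[PerfectSSR]:
        return [
            PerfectSSR(t["seq_id"], t["start"], t["end"], t["motif"], t["repeats"])
            for t in self.truth
        ]


def _scan_has_run(seq: str, thresholds: dict[int, int]) -> bool:
    """Exhaustive check for any qualifying tandem run (generator-internal).

    Deliberately simple O(n*k*L) sliding scan, independent of the
    production miner, so spacer validation does not depend on the code it
    is meant to test.
    """
    n = len(seq)
    for k, min_rep in thresholds.items():
        need = k * min_rep
        for i in range(0, n - need + 1):
            motif = seq[i : i + k]
            if not _is_primitive(motif):
                continue
            if seq[i : i + need] == motif * min_rep:
                return True
    return False


def _random_spacer(
    rng: np.random.Generator,
    length: int,
    gc: float,
    thresholds: dict[int, int],
    avoid_first: str | None = None,
) -> str:
    """Repeat-free random spacer; optionally constrain its first base.

    ``avoid_first`` prevents the spacer from extending a repeat run that
    ends immediately before it (the first spacer base must differ from
    the first base of the preceding motif).
    """
    if length == 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _ in range(1000):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        if avoid_first is not None and seq[0] == avoid_first:
            continue
        if not _scan_has_run(seq, thresholds):
            return seq
    raise RuntimeError("could not sample a repeat-free spacer")


class _Assembler:
    """Accumulates sequence parts while tracking 1-based coordinates."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0  # length so far

    def add(self, part: str) -> tuple[int, int]:
        start = self.pos + 1
        self.parts.append(part)
        self.pos += len(part)
        return start, self.pos

    def sequence(self) -> str:
        return "".join(self.parts)


def generate_genome(
    spec: PlantSpec, config: MiningConfig | None = None
) -> GenomeFixture:
    """Assemble a synthetic sequence from a plant spec.

    Deterministic for a given seed.  The returned truth table lists every
    planted perfect run with its coordinates, its region category
    (``intergenic`` unless embedded in a gene), and a compound-group id
    when members were planted within merge distance of each other.

    After assembly the whole sequence is re-scanned with the internal
    exhaustive check; if a junction between a plant and a spacer produced
    an unplanned qualifying run, the spacers are re-sampled.
    """
    config = config or MiningConfig()
    thresholds = config.active_thresholds()
    rng = np.random.default_rng(spec.seed)

    for attempt in range(20):
        asm = _Assembler()
        truth: list[dict] = []
        gff_lines: list[str] = []
        gene_n = 0
        compound_n = 0
        state = {"avoid_first": None, "protected": 0}

        def spacer(length: int | None = None) -> None:
            asm.add(
                _random_spacer(
                    rng, spec.spacer_length if length is None else length,
                    spec.spacer_gc, thresholds,
                    avoid_first=state["avoid_first"],
                )
            )
            state["avoid_first"] = None

        def plant(ssr: PlantedSSR, region: str, compound_id: str | None = None) -> None:
            # A base just before the plant equal to the motif's last base
            # would shift the maximal run one position left (changing the
            # recorded start and phase); flip it when it sits in spacer
            # territory.
            if asm.parts and asm.pos > state["protected"] and asm.parts[-1]:
                prev = asm.parts[-1][-1]
                if prev == ssr.motif[-1]:
                    for base in "ACGT":
                        if base != ssr.motif[-1] and base != prev:
                            asm.parts[-1] = asm.parts[-1][:-1] + base
                            break
            start, end = asm.add(ssr.sequence)
            truth.append(
                dict(seq_id=spec.seq_id, start=start, end=end, motif=ssr.motif,
                     repeats=ssr.repeats, region=region, compound_id=compound_id)
            )
            state["avoid_first"] = ssr.motif[0]
            state["protected"] = asm.pos

        spacer()
        for element in spec.elements:
            if isinstance(element, PlantedSSR):
                plant(element, "intergenic")
            elif isinstance(element, CompoundPlant):
                compound_n += 1
                cid = f"c{compound_n}"
                for idx, member in enumerate(element.members):
                    if idx:
                        spacer(element.linkers[idx - 1])
                    plant(member, "intergenic", cid)
            elif isinstance(element, GenePlant):
                gene_n += 1
                gid = f"gene{gene_n}"
                gene_start = asm.pos + 1
                exon_spans: list[tuple[int, int]] = []

                def region_block(length: int, region: str) -> None:
                    if element.ssr_in == region and element.ssr is not None:
                        pad = max((length - element.ssr.length) // 2, 10)
                        spacer(pad)
                        plant(element.ssr, region)
                        spacer(pad)
                    else:
                        spacer(length)

                # exon 1 = 5'UTR + first coding block
                exon1_start = asm.pos + 1
                region_block(element.utr5_length, "five_prime_UTR")
                utr5_end = asm.pos
                region_block(element.exon_lengths[0], "exon")
                exon_spans.append((exon1_start, asm.pos))
                for i, intron_len in enumerate(element.intron_lengths):
                    region_block(intron_len, "intron" if i == 0 else "_intron")
                    ex_start = asm.pos + 1
                    last = i == len(element.intron_lengths) - 1
                    region_block(element.exon_lengths[i + 1], "_exon")
                    if last:
                        utr3_start = asm.pos + 1
                        region_block(element.utr3_length, "three_prime_UTR")
                    exon_spans.append((ex_start, asm.pos))
                if len(element.exon_lengths) == 1:
                    utr3_start = asm.pos + 1
                    region_block(element.utr3_length, "three_prime_UTR")
                    exon_spans[0] = (exon1_start, asm.pos)
                gene_end = asm.pos
                sid = spec.seq_id
                gff_lines.append(
                    f"{sid}\tssrkit\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\tID={gid}"
                )
                gff_lines.append(
                    f"{sid}\tssrkit\tmRNA\t{gene_start}\t{gene_end}\t.\t+\t.\t"
                    f"ID={gid}.t1;Parent={gid}"
                )
                for j, (s, e) in enumerate(exon_spans, 1):
                    gff_lines.append(
                        f"{sid}\tssrkit\texon\t{s}\t{e}\t.\t+\t.\t"
                        f"ID={gid}.t1.exon{j};Parent={gid}.t1"
                    )
                gff_lines.append(
                    f"{sid}\tssrkit\tfive_prime_UTR\t{gene_start}\t{utr5_end}\t.\t+\t.\t"
                    f"ID={gid}.t1.utr5;Parent={gid}.t1"
                )
                gff_lines.append(
                    f"{sid}\tssrkit\tthree_prime_UTR\t{utr3_start}\t{gene_end}\t.\t+\t.\t"
                    f"ID={gid}.t1.utr3;Parent={gid}.t1"
                )
            else:
                raise TypeError(f"unknown element type {type(element)!r}")
            spacer()

        sequence = asm.sequence()

        # Junction audit: mask every planted span, then require the rest of
        # the sequence (including plant/spacer boundaries, widened by the
        # largest window) to contain no qualifying run.
        masked = list(sequence)
        for t in truth:
            for p in range(t["start"] - 1, t["end"]):
                masked[p] = "N"
        if not _scan_has_run("".join(masked), thresholds) and not _boundary_extended(
            sequence, truth
        ):
            break
    else:
        raise RuntimeError("could not assemble a clean genome in 20 attempts")

    header = (
        "##gff-version 3\n"
        f"##sequence-region {spec.seq_id} 1 {len(sequence)}\n"
    )
    gff3 = header + "\n".join(gff_lines) + ("\n" if gff_lines else "")
    return GenomeFixture(sequences={spec.seq_id: sequence}, truth=truth, gff3=gff3)


def _boundary_extended(sequence: str, truth: list[dict]) -> bool:
    """True if any planted run extends beyond its recorded coordinates."""
    for t in truth:
        k = len(t["motif"])
        s, e = t["start"] - 1, t["end"]  # 0-based half-open
        if s - 1 >= 0 and sequence[s - 1] == sequence[s - 1 + k]:
            return True
        if e < len(sequence) and sequence[e] == sequence[e - k]:
            return True
    return False


# ---------------------------------------------------------------------------
# Genotype panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusSpec:
    """One marker: allele frequencies (or exact counts) on a size ladder.

    Allele ``i`` has fragment size ``reference_size + i * motif_length``.
    ``allele_counts`` switches the locus to deterministic count placement:
    the 2n gene copies are laid out exactly with those counts and paired
    into individuals by splitting the copy list in half (copy ``i`` with
    copy ``i + n``), which is reproducible and independent of any RNG.
    """

    name: str
    frequencies: tuple[float, ...] = ()
    motif_length: int = 2
    reference_size: int = 200
    allele_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.allele_counts is None:
            if not self.frequencies:
                raise ValueError("need frequencies or allele_counts")
            if abs(sum(self.frequencies) - 1.0) > 1e-9:
                raise ValueError("frequencies must sum to 1")

    def sizes(self, n_alleles: int) -> list[int]:
        return [self.reference_size + i * self.motif_length for i in range(n_alleles)]


@dataclass
class PanelSpec:
    """A sample panel: loci x populations, with an optional missing rate."""

    loci: Sequence[LocusSpec]
    populations: dict[str, int] = field(default_factory=lambda: {"pop1": 12})
    missing_rate: float = 0.0
    seed: int = 0


def generate_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Draw a diploid genotype panel.

    Returns the genotype matrix and a sample -> population mapping.
    Random loci are drawn allele-by-allele (Hardy-Weinberg) within each
    population; count-placement loci ignore the population split and the
    RNG entirely.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[str] = []
    pops: dict[str, str] = {}
    for pop, size in spec.populations.items():
        if size < 1:
            raise ValueError("population sizes must be >= 1")
        for i in range(size):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            pops[name] = pop

    n = len(samples)
    loci = [Locus(ls.name, ls.motif_length) for ls in spec.loci]
    calls: list[list[tuple[int, int] | None]] = [[None] * len(loci) for _ in range(n)]

    for j, ls in enumerate(spec.loci):
        if ls.allele_counts is not None:
            counts = ls.allele_counts
            if sum(counts) != 2 * n:
                raise ValueError(
                    f"locus {ls.name}: counts sum to {sum(counts)}, need {2 * n}"
                )
            sizes = ls.sizes(len(counts))
            copies = [s for s, c in zip(sizes, counts) for _ in range(c)]
            pairs = [(copies[i], copies[i + n]) for i in range(n)]
        else:
            sizes = np.asarray(ls.sizes(len(ls.frequencies)))
            draws = rng.choice(sizes, size=(n, 2), p=ls.frequencies)
            pairs = [tuple(sorted(map(int, d))) for d in draws]
        for i, pair in enumerate(pairs):
            a, b = sorted(pair)
            calls[i][j] = (int(a), int(b))

    if spec.missing_rate > 0:
        mask = rng.random((n, len(loci))) < spec.missing_rate
        for i in range(n):
            for j in range(len(loci)):
                if mask[i, j]:
                    calls[i][j] = None

    return GenotypeMatrix(samples=samples, loci=loci, calls=calls), pops
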