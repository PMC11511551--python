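"""Perfect and compound microsatellite (SSR) detection.

A perfect SSR is an uninterrupted tandem run of a 1-6 nt motif; a compound
SSR is a chain of perfect SSRs whose intervening linker sequences do not
exceed a configurable bound.  Detection follows the MISA conventions:
per-motif-length minimum repeat counts, 1-based inclusive coordinates, runs
truncated at ambiguity codes, and motifs reported in the phase in which the
run first occurs (so GA/TC and AG/CT remain distinct classes).

A run whose motif is itself a repetition of a shorter word (e.g. ``ATAT``)
is reported at its shortest period only.  When maximal runs of different
periods overlap, the longer span wins; on a span tie the shorter period
wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "MiningConfig",
    "PerfectSSR",
    "CompoundSSR",
    "MotifClass",
    "MiningSummary",
    "find_perfect_ssrs",
    "merge_compound",
    "canonical_motif_class",
    "reverse_complement",
    "summarize_mining",
    "frequency_per_mb",
]

#: MISA-style defaults: dinucleotide motifs must repeat >= 6 times,
#: tri- through hexanucleotide motifs >= 5 times.
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Default minimum run length for mononucleotide repeats when enabled.
DEFAULT_MONO_MIN_REPEATS = 10

_UNAMBIGUOUS = frozenset("ACGT")
_IUPAC = frozenset("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds governing SSR detection and compound merging.

    Parameters
    ----------
    min_repeats
        Minimum tandem repeat count per motif length (nt).  Lengths must
        lie in 1..6 and counts must be >= 2.
    max_linker
        Maximum gap (nt) between consecutive perfect SSRs merged into one
        compound SSR.  The bound is inclusive.
    include_mono
        Whether mononucleotide runs are mined.  When enabled and no
        threshold for length 1 is given, ``DEFAULT_MONO_MIN_REPEATS``
        applies.
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_linker: int = 100
    include_mono: bool = False

    def __post_init__(self) -> None:
        for length, count in self.min_repeats.items():
            if not 1 <= length <= 6:
                raise ValueError(f"motif length {length} outside 1..6")
            if count < 2:
                raise ValueError(f"min repeat count {count} < 2 for length {length}")
        if self.max_linker < 0:
            raise ValueError("max_linker must be >= 0")

    def active_thresholds(self) -> dict[int, int]:
        """Motif-length -> minimum-repeats map actually used for mining."""
        thresholds = {k: v for k, v in self.min_repeats.items() if k != 1}
        if self.include_mono:
            thresholds[1] = self.min_repeats.get(1, DEFAULT_MONO_MIN_REPEATS)
        return thresholds


@dataclass(frozen=True)
class PerfectSSR:
    """A maximal uninterrupted tandem repeat (1-based inclusive coords)."""

    seq_id: str
    start: int
    end: int
    motif: str
    repeats: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.repeats:
            raise ValueError("span does not equal motif length x repeats")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    def __str__(self) -> str:  # MISA-style notation
        return f"({self.motif}){self.repeats}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more perfect SSRs joined by linkers within the merge bound."""

    seq_id: str
    members: tuple[PerfectSSR, ...]
    linkers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("compound SSR needs >= 2 members")
        if len(self.linkers) != len(self.members) - 1:
            raise ValueError("need exactly one linker per junction")

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        parts = [str(self.members[0])]
        for gap, member in zip(self.linkers, self.members[1:]):
            parts.append(f"n{gap}" if gap else "*")
            parts.append(str(member))
        return "".join(parts)


SSRRecord = Union[PerfectSSR, CompoundSSR]


@dataclass(frozen=True)
class MotifClass:
    """A motif paired with its reverse complement.

    The display label puts the lexicographically smaller member first
    (``GA`` -> ``GA/TC``).  Cyclic rotations are *not* collapsed, so GA/TC
    and AG/CT are distinct classes, matching the phase-preserving
    convention of genome SSR surveys.
    """

    members: frozenset[str]
    label: str


def canonical_motif_class(motif: str) -> MotifClass:
    """Return the reverse-complement equivalence class of ``motif``.

    Raises
    ------
    ValueError
        If the motif is empty, longer than 6 nt, or contains a base
        outside A/C/G/T.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1..6")
    if not set(motif) <= _UNAMBIGUOUS:
        raise ValueError(f"ambiguous base in motif {motif!r}")
    rc = reverse_complement(motif)
    lo, hi = sorted((motif, rc))
    return MotifClass(members=frozenset((motif, rc)), label=f"{lo}/{hi}")


def _is_primitive(motif: str) -> bool:
    """True unless the motif is a whole repetition of a shorter word."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def find_perfect_ssrs(
    sequence: str, config: MiningConfig | None = None, seq_id: str = "seq"
) -> list[PerfectSSR]:
    """Detect all maximal perfect SSRs meeting the configured thresholds.

    Runs never span ambiguity codes; a run is reported only over complete
    motif copies.  Output is sorted by start coordinate.

    Parameters
    ----------
    sequence
        Nucleotide text (IUPAC codes allowed; anything else is an error).
    config
        Mining thresholds; MISA defaults when omitted.
    seq_id
        Identifier recorded on each returned record.
    """
    config = config or MiningConfig()
    seq = _validate_sequence(sequence)
    n = len(seq)
    thresholds = config.active_thresholds()

    candidates: list[PerfectSSR] = []
    for k, min_rep in sorted(thresholds.items()):
        i = 0
        while i + k * min_rep <= n:
            motif = seq[i : i + k]
            if not set(motif) <= _UNAMBIGUOUS:
                # skip past the last ambiguous base in the window
                last_bad = max(p for p in range(i, i + k) if seq[p] not in _UNAMBIGUOUS)
                i = last_bad + 1
                continue
            j = i + k
            while j < n and seq[j] in _UNAMBIGUOUS and seq[j] == seq[j - k]:
                j += 1
            reps = (j - i) // k
            if reps >= min_rep:
                if _is_primitive(motif):
                    end = i + reps * k  # exclusive
                    candidates.append(
                        PerfectSSR(seq_id, i + 1, end, motif, reps)
                    )
                i = j - k + 1
            else:
                i += 1

    # Cross-period overlap resolution: longer span wins, then shorter
    # period, then leftmost start.
    candidates.sort(key=lambda s: (-s.length, s.motif_length, s.start))
    accepted: list[PerfectSSR] = []
    for cand in candidates:
        if all(cand.end < a.start or cand.start > a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda s: s.start)
    return accepted


def merge_compound(
    ssrs: Sequence[PerfectSSR], config: MiningConfig | None = None
) -> list[SSRRecord]:
    """Chain nearby perfect SSRs into compound SSRs.

    Consecutive SSRs separated by a gap of at most ``config.max_linker``
    nucleotides (inclusive) are merged; chaining is transitive.  Isolated
    SSRs pass through unchanged.

    Raises
    ------
    ValueError
        If the input is unsorted, overlapping, or mixes sequence ids.
    """
    config = config or MiningConfig()
    records: list[SSRRecord] = []
    chain: list[PerfectSSR] = []
    linkers: list[int] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            records.append(chain[0])
        else:
            records.append(CompoundSSR(chain[0].seq_id, tuple(chain), tuple(linkers)))

    for ssr in ssrs:
        if not chain:
            chain = [ssr]
            linkers = []
            continue
        prev = chain[-1]
        if ssr.seq_id != prev.seq_id:
            raise ValueError("merge_compound requires a single seq_id")
        gap = ssr.start - prev.end - 1
        if gap < 0:
            raise ValueError(
                f"overlapping or unsorted SSRs at {prev.start}-{prev.end} / "
                f"{ssr.start}-{ssr.end}"
            )
        if gap <= config.max_linker:
            chain.append(ssr)
            linkers.append(gap)
        else:
            flush()
            chain = [ssr]
            linkers = []
    flush()
    return records


def frequency_per_mb(n_ssrs: int, genome_length_bp: float) -> float:
    """SSR density in loci per megabase."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    return n_ssrs / (genome_length_bp / 1e6)


@dataclass
class MiningSummary:
    """Genome-wide composition of one mining run.

    ``n_total`` counts each standalone perfect SSR and each compound SSR
    as one locus; ``n_motifs`` counts every perfect run including compound
    members, which is why the two tallies differ.
    """

    n_perfect: int
    n_compound: int
    n_total: int
    n_motifs: int
    genome_length_bp: float
    frequency_per_mb: float
    by_motif_length: dict[int, int]
    by_motif_length_prop: dict[int, float]
    by_motif_class: dict[str, int]
    by_motif_class_prop: dict[str, float]
    repeat_histograms: dict[int, Counter]
    compound_member_histogram: Counter
    linker_histogram: Counter
    per_sequence: Counter


def _iter_perfect(records: Iterable[SSRRecord]) -> Iterable[PerfectSSR]:
    for rec in records:
        if isinstance(rec, CompoundSSR):
            yield from rec.members
        else:
            yield rec


def summarize_mining(
    records: Sequence[SSRRecord], genome_length: float
) -> MiningSummary:
    """Summarize counts, proportions, and histograms of a mining run.

    Parameters
    ----------
    records
        Output of :func:`merge_compound` (perfect and compound records
        mixed) or plain perfect SSRs.
    genome_length
        Total genome length in bp; used for the per-Mb frequency.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")

    n_compound = sum(isinstance(r, CompoundSSR) for r in records)
    n_perfect = len(records) - n_compound
    perfect_runs = list(_iter_perfect(records))

    by_len = Counter(p.motif_length for p in perfect_runs)
    by_class = Counter(canonical_motif_class(p.motif).label for p in perfect_runs)
    n_motifs = len(perfect_runs)

    repeat_hists: dict[int, Counter] = {}
    for p in perfect_runs:
        repeat_hists.setdefault(p.motif_length, Counter())[p.repeats] += 1

    member_hist = Counter()
    linker_hist = Counter()
    for rec in records:
        if isinstance(rec, CompoundSSR):
            member_hist[len(rec.members)] += 1
            linker_hist.update(rec.linkers)

    per_seq = Counter(rec.seq_id for rec in records)
    total = len(records)

    def props(counter: Counter) -> dict:
        s = sum(counter.values())
        return {k: v / s for k, v in counter.items()} if s else {}

    return MiningSummary(
        n_perfect=n_perfect,
        n_compound=n_compound,
        n_total=total,
        n_motifs=n_motifs,
        genome_length_bp=genome_length,
        frequency_per_mb=frequency_per_mb(total, genome_length),
        by_motif_length=dict(by_len),
        by_motif_length_prop=props(by_len),
        by_motif_class=dict(by_class),
        by_motif_class_prop=props(by_class),
        repeat_histograms=repeat_hists,
        compound_member_histogram=member_hist,
        linker_histogram=linker_hist,
        per_sequence=per_seq,
    )
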