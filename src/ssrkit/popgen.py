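"""Per-locus and panel diversity statistics for co-dominant SSR genotypes.

The statistics follow the POPGENE / PowerMarker conventions for diploid
co-dominant data:

* ``Na`` — observed number of alleles.
* ``Ne`` — effective number of alleles, ``1 / sum(p_i^2)``.
* ``I``  — Shannon's information index, ``-sum(p_i ln p_i)``.
* ``Ho`` — observed heterozygosity, the fraction of non-missing
  individuals that are heterozygous.
* ``He`` — Nei's unbiased expected heterozygosity,
  ``[2n / (2n - 1)] * (1 - sum(p_i^2))`` with ``n`` the number of
  non-missing individuals.
* ``PIC`` — Botstein's polymorphic information content,
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.

Legacy software frequently reports mean homozygosity under the ``Ho``
label; :attr:`LocusStats.ho_complement_of_he` reproduces that column
(``1 - He``) alongside the true observed heterozygosity.

Raw capillary fragment sizes are snapped onto an allele ladder whose
rungs are spaced by the repeat-unit length (:func:`bin_alleles`), since
true alleles of a microsatellite differ by whole motif copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Locus",
    "GenotypeMatrix",
    "AlleleFrequencies",
    "LocusStats",
    "PanelSummary",
    "WithinPopDiversity",
    "AlleleBinning",
    "bin_alleles",
    "allele_frequencies",
    "locus_stats",
    "summarize_panel",
    "within_population_diversity",
]

Call = tuple[float, float]


@dataclass(frozen=True)
class Locus:
    """A marker locus; motif length is needed only for allele binning."""

    name: str
    motif_length: int | None = None


@dataclass
class GenotypeMatrix:
    """Samples x loci co-dominant diploid calls (fragment sizes in bp).

    ``calls[i][j]`` is the unordered allele pair of sample ``i`` at locus
    ``j`` (stored sorted), or ``None`` for missing.
    """

    samples: list[str]
    loci: list[Locus]
    calls: list[list[Call | None]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.samples):
            raise ValueError("one call row per sample required")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("one call per locus required in each row")
        self.calls = [
            [tuple(sorted(c)) if c is not None else None for c in row]
            for row in self.calls
        ]

    def locus_index(self, locus: str | Locus) -> int:
        name = locus.name if isinstance(locus, Locus) else locus
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(f"unknown locus {name!r}")

    def column(self, locus: str | Locus) -> list[Call | None]:
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            calls=[list(self.calls[i]) for i in idx],
        )


@dataclass(frozen=True)
class AlleleFrequencies:
    """Diploid allele counts at one locus over ``2n`` gene copies."""

    locus: str
    counts: Mapping[float, int]
    n: int       # non-missing individuals
    n_het: int   # heterozygous individuals among them

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != 2 * self.n:
            raise ValueError("allele counts must sum to 2n")

    @property
    def frequencies(self) -> dict[float, float]:
        total = 2 * self.n
        return {a: c / total for a, c in self.counts.items()}

    @property
    def freq_vector(self) -> np.ndarray:
        return np.array(list(self.frequencies.values()))


def allele_frequencies(
    genotypes: GenotypeMatrix, locus: str | Locus
) -> AlleleFrequencies:
    """Count alleles at a locus; each non-missing call adds two gene copies."""
    name = locus.name if isinstance(locus, Locus) else locus
    counts: dict[float, int] = {}
    n = n_het = 0
    for call in genotypes.column(name):
        if call is None:
            continue
        a, b = call
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        n += 1
        if a != b:
            n_het += 1
    if n == 0:
        raise ValueError(f"locus {name!r}: all calls missing")
    return AlleleFrequencies(locus=name, counts=dict(sorted(counts.items())),
                             n=n, n_het=n_het)


@dataclass(frozen=True)
class LocusStats:
    """Diversity indices for one locus (dimensionless)."""

    locus: str
    na: int
    ne: float
    shannon: float
    ho: float
    he: float
    pic: float

    @property
    def ho_complement_of_he(self) -> float:
        """Mean homozygosity ``1 - He``, the column legacy reports label Ho."""
        return 1.0 - self.he

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Report-time rounding (round-half-even, as Python's round)."""
        return {
            "Na": float(self.na),
            "Ne": round(self.ne, ndigits),
            "I": round(self.shannon, ndigits),
            "Ho": round(self.ho, ndigits),
            "He": round(self.he, ndigits),
            "PIC": round(self.pic, ndigits),
        }


def locus_stats(freqs: AlleleFrequencies) -> LocusStats:
    """Compute Na, Ne, I, Ho, He, and PIC from allele frequencies.

    Raises
    ------
    ValueError
        If fewer than two individuals were genotyped (the unbiased He
        correction is undefined).
    """
    if freqs.n <= 1:
        raise ValueError("unbiased He requires n > 1 individuals")
    p = freqs.freq_vector
    sum_p2 = float(np.dot(p, p))
    ne = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    n = freqs.n
    he = (2 * n) / (2 * n - 1) * (1.0 - sum_p2)
    p2 = p * p
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pic = 1.0 - sum_p2 - (sum_p2 * sum_p2 - float(np.dot(p2, p2)))
    ho = freqs.n_het / n
    return LocusStats(
        locus=freqs.locus, na=len(p), ne=ne, shannon=shannon,
        ho=ho, he=he, pic=pic,
    )


@dataclass
class PanelSummary:
    """Across-locus summary: moments per statistic and PIC classes.

    ``pic_classes`` counts loci with PIC strictly below 0.25 (low
    polymorphism), strictly above 0.5 (high), and the rest (moderate).
    """

    n_loci: int
    total_alleles: int
    mean: dict[str, float]
    sd: dict[str, float]
    min: dict[str, float]
    max: dict[str, float]
    pic_classes: dict[str, int]


_STAT_FIELDS = ("na", "ne", "shannon", "ho", "he", "pic")
_STAT_LABELS = {"na": "Na", "ne": "Ne", "shannon": "I",
                "ho": "Ho", "he": "He", "pic": "PIC"}


def summarize_panel(stats: Sequence[LocusStats]) -> PanelSummary:
    """Aggregate per-locus statistics; SD is the sample SD (ddof=1)."""
    if not stats:
        raise ValueError("need at least one locus")
    cols = {
        _STAT_LABELS[f]: np.array([getattr(s, f) for s in stats], dtype=float)
        for f in _STAT_FIELDS
    }
    sd = {
        k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in cols.items()
    }
    pics = cols["PIC"]
    return PanelSummary(
        n_loci=len(stats),
        total_alleles=int(cols["Na"].sum()),
        mean={k: float(v.mean()) for k, v in cols.items()},
        sd=sd,
        min={k: float(v.min()) for k, v in cols.items()},
        max={k: float(v.max()) for k, v in cols.items()},
        pic_classes={
            "low(<0.25)": int((pics < 0.25).sum()),
            "moderate": int(((pics >= 0.25) & (pics <= 0.5)).sum()),
            "high(>0.5)": int((pics > 0.5).sum()),
        },
    )


@dataclass
class WithinPopDiversity:
    """Mean within-population diversity across populations and loci."""

    hs: float
    populations: dict[str, dict[str, float]]  # pop -> mean Na/Ne/I/He
    mean: dict[str, float]
    sd: dict[str, float]
    excluded: list[str] = field(default_factory=list)


def within_population_diversity(
    genotypes: GenotypeMatrix,
    populations: Mapping[str, str],
    unbiased: bool = False,
) -> WithinPopDiversity:
    """Within-population gene diversity (Hs) and per-population indices.

    ``Hs`` is the average over populations and loci of the
    within-population gene diversity ``1 - sum(p_i^2)``; with
    ``unbiased=True`` the Nei (1978) small-sample correction
    ``2n/(2n-1)`` is applied to each term.  Populations of size one are
    excluded with a warning.
    """
    import warnings

    by_pop: dict[str, list[str]] = {}
    for sample in genotypes.samples:
        by_pop.setdefault(populations[sample], []).append(sample)

    excluded = [p for p, members in by_pop.items() if len(members) < 2]
    for pop in excluded:
        warnings.warn(f"population {pop!r} has a single individual; excluded")
        del by_pop[pop]
    if not by_pop:
        raise ValueError("no population with >= 2 individuals")

    hs_terms: list[float] = []
    per_pop: dict[str, dict[str, float]] = {}
    pop_rows: dict[str, list[float]] = {"Na": [], "Ne": [], "I": [], "He": []}
    for pop, members in by_pop.items():
        sub = genotypes.subset_samples(members)
        stats = []
        for locus in sub.loci:
            freqs = allele_frequencies(sub, locus)
            st = locus_stats(freqs)
            stats.append(st)
            gene_div = 1.0 - float(np.dot(freqs.freq_vector, freqs.freq_vector))
            if unbiased:
                gene_div *= (2 * freqs.n) / (2 * freqs.n - 1)
            hs_terms.append(gene_div)
        per_pop[pop] = {
            "Na": float(np.mean([s.na for s in stats])),
            "Ne": float(np.mean([s.ne for s in stats])),
            "I": float(np.mean([s.shannon for s in stats])),
            "He": float(np.mean([s.he for s in stats])),
        }
        for key in pop_rows:
            pop_rows[key].append(per_pop[pop][key])

    arr = {k: np.array(v) for k, v in pop_rows.items()}
    return WithinPopDiversity(
        hs=float(np.mean(hs_terms)),
        populations=per_pop,
        mean={k: float(v.mean()) for k, v in arr.items()},
        sd={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in arr.items()},
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Allele-ladder binning
# ---------------------------------------------------------------------------

@dataclass
class AlleleBinning:
    """Raw fragment sizes snapped onto a repeat-unit ladder."""

    reference_size: float
    motif_length: int
    bins: dict[float, list[float]]      # rung size -> member raw sizes
    ambiguous: list[float]              # sizes equidistant from two rungs

    @property
    def alleles(self) -> list[float]:
        return sorted(self.bins)


def bin_alleles(
    raw_sizes: Sequence[float], motif_length: int, reference_size: float
) -> AlleleBinning:
    """Snap raw fragment sizes to ``reference_size + k * motif_length``.

    A size is assigned to the nearest ladder rung when its offset is
    strictly less than half the motif length; a size exactly halfway
    between two rungs is flagged ambiguous rather than silently assigned.
    """
    if motif_length < 1:
        raise ValueError("motif_length must be >= 1")
    bins: dict[float, list[float]] = {}
    ambiguous: list[float] = []
    for raw in raw_sizes:
        if raw <= 0:
            raise ValueError("fragment sizes must be positive")
        k = (raw - reference_size) / motif_length
        lo, hi = math.floor(k), math.ceil(k)
        d_lo = abs(raw - (reference_size + lo * motif_length))
        d_hi = abs(raw - (reference_size + hi * motif_length))
        if lo != hi and math.isclose(d_lo, d_hi):
            ambiguous.append(raw)
            continue
        k_best = lo if d_lo < d_hi else hi
        rung = reference_size + k_best * motif_length
        bins.setdefault(rung, []).append(raw)
    return AlleleBinning(
        reference_size=reference_size,
        motif_length=motif_length,
        bins={k: bins[k] for k in sorted(bins)},
        ambiguous=ambiguous,
    )
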