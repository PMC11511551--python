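"""SSR flank extraction, primer constraint validation, and TP-M13 tailing.

Marker development screens primer pairs against four ranges — primer
length 18-25 nt, melting temperature 57-62 °C, PCR product 120-400 bp,
and GC content 40-60% — and labels amplicons for capillary detection by
prepending a universal M13 tail to the forward primer, so a single
dye-labeled M13 primer fluoresces every product (TP-M13).  The tail adds
its own length to the raw fragment size, which matters when binning
alleles.

This module validates and enumerates constraint-satisfying candidates;
full primer optimization (penalty weighting, dimer/hairpin checks) is a
job for a dedicated designer and is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp, gc_fraction

from .mining import PerfectSSR, reverse_complement

__all__ = [
    "M13_TAIL_DEFAULT",
    "M13_TAIL_CANONICAL",
    "PrimerConstraints",
    "PrimerPair",
    "M13Tail",
    "extract_flanks",
    "compute_tm",
    "gc_percent",
    "check_primer_pair",
    "apply_m13_tail",
    "enumerate_primer_pairs",
]

#: Tail used by the TP-M13 protocol this toolkit targets (stored verbatim;
#: note it is 19 nt long despite often being described as an 18 bp tail).
M13_TAIL_DEFAULT = "TGTAAAAACGACGGCCAGT"

#: The canonical 18-nt M13(-21) universal primer, available as an
#: alternative tail.
M13_TAIL_CANONICAL = "TGTAAAACGACGGCCAGT"


@dataclass(frozen=True)
class PrimerConstraints:
    """Screening ranges for a primer pair; all bounds inclusive."""

    length: tuple[int, int] = (18, 25)
    tm: tuple[float, float] = (57.0, 62.0)
    product_size: tuple[int, int] = (120, 400)
    gc: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("length", "tm", "product_size", "gc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty: {lo} > {hi}")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair on a template (1-based positions).

    The reverse primer is given 5'->3' on the opposite strand.
    ``forward_start`` is the first template base of the forward primer and
    ``reverse_end`` the last template base covered by the reverse primer,
    so ``product_size = reverse_end - forward_start + 1``.
    """

    forward: str
    reverse: str
    forward_start: int
    reverse_end: int

    @property
    def product_size(self) -> int:
        return self.reverse_end - self.forward_start + 1


@dataclass(frozen=True)
class M13Tail:
    """A universal tail plus the dye attached to its labeled counterpart."""

    sequence: str = M13_TAIL_DEFAULT
    dye: str = "FAM"

    def __post_init__(self) -> None:
        if self.dye not in {"ROX", "HEX", "TET", "FAM"}:
            raise ValueError(f"unknown dye {self.dye!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Flanks:
    """Flanking sequence around an SSR, with truncation bookkeeping."""

    left: str
    right: str
    truncated_left: bool = False
    truncated_right: bool = False


def extract_flanks(
    ssr: PerfectSSR, sequence: str, flank_length: int = 200
) -> Flanks:
    """Extract up to ``flank_length`` nt either side of an SSR.

    Flanks are truncated (with a warning flag set) at sequence ends;
    ``left + spanned SSR + right`` always equals the corresponding
    genomic slice.
    """
    import warnings

    n = len(sequence)
    if ssr.start < 1 or ssr.end > n:
        raise ValueError("SSR span outside sequence bounds")
    left_start = max(ssr.start - flank_length, 1)
    right_end = min(ssr.end + flank_length, n)
    trunc_left = left_start == 1 and ssr.start - flank_length < 1
    trunc_right = right_end == n and ssr.end + flank_length > n
    if trunc_left or trunc_right:
        warnings.warn(
            f"flank truncated at sequence end for SSR {ssr.start}-{ssr.end}"
        )
    return Flanks(
        left=sequence[left_start - 1 : ssr.start - 1],
        right=sequence[ssr.end : right_end],
        truncated_left=trunc_left,
        truncated_right=trunc_right,
    )


def compute_tm(primer: str, method: str = "nn", **kwargs) -> float:
    """Primer melting temperature in °C.

    ``method='nn'`` uses nearest-neighbor thermodynamics (Biopython's
    ``Tm_NN``; Allawi & SantaLucia 1997 unified parameter set, 50 mM Na+,
    25 nM each strand, entropic salt correction, unless overridden via
    keyword arguments).  ``method='wallace'`` is the simple
    2(A+T) + 4(G+C) rule.
    """
    primer = primer.upper()
    if not primer:
        raise ValueError("empty primer")
    if set(primer) - set("ACGT"):
        raise ValueError(f"ambiguous base in primer {primer!r}")
    if method == "nn":
        return float(MeltingTemp.Tm_NN(primer, **kwargs))
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(primer))
    raise ValueError(f"unknown Tm method {method!r}")


def gc_percent(primer: str) -> float:
    """GC content as a percentage."""
    return 100.0 * gc_fraction(primer)


@dataclass
class PrimerCheck:
    """Outcome of a constraint screen; empty ``failures`` means pass."""

    passed: bool
    failures: list[str] = field(default_factory=list)


def check_primer_pair(
    pair: PrimerPair,
    constraints: PrimerConstraints | None = None,
    tm_method: str = "nn",
) -> PrimerCheck:
    """Screen a primer pair against the four constraint ranges.

    Every violated rule is listed (``length``, ``Tm``, ``GC-content`` per
    primer, and ``product-size``); the pair passes iff no rule fails.
    """
    constraints = constraints or PrimerConstraints()
    failures: list[str] = []
    for which, primer in (("forward", pair.forward), ("reverse", pair.reverse)):
        lo, hi = constraints.length
        if not lo <= len(primer) <= hi:
            failures.append(f"{which} length {len(primer)} outside {lo}-{hi}")
        tm = compute_tm(primer, method=tm_method)
        lo, hi = constraints.tm
        if not lo <= tm <= hi:
            failures.append(f"{which} Tm {tm:.1f} outside {lo}-{hi}")
        gc = gc_percent(primer)
        lo, hi = constraints.gc
        if not lo <= gc <= hi:
            failures.append(f"{which} GC-content {gc:.1f} outside {lo}-{hi}")
    lo, hi = constraints.product_size
    if not lo <= pair.product_size <= hi:
        failures.append(f"product-size {pair.product_size} outside {lo}-{hi}")
    return PrimerCheck(passed=not failures, failures=failures)


def apply_m13_tail(forward_primer: str, tail: M13Tail | None = None) -> str:
    """Prepend the M13 tail to a forward primer (exactly once).

    Raises
    ------
    ValueError
        If the primer already starts with the tail (double-tailing guard).
    """
    tail = tail or M13Tail()
    primer = forward_primer.upper()
    if primer.startswith(tail.sequence):
        raise ValueError("primer already carries the M13 tail")
    return tail.sequence + primer


def tailed_fragment_size(product_size: int, tail: M13Tail | None = None) -> int:
    """Raw fragment size read off the trace after tailing."""
    tail = tail or M13Tail()
    return product_size + tail.length


def enumerate_primer_pairs(
    ssr: PerfectSSR,
    sequence: str,
    constraints: PrimerConstraints | None = None,
    flank_length: int = 200,
    tm_method: str = "nn",
    max_pairs: int = 10,
) -> list[tuple[PrimerPair, PrimerCheck]]:
    """Enumerate constraint-satisfying primer pairs around an SSR.

    Slides windows of every allowed length across the left flank (forward
    primer) and right flank (reverse primer, reverse-complemented) and
    keeps pairs passing :func:`check_primer_pair`.  The product always
    contains the SSR.  This is a screening enumerator, not an optimizer.
    """
    constraints = constraints or PrimerConstraints()
    flanks = extract_flanks(ssr, sequence, flank_length)
    left_offset = ssr.start - len(flanks.left)  # template pos of flank start
    results: list[tuple[PrimerPair, PrimerCheck]] = []

    def ok_single(primer: str) -> bool:
        lo, hi = constraints.tm
        glo, ghi = constraints.gc
        try:
            tm = compute_tm(primer, method=tm_method)
        except ValueError:
            return False
        return lo <= tm <= hi and glo <= gc_percent(primer) <= ghi

    lmin, lmax = constraints.length
    fwd_candidates = []
    for length in range(lmin, lmax + 1):
        for i in range(len(flanks.left) - length + 1):
            primer = flanks.left[i : i + length]
            if ok_single(primer):
                fwd_candidates.append((primer, left_offset + i))
    rev_candidates = []
    for length in range(lmin, lmax + 1):
        for i in range(len(flanks.right) - length + 1):
            primer = reverse_complement(flanks.right[i : i + length])
            if ok_single(primer):
                rev_candidates.append((primer, ssr.end + i + length))
    for fwd, fstart in fwd_candidates:
        for rev, rend in rev_candidates:
            pair = PrimerPair(fwd, rev, fstart, rend)
            check = check_primer_pair(pair, constraints, tm_method)
            if check.passed:
                results.append((pair, check))
                if len(results) >= max_pairs:
                    return results
    return results
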