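"""DNA fingerprint profiles and minimal core-marker set search.

A fingerprint profile records, per sample and marker, the set of fragment
sizes present (the band pattern).  A marker subset *discriminates* a
panel when every pair of samples shows a distinct combined pattern over
that subset; a *core* set is a minimal discriminating subset — drop any
marker and some pair collapses.  The search enumerates subsets in
increasing size, skipping supersets of sets already found (which both
prunes and guarantees minimality) and, within a size, extending only
with markers that separate at least one still-unresolved pair.

Missing data are handled conservatively: a missing call makes every
comparison involving that sample at that subset indeterminate, so the
subset is counted as non-discriminating for those pairs.

Two comparison modes exist: band patterns (presence/absence of fragment
sizes, the default, matching how fingerprints are read off a trace) and
strict diploid genotypes (the unordered allele pair), which can separate
samples that band patterns cannot not — e.g. an A/A homozygote versus an
A/B heterozygote contributes different genotypes but the A band is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .popgen import GenotypeMatrix

__all__ = [
    "FingerprintProfile",
    "CorePrimerSet",
    "CoreSearchResult",
    "distinguishes",
    "find_core_sets",
    "fingerprint_report",
]

Pattern = frozenset[float] | None


@dataclass
class FingerprintProfile:
    """Per sample, per marker, the set of present fragment sizes.

    ``bands[sample][marker]`` is a frozenset of sizes, or ``None`` for a
    missing call.  In strict-genotype mode the stored value is the
    ordered allele pair tuple instead of the band set.
    """

    samples: list[str]
    markers: list[str]
    bands: dict[str, dict[str, Pattern]]

    @classmethod
    def from_genotypes(
        cls, genotypes: GenotypeMatrix, mode: str = "bands"
    ) -> "FingerprintProfile":
        """Build a profile from co-dominant calls.

        ``mode='bands'`` collapses each call to its set of fragment sizes;
        ``mode='genotype'`` keeps the ordered allele pair.
        """
        if mode not in {"bands", "genotype"}:
            raise ValueError(f"unknown mode {mode!r}")
        markers = [loc.name for loc in genotypes.loci]
        bands: dict[str, dict[str, Pattern]] = {}
        for i, sample in enumerate(genotypes.samples):
            row: dict[str, Pattern] = {}
            for j, marker in enumerate(markers):
                call = genotypes.calls[i][j]
                if call is None:
                    row[marker] = None
                elif mode == "bands":
                    row[marker] = frozenset(call)
                else:
                    row[marker] = tuple(call)  # type: ignore[assignment]
            bands[sample] = row
        return cls(samples=list(genotypes.samples), markers=markers, bands=bands)

    def pattern(self, sample: str, markers: Sequence[str]) -> tuple | None:
        """Combined pattern over a marker subset; None if any call missing."""
        parts = []
        for m in markers:
            v = self.bands[sample][m]
            if v is None:
                return None
            parts.append(v)
        return tuple(parts)


@dataclass(frozen=True)
class CorePrimerSet:
    """A marker subset reported by the core search."""

    markers: tuple[str, ...]
    discriminating: bool = True
    minimal: bool = True


@dataclass
class CoreSearchResult:
    """All minimal discriminating subsets found, or the pairs that block them."""

    sets: list[CorePrimerSet]
    unresolved_pairs: list[tuple[str, str]] = field(default_factory=list)


def _check_markers(markers: Iterable[str], profile: FingerprintProfile) -> list[str]:
    markers = list(markers)
    if not markers:
        raise ValueError("marker subset must be non-empty")
    unknown = set(markers) - set(profile.markers)
    if unknown:
        raise KeyError(f"unknown markers: {sorted(unknown)}")
    return markers


def distinguishes(markers: Sequence[str], profile: FingerprintProfile) -> bool:
    """True iff every pair of samples differs on the combined subset pattern.

    A pair with a missing call anywhere in the subset is indeterminate and
    counts against discrimination.
    """
    markers = _check_markers(markers, profile)
    seen: dict[tuple, str] = {}
    for sample in profile.samples:
        pat = profile.pattern(sample, markers)
        if pat is None or pat in seen:
            return False
        seen[pat] = sample
    return True


def _separated_pairs(
    profile: FingerprintProfile, marker: str
) -> set[tuple[str, str]]:
    out = set()
    for a, b in combinations(profile.samples, 2):
        va, vb = profile.bands[a][marker], profile.bands[b][marker]
        if va is not None and vb is not None and va != vb:
            out.add((a, b))
    return out


def find_core_sets(
    profile: FingerprintProfile, max_size: int
) -> CoreSearchResult:
    """Enumerate all minimal discriminating marker subsets up to ``max_size``.

    Results are sorted by size, then lexicographically by marker labels.
    If no subset of the allowed size discriminates, the unresolved sample
    pairs of the *full* marker set are reported — pairs identical (or
    indeterminate) across every marker can never be separated.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    markers = sorted(profile.markers)
    sep = {m: _separated_pairs(profile, m) for m in markers}
    all_pairs = set(combinations(profile.samples, 2))

    found: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        for subset in combinations(markers, size):
            if any(set(prev) <= set(subset) for prev in found):
                continue  # superset of a known core set: not minimal
            # cheap necessary condition: the union of pairwise separations
            # must cover all pairs before the full pattern test runs
            covered = set()
            for m in subset:
                covered |= sep[m]
            if covered != all_pairs:
                continue
            if distinguishes(list(subset), profile):
                found.append(subset)

    if found:
        found.sort(key=lambda s: (len(s), s))
        return CoreSearchResult(
            sets=[CorePrimerSet(markers=s) for s in found]
        )
    unresolved = sorted(all_pairs - set().union(*sep.values()) if sep else all_pairs)
    return CoreSearchResult(sets=[], unresolved_pairs=unresolved)


def fingerprint_report(profile: FingerprintProfile) -> dict:
    """Per-marker band counts and archival per-sample pattern strings.

    The band count of a marker is the number of distinct fragment sizes
    observed across the panel; a monomorphic marker has one band and
    contributes nothing to discrimination.
    """
    band_counts: dict[str, int] = {}
    for marker in profile.markers:
        sizes = set()
        for sample in profile.samples:
            v = profile.bands[sample][marker]
            if v is not None:
                sizes |= set(v) if isinstance(v, frozenset) else set(v)
        band_counts[marker] = len(sizes)

    def fmt(v: Pattern) -> str:
        if v is None:
            return "NA"
        vals = sorted(v)
        return "|".join(str(int(x)) if float(x).is_integer() else str(x) for x in vals)

    patterns = {
        sample: ";".join(
            f"{marker}:{fmt(profile.bands[sample][marker])}"
            for marker in profile.markers
        )
        for sample in profile.samples
    }
    return {"band_counts": band_counts, "patterns": patterns}
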