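"""Independent reference implementations used as test oracles.

These are deliberately naive — exhaustive scans and unpruned
enumerations — and share no code with the package internals they check.
"""

from __future__ import annotations

from itertools import combinations

_ACGT = set("ACGT")


def exhaustive_perfect_ssrs(
    seq: str, thresholds: dict[int, int]
) -> list[tuple[int, int, str, int]]:
    """Every maximal perfect repeat run, by brute-force window comparison.

    Tests each (position, period) pair directly with slice equality,
    keeps only primitive motifs at leftmost-maximal starts, then resolves
    cross-period overlaps by longest span, then shortest period, then
    leftmost start.  Returns (start, end, motif, repeats) 1-based
    inclusive, sorted by start.
    """
    seq = seq.upper()
    n = len(seq)
    found: list[tuple[int, int, str, int, int]] = []
    for k, min_rep in thresholds.items():
        for i in range(n - k * min_rep + 1):
            window = seq[i : i + k]
            if any(c not in _ACGT for c in window):
                continue
            if any(
                k % d == 0 and window == window[: d] * (k // d)
                for d in range(1, k)
            ):
                continue  # motif reducible to a shorter period
            if i >= 1 and seq[i - 1] in _ACGT and seq[i - 1] == seq[i - 1 + k]:
                continue  # not the leftmost start of this run
            reps = 1
            while seq[i + reps * k : i + (reps + 1) * k] == window:
                reps += 1
            if reps >= min_rep:
                found.append((i + 1, i + reps * k, window, reps, k))
    found.sort(key=lambda t: (-(t[1] - t[0] + 1), t[4], t[0]))
    chosen: list[tuple[int, int, str, int, int]] = []
    for cand in found:
        if all(cand[1] < c[0] or cand[0] > c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda t: t[0])
    return [(s, e, m, r) for s, e, m, r, _k in chosen]


def brute_force_core_sets(
    patterns: dict[str, dict[str, object]],
    samples: list[str],
    markers: list[str],
    max_size: int,
) -> list[tuple[str, ...]]:
    """All minimal discriminating subsets by unpruned enumeration.

    ``patterns[sample][marker]`` is a hashable band pattern or ``None``
    (missing, which blocks discrimination).  Minimality is derived by a
    second pass over the discriminating list.
    """
    discriminating: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        for sub in combinations(sorted(markers), size):
            combined = []
            complete = True
            for s in samples:
                vals = tuple(patterns[s][m] for m in sub)
                if any(v is None for v in vals):
                    complete = False
                    break
                combined.append(vals)
            if complete and len(set(combined)) == len(samples):
                discriminating.append(sub)
    minimal = [
        s for s in discriminating
        if not any(set(t) < set(s) for t in discriminating)
    ]
    return sorted(minimal, key=lambda s: (len(s), s))
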