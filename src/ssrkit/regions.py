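"""Assignment of SSR loci to genomic region categories from a GFF3 annotation.

Each SSR span is placed into one of six categories: 5'UTR, 3'UTR, exon,
intron, intergenic, or multi-mapped (overlapping two or more of the first
five simultaneously).  Spans on sequences absent from the annotation are
reported as *unplaced* and counted separately.

Category construction: per transcript, introns are the gaps between its
exons; UTR features take precedence over the exon category for the bases
they cover (in GFF3 a UTR base is also an exon base, and a six-way split
requires the UTR label to win); the per-category intervals are unioned
across all transcripts and genes; everything outside any gene span is
intergenic.  Strand is ignored — region identity is strand-independent
here.  Any overlap of >= 1 bp with a category counts; an SSR need not be
contained in it.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "CATEGORIES",
    "RegionIndex",
    "RegionAssignment",
    "build_region_index",
    "assign_region",
    "region_distribution",
]

CATEGORIES = (
    "five_prime_UTR",
    "three_prime_UTR",
    "exon",
    "intron",
    "intergenic",
    "multi_mapped",
)

Interval = tuple[int, int]  # 1-based inclusive


def _merge(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if s <= pe + 1:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b on merged 1-based inclusive intervals."""
    out: list[Interval] = []
    b = _merge(b)
    for s, e in _merge(a):
        cur = s
        for bs, be in b:
            if be < cur or bs > e:
                continue
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


@dataclass
class RegionIndex:
    """Queryable per-sequence interval sets for the five base categories."""

    trees: dict[str, dict[str, IntervalTree]]
    gene_spans: dict[str, list[Interval]]
    feature_trees: dict[str, IntervalTree] = field(default_factory=dict)

    def seq_ids(self) -> list[str]:
        return sorted(self.trees)

    def categories_at(self, seq_id: str, start: int, end: int) -> set[str]:
        """Final categories overlapping a 1-based inclusive span."""
        cats: set[str] = set()
        for cat, tree in self.trees[seq_id].items():
            if tree.overlap(start, end + 1):
                cats.add(cat)
        covered = 0
        for s, e in self.gene_spans.get(seq_id, []):
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                covered += hi - lo + 1
        if covered < end - start + 1:
            cats.add("intergenic")
        return cats

    def features_at(self, seq_id: str, start: int, end: int) -> list[str]:
        tree = self.feature_trees.get(seq_id)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def build_region_index(annotation: str | Path) -> RegionIndex:
    """Build the region index from GFF3 content (path or text).

    Introns are derived per transcript as the gaps between its exons;
    exons extending past their gene span are clipped with a warning.

    Raises
    ------
    ValueError
        With the offending line number when a GFF3 line cannot be parsed.
    """
    text = (
        Path(annotation).read_text()
        if isinstance(annotation, Path) or (len(str(annotation)) < 4096 and "\n" not in str(annotation) and Path(str(annotation)).exists())
        else str(annotation)
    )
    _validate_gff_lines(text)
    feature_lines = [
        ln for ln in text.splitlines() if ln and not ln.startswith("#")
    ]
    if not feature_lines:
        seqids = {
            d.split()[1]
            for d in text.splitlines()
            if d.startswith("##sequence-region")
        }
        empty = {
            c: IntervalTree()
            for c in ("five_prime_UTR", "three_prime_UTR", "exon", "intron")
        }
        return RegionIndex(
            trees={s: dict(empty) for s in seqids}, gene_spans={}, feature_trees={}
        )
    try:
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error paths vary
        raise ValueError(f"malformed GFF3: {exc}") from exc

    utr5: dict[str, list[Interval]] = {}
    utr3: dict[str, list[Interval]] = {}
    exon_raw: dict[str, list[Interval]] = {}
    intron: dict[str, list[Interval]] = {}
    genes: dict[str, list[Interval]] = {}
    features: dict[str, list[tuple[int, int, str]]] = {}
    seqids: set[str] = set()

    for directive in db.directives:
        if directive.startswith("sequence-region"):
            seqids.add(directive.split()[1])

    for gene in db.features_of_type("gene"):
        genes.setdefault(gene.seqid, []).append((gene.start, gene.end))
        seqids.add(gene.seqid)
        features.setdefault(gene.seqid, []).append((gene.start, gene.end, gene.id))
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if not transcripts:
            transcripts = [gene]  # exons attached directly to the gene
        for tx in transcripts:
            exons = sorted(
                db.children(tx, featuretype="exon"), key=lambda f: f.start
            )
            spans = []
            for ex in exons:
                s, e = ex.start, ex.end
                if s < gene.start or e > gene.end:
                    warnings.warn(
                        f"exon {ex.id or '?'} outside gene span of {gene.id}; clipped"
                    )
                    s, e = max(s, gene.start), min(e, gene.end)
                spans.append((s, e))
            exon_raw.setdefault(gene.seqid, []).extend(spans)
            for (_ps, prev_end), (next_start, _ne) in zip(spans, spans[1:]):
                if next_start > prev_end + 1:
                    intron.setdefault(gene.seqid, []).append(
                        (prev_end + 1, next_start - 1)
                    )
            for ft, store in (("five_prime_UTR", utr5), ("three_prime_UTR", utr3)):
                for u in db.children(tx, featuretype=ft):
                    store.setdefault(gene.seqid, []).append((u.start, u.end))

    trees: dict[str, dict[str, IntervalTree]] = {}
    for seqid in seqids:
        utr = _merge(utr5.get(seqid, [])) + _merge(utr3.get(seqid, []))
        exon_final = _subtract(exon_raw.get(seqid, []), utr)
        cat_intervals = {
            "five_prime_UTR": _merge(utr5.get(seqid, [])),
            "three_prime_UTR": _merge(utr3.get(seqid, [])),
            "exon": exon_final,
            "intron": _merge(intron.get(seqid, [])),
        }
        trees[seqid] = {
            cat: IntervalTree.from_tuples((s, e + 1) for s, e in ivs)
            for cat, ivs in cat_intervals.items()
            if ivs
        }
        trees[seqid] = {**{c: IntervalTree() for c in cat_intervals}, **trees[seqid]}

    feature_trees = {
        seqid: IntervalTree.from_tuples((s, e + 1, fid) for s, e, fid in fl)
        for seqid, fl in features.items()
    }
    return RegionIndex(
        trees=trees,
        gene_spans={k: _merge(v) for k, v in genes.items()},
        feature_trees=feature_trees,
    )


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(
                f"malformed GFF3 at line {lineno}: expected 9 fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(f"malformed GFF3 at line {lineno}: {exc}") from exc
        if start < 1 or end < start:
            raise ValueError(f"malformed GFF3 at line {lineno}: bad coordinates")


@dataclass(frozen=True)
class RegionAssignment:
    """One SSR's category and the gene features it overlaps."""

    seq_id: str
    start: int
    end: int
    category: str
    overlapped_feature_ids: tuple[str, ...] = ()


def assign_region(
    ssr_span: tuple[str, int, int], index: RegionIndex
) -> RegionAssignment:
    """Assign a 1-based inclusive span to its region category.

    Spans on sequences unknown to the annotation yield the ``unplaced``
    category (counted separately from the six regions).
    """
    seq_id, start, end = ssr_span
    if seq_id not in index.trees:
        return RegionAssignment(seq_id, start, end, "unplaced")
    cats = index.categories_at(seq_id, start, end)
    if len(cats) == 0:
        # inside a gene with no exon substructure: no finer category applies
        category = "intergenic"
    elif len(cats) == 1:
        category = cats.pop()
    else:
        category = "multi_mapped"
    return RegionAssignment(
        seq_id, start, end, category,
        tuple(index.features_at(seq_id, start, end)),
    )


def region_distribution(assignments: list[RegionAssignment]) -> pd.DataFrame:
    """Counts and proportions per category, overall and per sequence.

    Returns a table indexed by (seq_id, category) plus an ``__all__``
    block; proportions are over assigned (non-unplaced) SSRs.
    """
    rows = []
    total_counter = Counter(a.category for a in assignments)
    per_seq: dict[str, Counter] = {}
    for a in assignments:
        per_seq.setdefault(a.seq_id, Counter())[a.category] += 1

    def block(seq_id: str, counter: Counter) -> None:
        assigned = sum(v for k, v in counter.items() if k != "unplaced")
        for cat in CATEGORIES + ("unplaced",):
            count = counter.get(cat, 0)
            rows.append(
                {
                    "seq_id": seq_id,
                    "category": cat,
                    "count": count,
                    "proportion": (count / assigned) if assigned and cat != "unplaced" else 0.0,
                }
            )

    block("__all__", total_counter)
    for seq_id in sorted(per_seq):
        block(seq_id, per_seq[seq_id])
    return pd.DataFrame(rows).set_index(["seq_id", "category"])
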