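"""Readers and writers for the toolkit's file formats.

Formats touched: FASTA (via Biopython, gzip transparent), GFF3 (consumed
by :mod:`ssrkit.regions`), a MISA-compatible SSR table, a richer native
SSR table with compound membership, the fragment-size genotype dialect,
population assignments, Newick trees, and delimited stats tables.

Genotype-table dialect (no standard exists for fragment-size genotypes):
a header row ``sample<TAB>locus.A1<TAB>locus.A2...``, fragment sizes in
bp, ``NA`` for missing — both alleles of a missing call are NA.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from .mining import CompoundSSR, MiningSummary, PerfectSSR, SSRRecord
from .popgen import GenotypeMatrix, Locus, LocusStats, PanelSummary

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_misa_table",
    "write_ssr_tables",
    "read_ssr_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_populations",
    "write_locus_stats",
    "write_panel_summary",
    "write_mining_summary",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into id -> sequence."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SSR tables
# ---------------------------------------------------------------------------

def _ssr_type(record: SSRRecord) -> str:
    if isinstance(record, CompoundSSR):
        return "c"
    return f"p{record.motif_length}"


def write_misa_table(records: Sequence[SSRRecord], path: str | Path) -> None:
    """MISA-compatible table: ID, SSR nr., SSR type, SSR, size, start, end."""
    rows = []
    counters: dict[str, int] = {}
    for rec in records:
        counters[rec.seq_id] = counters.get(rec.seq_id, 0) + 1
        rows.append(
            {
                "ID": rec.seq_id,
                "SSR nr.": counters[rec.seq_id],
                "SSR type": _ssr_type(rec),
                "SSR": str(rec),
                "size": rec.length,
                "start": rec.start,
                "end": rec.end,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ssr_tables(
    records: Sequence[SSRRecord], out_dir: str | Path, prefix: str = "ssrs"
) -> dict[str, Path]:
    """Native tables: one row per perfect run plus a compound table.

    Returns the written paths keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    perfect_rows = []
    compound_rows = []
    ssr_n = 0
    compound_n = 0
    for rec in records:
        if isinstance(rec, CompoundSSR):
            compound_n += 1
            cid = f"c{compound_n}"
            compound_rows.append(
                {
                    "compound_id": cid,
                    "seq_id": rec.seq_id,
                    "start": rec.start,
                    "end": rec.end,
                    "n_members": len(rec.members),
                    "linkers": ",".join(map(str, rec.linkers)),
                }
            )
            for idx, member in enumerate(rec.members, 1):
                ssr_n += 1
                perfect_rows.append(_perfect_row(member, f"ssr{ssr_n}", cid, idx))
        else:
            ssr_n += 1
            perfect_rows.append(_perfect_row(rec, f"ssr{ssr_n}", "", 0))
    paths = {
        "ssrs": out_dir / f"{prefix}.tsv",
        "compounds": out_dir / f"{prefix}_compounds.tsv",
    }
    pd.DataFrame(
        perfect_rows,
        columns=["ssr_id", "seq_id", "start", "end", "motif", "repeats",
                 "length", "compound_id", "member_index"],
    ).to_csv(paths["ssrs"], sep="\t", index=False)
    pd.DataFrame(
        compound_rows,
        columns=["compound_id", "seq_id", "start", "end", "n_members", "linkers"],
    ).to_csv(paths["compounds"], sep="\t", index=False)
    return paths


def _perfect_row(ssr: PerfectSSR, ssr_id: str, cid: str, member_index: int) -> dict:
    return {
        "ssr_id": ssr_id,
        "seq_id": ssr.seq_id,
        "start": ssr.start,
        "end": ssr.end,
        "motif": ssr.motif,
        "repeats": ssr.repeats,
        "length": ssr.length,
        "compound_id": cid,
        "member_index": member_index,
    }


def read_ssr_table(path: str | Path) -> list[PerfectSSR]:
    """Read the native perfect-SSR table back into records."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    return [
        PerfectSSR(
            seq_id=str(r.seq_id), start=int(r.start), end=int(r.end),
            motif=str(r.motif), repeats=int(r.repeats),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------

def read_genotype_table(
    path: str | Path, motif_lengths: dict[str, int] | None = None
) -> GenotypeMatrix:
    """Read the two-columns-per-locus genotype dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample":
        raise ValueError("first column must be 'sample'")
    locus_names: list[str] = []
    for col in df.columns[1:]:
        if not (col.endswith(".A1") or col.endswith(".A2")):
            raise ValueError(f"genotype column {col!r} lacks .A1/.A2 suffix")
        name = col[:-3]
        if name not in locus_names:
            locus_names.append(name)
    for name in locus_names:
        for suffix in (".A1", ".A2"):
            if f"{name}{suffix}" not in df.columns:
                raise ValueError(f"locus {name!r} missing column {name}{suffix}")
    motif_lengths = motif_lengths or {}
    loci = [Locus(n, motif_lengths.get(n)) for n in locus_names]
    calls: list[list[tuple[float, float] | None]] = []
    for _, row in df.iterrows():
        sample_calls = []
        for name in locus_names:
            a1, a2 = row[f"{name}.A1"], row[f"{name}.A2"]
            if pd.isna(a1) or pd.isna(a2) or a1 == "NA" or a2 == "NA":
                sample_calls.append(None)
            else:
                sample_calls.append((_num(a1), _num(a2)))
        calls.append(sample_calls)
    return GenotypeMatrix(samples=df["sample"].tolist(), loci=loci, calls=calls)


def _num(x: str) -> float:
    v = float(x)
    return int(v) if v.is_integer() else v


def write_genotype_table(genotypes: GenotypeMatrix, path: str | Path) -> None:
    cols: dict[str, list] = {"sample": genotypes.samples}
    for j, locus in enumerate(genotypes.loci):
        a1, a2 = [], []
        for row in genotypes.calls:
            call = row[j]
            if call is None:
                a1.append("NA")
                a2.append("NA")
            else:
                a1.append(call[0])
                a2.append(call[1])
        cols[f"{locus.name}.A1"] = a1
        cols[f"{locus.name}.A2"] = a2
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_populations(path: str | Path) -> dict[str, str]:
    """Read a sample<TAB>population table into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "population"]:
        raise ValueError("population table needs 'sample' and 'population' columns")
    return dict(zip(df["sample"], df["population"]))


# ---------------------------------------------------------------------------
# Stats tables
# ---------------------------------------------------------------------------

def write_locus_stats(
    stats: Iterable[LocusStats], path: str | Path, ndigits: int = 4
) -> None:
    """Per-locus table; includes the legacy complement-of-He column."""
    rows = []
    for s in stats:
        row = {"locus": s.locus, **s.rounded(ndigits)}
        row["Ho_as_1_minus_He"] = round(s.ho_complement_of_he, ndigits)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_panel_summary(summary: PanelSummary, path: str | Path) -> None:
    rows = [
        {"statistic": k, "mean": summary.mean[k], "sd": summary.sd[k],
         "min": summary.min[k], "max": summary.max[k]}
        for k in summary.mean
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as out:
        out.write(f"# loci\t{summary.n_loci}\n")
        out.write(f"# total_alleles\t{summary.total_alleles}\n")
        for cls, count in summary.pic_classes.items():
            out.write(f"# PIC_{cls}\t{count}\n")
        df.to_csv(out, sep="\t", index=False)


def write_mining_summary(summary: MiningSummary, out_dir: str | Path) -> dict[str, Path]:
    """Write the mining summary as a set of small delimited tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    totals = pd.DataFrame(
        [
            ("perfect", summary.n_perfect),
            ("compound", summary.n_compound),
            ("total", summary.n_total),
            ("motif_runs", summary.n_motifs),
            ("genome_length_bp", summary.genome_length_bp),
            ("frequency_per_mb", round(summary.frequency_per_mb, 4)),
        ],
        columns=["quantity", "value"],
    )
    paths["totals"] = out_dir / "summary_totals.tsv"
    totals.to_csv(paths["totals"], sep="\t", index=False)

    by_len = pd.DataFrame(
        [
            (k, summary.by_motif_length[k], summary.by_motif_length_prop[k])
            for k in sorted(summary.by_motif_length)
        ],
        columns=["motif_length", "count", "proportion"],
    )
    paths["by_motif_length"] = out_dir / "summary_motif_length.tsv"
    by_len.to_csv(paths["by_motif_length"], sep="\t", index=False)

    by_class = pd.DataFrame(
        sorted(
            ((k, v, summary.by_motif_class_prop[k]) for k, v in summary.by_motif_class.items()),
            key=lambda r: (-r[1], r[0]),
        ),
        columns=["motif_class", "count", "proportion"],
    )
    paths["by_motif_class"] = out_dir / "summary_motif_class.tsv"
    by_class.to_csv(paths["by_motif_class"], sep="\t", index=False)
    return paths
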