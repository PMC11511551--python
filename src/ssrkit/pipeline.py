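"""End-to-end pipeline runner with a machine-readable manifest.

Stages run in dependency order — mine -> map regions -> primers on the
genome side; stats -> cluster -> fingerprint on the genotype side — and
each stage's outputs are ordinary files a later stage (or a re-run) can
pick up.  The manifest lists every artifact with its SHA-256 checksum and
echoes the full parameter block, so a run is reproducible from the
manifest alone.  On stage failure the partial outputs are retained next
to a failure marker and the error is re-raised.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import io as ssrio
from .clustering import (bands_from_genotypes, cophenetic_correlation,
                         similarity_matrix, upgma)
from .config import RunConfig
from .fingerprint import FingerprintProfile, find_core_sets, fingerprint_report
from .mining import find_perfect_ssrs, merge_compound, summarize_mining
from .popgen import allele_frequencies, locus_stats, summarize_panel, within_population_diversity
from .regions import assign_region, build_region_index, region_distribution

__all__ = ["run_pipeline"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages the config provides inputs for.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {
        "config": config.model_dump(),
        "stages": [],
        "artifacts": artifacts,
    }

    def register(name: str, path: Path) -> None:
        artifacts[name] = ""
        artifacts[name] = f"{path.name}:{_checksum(path)}"

    try:
        if config.fasta:
            sequences = ssrio.read_fasta(config.fasta)
            mining_cfg = config.mining.to_mining_config()
            records = []
            for seq_id, seq in sequences.items():
                perfect = find_perfect_ssrs(seq, mining_cfg, seq_id=seq_id)
                records.extend(merge_compound(perfect, mining_cfg))
            misa_path = out / "ssrs_misa.tsv"
            ssrio.write_misa_table(records, misa_path)
            register("misa_table", misa_path)
            for name, path in ssrio.write_ssr_tables(records, out).items():
                register(f"ssr_{name}", path)
            genome_length = sum(len(s) for s in sequences.values())
            summary = summarize_mining(records, genome_length)
            for name, path in ssrio.write_mining_summary(summary, out).items():
                register(f"mining_{name}", path)
            manifest["stages"].append("mine")

            if config.gff3:
                index = build_region_index(Path(config.gff3))
                assignments = []
                for rec in records:
                    assignments.append(
                        assign_region((rec.seq_id, rec.start, rec.end), index)
                    )
                dist = region_distribution(assignments)
                region_path = out / "region_distribution.tsv"
                dist.to_csv(region_path, sep="\t")
                register("region_distribution", region_path)
                assign_path = out / "region_assignments.tsv"
                with open(assign_path, "w") as fh:
                    fh.write("seq_id\tstart\tend\tcategory\tfeatures\n")
                    for a in assignments:
                        fh.write(
                            f"{a.seq_id}\t{a.start}\t{a.end}\t{a.category}\t"
                            f"{','.join(a.overlapped_feature_ids)}\n"
                        )
                register("region_assignments", assign_path)
                manifest["stages"].append("map-regions")

            if records:
                from .primers import enumerate_primer_pairs
                constraints = config.primers.to_constraints()
                primer_rows = []
                perfect_only = [
                    r for r in records if not hasattr(r, "members")
                ]
                for i, ssr in enumerate(perfect_only, 1):
                    pairs = enumerate_primer_pairs(
                        ssr, sequences[ssr.seq_id], constraints,
                        flank_length=config.primers.flank_length,
                        tm_method=config.primers.tm_method, max_pairs=1,
                    )
                    for pair, check in pairs:
                        from .primers import compute_tm, gc_percent
                        primer_rows.append(
                            {
                                "ssr": f"{ssr.seq_id}:{ssr.start}-{ssr.end}",
                                "forward": pair.forward,
                                "reverse": pair.reverse,
                                "tm_f": round(compute_tm(pair.forward), 2),
                                "tm_r": round(compute_tm(pair.reverse), 2),
                                "gc_f": round(gc_percent(pair.forward), 1),
                                "gc_r": round(gc_percent(pair.reverse), 1),
                                "product_size": pair.product_size,
                                "passed": check.passed,
                            }
                        )
                import pandas as pd
                primer_path = out / "primers.tsv"
                pd.DataFrame(
                    primer_rows,
                    columns=["ssr", "forward", "reverse", "tm_f", "tm_r",
                             "gc_f", "gc_r", "product_size", "passed"],
                ).to_csv(primer_path, sep="\t", index=False)
                register("primers", primer_path)
                manifest["stages"].append("primers")

        if config.genotypes:
            genotypes = ssrio.read_genotype_table(config.genotypes)
            stats = [
                locus_stats(allele_frequencies(genotypes, locus))
                for locus in genotypes.loci
            ]
            stats_path = out / "locus_stats.tsv"
            ssrio.write_locus_stats(stats, stats_path, config.stats.report_decimals)
            register("locus_stats", stats_path)
            summary_path = out / "panel_summary.tsv"
            ssrio.write_panel_summary(summarize_panel(stats), summary_path)
            register("panel_summary", summary_path)
            manifest["stages"].append("stats")

            if config.populations:
                pops = ssrio.read_populations(config.populations)
                wp = within_population_diversity(
                    genotypes, pops, unbiased=config.stats.unbiased_hs
                )
                hs_path = out / "within_population.tsv"
                with open(hs_path, "w") as fh:
                    fh.write(f"Hs\t{wp.hs:.4f}\n")
                    for pop, vals in wp.populations.items():
                        line = "\t".join(f"{k}={v:.4f}" for k, v in vals.items())
                        fh.write(f"{pop}\t{line}\n")
                register("within_population", hs_path)

            bands = bands_from_genotypes(genotypes)
            sim = similarity_matrix(bands)
            sim_path = out / "similarity.tsv"
            sim.round(4).to_csv(sim_path, sep="\t")
            register("similarity", sim_path)
            if len(genotypes.samples) >= 2:
                tree = upgma(sim)
                tree_path = out / "upgma.nwk"
                tree_path.write_text(tree.to_newick() + "\n")
                register("tree", tree_path)
                if len(genotypes.samples) >= 3:
                    r = cophenetic_correlation(tree, sim)
                    (out / "cophenetic_r.txt").write_text(f"{r:.4f}\n")
                    register("cophenetic_r", out / "cophenetic_r.txt")
                manifest["stages"].append("cluster")

            profile = FingerprintProfile.from_genotypes(
                genotypes, mode=config.fingerprint.mode
            )
            report = fingerprint_report(profile)
            fp_path = out / "fingerprint.tsv"
            bands.to_csv(fp_path, sep="\t")
            register("fingerprint", fp_path)
            core = find_core_sets(profile, config.fingerprint.max_core_size)
            core_path = out / "core_sets.tsv"
            with open(core_path, "w") as fh:
                fh.write("markers\tsize\n")
                for cs in core.sets:
                    fh.write(f"{','.join(cs.markers)}\t{len(cs.markers)}\n")
                if not core.sets:
                    for a, b in core.unresolved_pairs:
                        fh.write(f"# unresolved\t{a}/{b}\n")
            register("core_sets", core_path)
            counts_path = out / "band_counts.tsv"
            with open(counts_path, "w") as fh:
                fh.write("marker\tbands\n")
                for marker, count in report["band_counts"].items():
                    fh.write(f"{marker}\t{count}\n")
            register("band_counts", counts_path)
            manifest["stages"].append("fingerprint")

    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; partial outputs retained\n")
        raise

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
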