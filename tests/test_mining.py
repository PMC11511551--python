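"""Perfect-SSR detection, compound merging, motif classes, summaries."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import exhaustive_perfect_ssrs
from ssrkit.mining import (CompoundSSR, MiningConfig, PerfectSSR,
                           canonical_motif_class, find_perfect_ssrs,
                           frequency_per_mb, merge_compound,
                           reverse_complement, summarize_mining)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=6)


def random_sequence(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    bases = "ACGTN" if with_n else "ACGT"
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else [0.25] * 4
    return "".join(rng.choice(list(bases), size=length, p=probs))


class TestFindPerfectSSRs:
    def test_dinucleotide_threshold_boundary(self):
        assert find_perfect_ssrs("ATATATATATAT") == [
            PerfectSSR("seq", 1, 12, "AT", 6)
        ]
        assert find_perfect_ssrs("ATATATATAT") == []

    def test_reports_leftmost_phase_and_floor_repeats(self):
        # 13 bases: six complete AT copies plus a trailing A
        out = find_perfect_ssrs("ATATATATATATA")
        assert out == [PerfectSSR("seq", 1, 12, "AT", 6)]

    def test_shortest_period_rule(self):
        # a pure AT run must never be reported as an ATAT tetramer
        out = find_perfect_ssrs("G" + "AT" * 10 + "G")
        assert len(out) == 1 and out[0].motif == "AT"

    def test_run_truncated_at_ambiguity(self):
        seq = "AT" * 6 + "N" + "AT" * 6
        out = find_perfect_ssrs(seq)
        assert [(s.start, s.end) for s in out] == [(1, 12), (14, 25)]

    def test_empty_and_invalid_input(self):
        assert find_perfect_ssrs("") == []
        with pytest.raises(ValueError):
            find_perfect_ssrs("ACGTXACGT")

    def test_mononucleotide_excluded_by_default(self):
        assert find_perfect_ssrs("A" * 30) == []
        cfg = MiningConfig(include_mono=True)
        out = find_perfect_ssrs("A" * 30, cfg)
        assert out == [PerfectSSR("seq", 1, 30, "A", 30)]

    def test_planted_recovery(self, planted_genome):
        seq = planted_genome.sequences["chr1"]
        mined = find_perfect_ssrs(seq, seq_id="chr1")
        assert mined == planted_genome.truth_ssrs()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 2000, with_n=seed % 2 == 0)
        cfg = MiningConfig()
        mined = [
            (s.start, s.end, s.motif, s.repeats)
            for s in find_perfect_ssrs(seq, cfg)
        ]
        assert mined == exhaustive_perfect_ssrs(seq, cfg.active_thresholds())

    @pytest.mark.parametrize(
        "seq",
        [
            "AT" * 50,                        # one long run spanning everything
            "AT" * 6 + "GA" * 6,              # adjacent runs, shared boundary base
            "AT" * 6 + "C" + "AT" * 6,        # runs split by a single base
            "AAG" * 5 + "AGA" * 2,            # phase shifts at the junction
            "ACGT" * 20,                      # tetramer run
            "AT" * 7 + "ATA" + "TA" * 7,      # overlapping di-runs, phases differ
            "N" * 10 + "CG" * 8 + "N" * 10,   # run flanked by ambiguity
            "AT" * 6 + "AAG" * 5,             # di meets tri
        ],
    )
    def test_matches_exhaustive_oracle_on_adversarial_sequences(self, seq):
        cfg = MiningConfig()
        mined = [
            (s.start, s.end, s.motif, s.repeats)
            for s in find_perfect_ssrs(seq, cfg)
        ]
        assert mined == exhaustive_perfect_ssrs(seq, cfg.active_thresholds())


class TestMergeCompound:
    def _ssrs(self, *spans):
        return [
            PerfectSSR("chr", s, s + 11, "AT", 6) for s in spans
        ]

    def test_zero_gap_merges_with_zero_linker(self):
        a = PerfectSSR("chr", 1, 12, "AT", 6)
        b = PerfectSSR("chr", 13, 24, "GA", 6)
        (rec,) = merge_compound([a, b])
        assert isinstance(rec, CompoundSSR)
        assert rec.linkers == (0,) and len(rec.members) == 2

    def test_gap_just_over_bound_stays_separate(self):
        a = PerfectSSR("chr", 1, 12, "AT", 6)
        b = PerfectSSR("chr", 12 + 101 + 1, 12 + 101 + 12, "GA", 6)
        out = merge_compound([a, b], MiningConfig(max_linker=100))
        assert out == [a, b]

    def test_transitive_chaining_three_members(self):
        a = PerfectSSR("chr", 1, 12, "AT", 6)
        b = PerfectSSR("chr", 18, 29, "GA", 6)     # gap 5
        c = PerfectSSR("chr", 70, 81, "CT", 6)     # gap 40
        (rec,) = merge_compound([a, b, c])
        assert isinstance(rec, CompoundSSR)
        assert len(rec.members) == 3 and rec.linkers == (5, 40)

    def test_overlapping_input_rejected(self):
        a = PerfectSSR("chr", 1, 12, "AT", 6)
        b = PerfectSSR("chr", 10, 21, "GA", 6)
        with pytest.raises(ValueError, match="overlap"):
            merge_compound([a, b])

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_and_count_conserving(self, seed):
        rng = np.random.default_rng(seed)
        pos = 1
        ssrs = []
        for _ in range(30):
            ssrs.append(PerfectSSR("chr", pos, pos + 11, "AT", 6))
            pos += 12 + int(rng.integers(0, 250))
        merged = merge_compound(ssrs)
        n_members = sum(
            len(r.members) if isinstance(r, CompoundSSR) else 1 for r in merged
        )
        assert n_members == len(ssrs)
        remerged = merge_compound(
            [m for r in merged for m in (r.members if isinstance(r, CompoundSSR) else [r])]
        )
        assert remerged == merged


class TestMotifClass:
    @pytest.mark.parametrize(
        "motif,label",
        [("GA", "GA/TC"), ("CT", "AG/CT"), ("AT", "AT/AT"),
         ("CCG", "CCG/CGG"), ("GCC", "GCC/GGC")],
    )
    def test_labels(self, motif, label):
        assert canonical_motif_class(motif).label == label

    def test_rotations_stay_distinct(self):
        assert canonical_motif_class("GA").label != canonical_motif_class("AG").label

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif_class("AN")

    @given(DNA)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_closed_under_reverse_complement(self, motif):
        assert (
            canonical_motif_class(motif)
            == canonical_motif_class(reverse_complement(motif))
        )


class TestSummarize:
    def test_genome_scale_frequency_arithmetic(self):
        assert round(frequency_per_mb(231_789, 2813.5e6), 1) == 82.4

    def test_empty_records(self):
        s = summarize_mining([], 1e6)
        assert s.n_total == 0 and s.frequency_per_mb == 0.0

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            summarize_mining([], 0)

    def test_planted_composition_recovered(self):
        records = (
            [PerfectSSR("c", 1 + 500 * i, 12 + 500 * i, "AT", 6) for i in range(6)]
            + [PerfectSSR("c", 4000 + 500 * i, 4014 + 500 * i, "AAG", 5) for i in range(3)]
            + [PerfectSSR("c", 8000, 8023, "GATC", 6)]
        )
        s = summarize_mining(records, 10_000)
        assert s.by_motif_length == {2: 6, 3: 3, 4: 1}
        assert s.by_motif_length_prop == {2: 0.6, 3: 0.3, 4: 0.1}
        assert s.frequency_per_mb == pytest.approx(1000.0)

    def test_compound_members_counted_in_motif_tally_only(self):
        a = PerfectSSR("c", 1, 12, "AT", 6)
        b = PerfectSSR("c", 13, 24, "GA", 6)
        lone = PerfectSSR("c", 500, 511, "CT", 6)
        records = merge_compound([a, b]) + [lone]
        s = summarize_mining(records, 1000)
        assert (s.n_perfect, s.n_compound, s.n_total, s.n_motifs) == (1, 1, 2, 3)
        assert s.compound_member_histogram == {2: 1}
        assert s.linker_histogram == {0: 1}
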