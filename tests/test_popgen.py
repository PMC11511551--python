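"""Diversity statistics: allele counting, Na/Ne/I/Ho/He/PIC, Hs, binning."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ANCHOR_ROWS
from ssrkit.datasets import bamboo_marker_panel
from ssrkit.popgen import (AlleleFrequencies, GenotypeMatrix, Locus,
                           allele_frequencies, bin_alleles, locus_stats,
                           summarize_panel, within_population_diversity)


def freqs_from_counts(counts, n=12, n_het=0):
    alleles = {200.0 + 2 * i: c for i, c in enumerate(counts)}
    return AlleleFrequencies(locus="L", counts=alleles, n=n, n_het=n_het)


class TestAlleleFrequencies:
    def test_diploid_counting(self):
        # 7 het A/B, 5 hom B/B over 12 individuals -> A:7, B:17? use explicit:
        calls = [[(200, 202)]] * 7 + [[(200, 200)]] * 5
        gm = GenotypeMatrix([f"s{i}" for i in range(12)], [Locus("L")], calls)
        f = allele_frequencies(gm, "L")
        assert f.counts == {200: 17, 202: 7} and f.n == 12 and f.n_het == 7

    def test_missing_calls_excluded(self):
        calls = [[(200, 202)], [None], [(202, 202)]]
        gm = GenotypeMatrix(["a", "b", "c"], [Locus("L")], calls)
        f = allele_frequencies(gm, "L")
        assert f.n == 2 and sum(f.counts.values()) == 4

    def test_all_missing_errors(self):
        gm = GenotypeMatrix(["a"], [Locus("L")], [[None]])
        with pytest.raises(ValueError, match="missing"):
            allele_frequencies(gm, "L")


class TestLocusStats:
    @pytest.mark.parametrize("name", sorted(ANCHOR_ROWS))
    def test_reproduces_published_marker_rows_jointly(self, name):
        """All four closed forms must match the printed row simultaneously."""
        counts, expected = ANCHOR_ROWS[name]
        st_ = locus_stats(freqs_from_counts(counts))
        got = st_.rounded()
        for key, value in expected.items():
            assert got[key] == pytest.approx(value, abs=5e-5), key

    def test_equifrequent_biallelic_closed_forms(self):
        st_ = locus_stats(freqs_from_counts((12, 12)))
        assert st_.ne == pytest.approx(2.0)
        assert st_.shannon == pytest.approx(math.log(2))
        assert st_.pic == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        st_ = locus_stats(freqs_from_counts((24,)))
        assert (st_.na, st_.ne, st_.shannon, st_.he, st_.pic) == (1, 1.0, 0.0, 0.0, 0.0)

    def test_observed_vs_complement_heterozygosity(self):
        st_ = locus_stats(freqs_from_counts((14, 10), n_het=6))
        assert st_.ho == pytest.approx(0.5)
        assert st_.ho_complement_of_he == pytest.approx(1 - st_.he)

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            locus_stats(AlleleFrequencies("L", {200.0: 2}, n=1, n_het=0))

    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariants_for_any_count_vector(self, counts):
        if sum(counts) % 2:
            counts = counts + [1]
        while sum(counts) // 2 < 2:
            counts = [c * 2 for c in counts]
        total = sum(counts)
        n = total // 2
        st_ = locus_stats(freqs_from_counts(tuple(counts), n=n))
        p = np.array(counts) / total
        gene_div = 1 - float(p @ p)
        assert 1.0 - 1e-12 <= st_.ne <= st_.na + 1e-12
        assert 0 <= st_.pic <= gene_div + 1e-12
        assert st_.shannon >= -1e-12
        assert 0 <= st_.he <= 1

    def test_label_permutation_invariance(self):
        a = locus_stats(freqs_from_counts((14, 6, 4)))
        b = locus_stats(freqs_from_counts((4, 14, 6)))
        for field in ("ne", "shannon", "he", "pic"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))

    def test_unbiased_correction_vanishes_with_sample_size(self):
        prev = None
        for n in (10, 100, 1000, 10000):
            st_ = locus_stats(freqs_from_counts((n, n), n=n))
            excess = st_.he - 0.5
            assert excess > 0
            if prev is not None:
                assert excess < prev
            prev = excess


class TestPanelSummary:
    def test_reproduces_published_panel_columns(self):
        """Mean/SD/total of the 28-marker bamboo panel as printed."""
        table = bamboo_marker_panel()
        from ssrkit.popgen import LocusStats

        stats = [
            LocusStats(locus=r.marker, na=int(r.Na), ne=r.Ne, shannon=r.I,
                       ho=r.Ho, he=r.He, pic=r.PIC)
            for r in table.itertuples()
        ]
        s = summarize_panel(stats)
        assert s.total_alleles == 81
        assert s.mean["Na"] == pytest.approx(2.8929, abs=5e-5)
        assert s.mean["Ne"] == pytest.approx(2.0281, abs=5e-5)
        assert s.mean["I"] == pytest.approx(0.7600, abs=5e-5)
        assert s.mean["He"] == pytest.approx(0.4732, abs=5e-5)
        assert s.mean["PIC"] == pytest.approx(0.3863, abs=5e-5)
        assert s.sd["Na"] == pytest.approx(1.1333, abs=5e-5)
        assert s.pic_classes["low(<0.25)"] == 7
        assert s.pic_classes["high(>0.5)"] == 6

    def test_single_locus_summary(self):
        st_ = locus_stats(freqs_from_counts((14, 10)))
        s = summarize_panel([st_])
        assert s.mean["Ne"] == pytest.approx(st_.ne)
        assert s.sd["Ne"] == 0.0


class TestWithinPopulationDiversity:
    def _panel(self, calls_by_pop):
        samples, calls, pops = [], [], {}
        for pop, rows in calls_by_pop.items():
            for i, row in enumerate(rows):
                name = f"{pop}{i}"
                samples.append(name)
                calls.append(row)
                pops[name] = pop
        gm = GenotypeMatrix(samples, [Locus("L")], calls)
        return gm, pops

    def test_clonal_populations_have_zero_hs(self):
        gm, pops = self._panel({
            "a": [[(200, 200)]] * 3,
            "b": [[(202, 202)]] * 3,
        })
        wp = within_population_diversity(gm, pops)
        assert wp.hs == 0.0

    def test_between_population_divergence_ignored(self):
        # total diversity > 0 but each population fixed -> Hs stays 0
        gm, pops = self._panel({
            "a": [[(200, 200)]] * 4,
            "b": [[(204, 204)]] * 4,
        })
        assert within_population_diversity(gm, pops).hs == 0.0
        pooled = locus_stats(allele_frequencies(gm, "L"))
        assert pooled.he > 0

    def test_singleton_population_excluded_with_warning(self):
        gm, pops = self._panel({
            "a": [[(200, 202)]] * 3,
            "solo": [[(200, 200)]],
        })
        with pytest.warns(UserWarning, match="solo"):
            wp = within_population_diversity(gm, pops)
        assert wp.excluded == ["solo"]

    def test_matches_closed_form_expectation_on_simulated_panel(self):
        from ssrkit.simulate import LocusSpec, PanelSpec, generate_panel

        freqs = (0.6, 0.4)
        spec = PanelSpec(
            loci=[LocusSpec("L", freqs, 2, 200)],
            populations={"a": 300, "b": 300},
            seed=11,
        )
        gm, pops = generate_panel(spec)
        wp = within_population_diversity(gm, pops)
        expected = 1 - sum(f * f for f in freqs)
        assert wp.hs == pytest.approx(expected, abs=0.03)


class TestBinAlleles:
    def test_snaps_to_repeat_ladder(self):
        b = bin_alleles([200.1, 202.0, 203.9], 2, 200)
        assert b.alleles == [200, 202, 204]
        assert b.bins[204] == [203.9]

    def test_single_size(self):
        b = bin_alleles([201.2], 2, 200)
        assert b.alleles == [202] and not b.ambiguous

    def test_halfway_size_flagged_ambiguous(self):
        b = bin_alleles([201.0], 2, 200)
        assert b.ambiguous == [201.0] and not b.bins

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bin_alleles([200], 0, 200)
        with pytest.raises(ValueError):
            bin_alleles([-1], 2, 200)
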