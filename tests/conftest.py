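"""Shared fixtures: synthetic genomes, anchor panels, engineered fingerprints."""

from __future__ import annotations

import pytest

from ssrkit.popgen import GenotypeMatrix, Locus
from ssrkit.simulate import (CompoundPlant, GenePlant, LocusSpec, PanelSpec,
                             PlantSpec, PlantedSSR, generate_genome,
                             generate_panel)

#: Back-derived allele-count vectors over 24 gene copies (n = 12) whose
#: four statistics jointly reproduce published marker rows to 4 decimals.
ANCHOR_ROWS = {
    "biallelic_14_10": ((14, 10), {"Ne": 1.9459, "I": 0.6792, "He": 0.5072, "PIC": 0.3680}),
    "five_allele_8_6_6_2_2": ((8, 6, 6, 2, 2), {"Ne": 4.0000, "I": 1.4735, "He": 0.7826, "PIC": 0.7078}),
    "skewed_22_2": ((22, 2), {"Ne": 1.1803, "I": 0.2868, "He": 0.1594, "PIC": 0.1411}),
}


@pytest.fixture(scope="session")
def planted_genome():
    """A ~12 kb sequence with 12 planted SSRs, genes, and a compound group."""
    spec = PlantSpec(
        seq_id="chr1",
        elements=[
            PlantedSSR("AT", 8),
            PlantedSSR("AAG", 6),
            PlantedSSR("GATC", 6),
            PlantedSSR("AACGT", 5),
            PlantedSSR("CG", 7),
            CompoundPlant((PlantedSSR("GA", 7), PlantedSSR("CT", 6)), (12,)),
            CompoundPlant(
                (PlantedSSR("AC", 6), PlantedSSR("AGG", 5), PlantedSSR("AT", 6)),
                (5, 40),
            ),
            GenePlant(ssr_in="intron", ssr=PlantedSSR("AC", 9)),
            GenePlant(ssr_in="five_prime_UTR", ssr=PlantedSSR("AG", 7), utr5_length=80),
        ],
        spacer_length=400,
        seed=20240917,
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def anchor_panel():
    """Deterministic 12-sample panel with the three anchor allele-count vectors."""
    spec = PanelSpec(
        loci=[
            LocusSpec("SSR52", motif_length=2, allele_counts=(14, 10)),
            LocusSpec("SSR522", motif_length=2, allele_counts=(8, 6, 6, 2, 2)),
            LocusSpec("SSR41", motif_length=2, allele_counts=(22, 2)),
        ],
        populations={"panel": 12},
    )
    gm, _pops = generate_panel(spec)
    return gm


def engineered_fingerprint_matrix() -> GenotypeMatrix:
    """12 samples x 8 markers where {M1,M2} plus any one of M3..M7 is a core set.

    M1 alone separates the pair (s01, s02); M2 alone separates (s03, s04);
    together they leave exactly the pair (s11, s12) unresolved, which each
    of M3..M7 (and nothing else) separates.  M8 is a filler separating
    none of the three critical pairs.
    """
    m1 = [0, 1, 2, 2, 3, 4, 5, 6, 7, 8, 9, 9]
    m2 = [0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 9]
    m_sep_last = [0] * 11 + [1]
    m8 = [5, 5, 6, 6, 0, 1, 2, 3, 4, 7, 8, 8]
    columns = {"M1": m1, "M2": m2, "M8": m8}
    for name in ("M3", "M4", "M5", "M6", "M7"):
        columns[name] = m_sep_last
    marker_order = ["M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8"]
    samples = [f"s{i + 1:02d}" for i in range(12)]
    loci = [Locus(m, 2) for m in marker_order]
    calls = [
        [(200 + 2 * columns[m][i],) * 2 for m in marker_order]
        for i in range(12)
    ]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


@pytest.fixture
def engineered_fingerprint():
    return engineered_fingerprint_matrix()
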