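"""Band matrices, SM similarity, UPGMA, cophenetic correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ssrkit.clustering import (bands_from_genotypes, cophenetic_correlation,
                               similarity_matrix, sm_coefficient, upgma)
from ssrkit.popgen import GenotypeMatrix, Locus


def random_similarity(rng: np.random.Generator, n: int) -> pd.DataFrame:
    u = rng.uniform(0, 1, size=(n, n))
    arr = (u + u.T) / 2
    np.fill_diagonal(arr, 1.0)
    labels = [f"s{i:02d}" for i in range(n)]
    return pd.DataFrame(arr, index=labels, columns=labels)


class TestBandMatrix:
    def test_heterozygote_sets_both_columns_homozygote_one(self):
        gm = GenotypeMatrix(
            ["het", "hom"],
            [Locus("L")],
            [[(200, 202)], [(200, 200)]],
        )
        bands = bands_from_genotypes(gm)
        assert list(bands.columns) == ["L:200", "L:202"]
        assert bands.loc["het"].tolist() == [1, 1]
        assert bands.loc["hom"].tolist() == [1, 0]

    def test_column_per_distinct_allele(self):
        calls = [[(200 + 2 * i, 200 + 2 * ((i + 1) % 6))] for i in range(6)]
        gm = GenotypeMatrix([f"s{i}" for i in range(6)], [Locus("M")], calls)
        assert bands_from_genotypes(gm).shape[1] == 6


class TestSMCoefficient:
    def test_identical_and_complementary(self):
        assert sm_coefficient([1, 0, 1], [1, 0, 1]) == 1.0
        assert sm_coefficient([1, 1, 0], [0, 0, 1]) == 0.0

    def test_shared_absences_count(self):
        assert sm_coefficient([1, 1, 0, 0], [1, 0, 1, 0]) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm_coefficient([1, 0], [1])

    def test_symmetry_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 2, 12)
            y = rng.integers(0, 2, 12)
            assert sm_coefficient(x, y) == sm_coefficient(y, x)

    def test_similarity_matrix_matches_pairwise_coefficient(self):
        rng = np.random.default_rng(1)
        bands = pd.DataFrame(
            rng.integers(0, 2, size=(5, 14)),
            index=[f"s{i}" for i in range(5)],
        )
        sim = similarity_matrix(bands)
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else sm_coefficient(
                    bands.iloc[i], bands.iloc[j]
                )
                assert sim.iloc[i, j] == pytest.approx(expected)


class TestUPGMA:
    def test_three_taxa_forced_order(self):
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.5], [0.9, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = upgma(sim)
        assert tree.fusion_similarities.tolist() == pytest.approx([0.9, 0.5])
        coph = tree.cophenetic_similarities()
        assert coph.loc["A", "B"] == pytest.approx(0.9)
        assert coph.loc["A", "C"] == pytest.approx(0.5)

    def test_exact_on_ultrametric_input(self):
        rng = np.random.default_rng(1)
        base = upgma(random_similarity(rng, 6))
        ultra = base.cophenetic_similarities()
        tree = upgma(ultra)
        assert np.allclose(
            tree.cophenetic_similarities().loc[ultra.index, ultra.index], ultra
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        sim = random_similarity(rng, 8)
        tree = upgma(sim)
        z_ref = linkage(squareform(1 - sim.to_numpy(), checks=False), "average")
        assert np.allclose(
            tree.cophenetic_distances().to_numpy(), squareform(cophenet(z_ref))
        )

    def test_ultrametric_monotone_fusion_levels(self):
        rng = np.random.default_rng(2)
        tree = upgma(random_similarity(rng, 10))
        levels = tree.linkage[:, 2]
        assert np.all(np.diff(levels) >= -1e-12)

    def test_relabeling_permutes_but_preserves_heights(self):
        rng = np.random.default_rng(3)
        sim = random_similarity(rng, 7)
        perm = rng.permutation(len(sim))
        shuffled = sim.iloc[perm, perm]
        a = upgma(sim).cophenetic_similarities()
        b = upgma(shuffled).cophenetic_similarities()
        assert np.allclose(a, b.loc[a.index, a.columns])

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="symmetric"):
            upgma(bad)
        with pytest.raises(ValueError):
            upgma(pd.DataFrame([[1.0]], index=["A"], columns=["A"]))

    def test_newick_roundtrip_heights(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(4)
        sim = random_similarity(rng, 5)
        tree = upgma(sim)
        phylo = Phylo.read(StringIO(tree.to_newick()), "newick")
        depths = phylo.depths()
        leaf_depths = {t.name: d for t, d in depths.items() if t.name}
        root_height = max(tree.linkage[:, 2]) / 2
        for depth in leaf_depths.values():
            assert depth == pytest.approx(root_height, abs=1e-4)


class TestCopheneticCorrelation:
    def test_unity_on_ultrametric_input(self):
        rng = np.random.default_rng(5)
        ultra = upgma(random_similarity(rng, 8)).cophenetic_similarities()
        tree = upgma(ultra)
        assert cophenetic_correlation(tree, ultra) == pytest.approx(1.0)

    def test_approaches_unity_under_vanishing_noise(self):
        rng = np.random.default_rng(6)
        ultra = upgma(random_similarity(rng, 8)).cophenetic_similarities()
        prev = 0.0
        for eps in (3e-2, 1e-3):
            noise = rng.uniform(-eps, eps, size=ultra.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            perturbed = (ultra + noise).clip(0, 1)
            r = cophenetic_correlation(upgma(perturbed), perturbed)
            assert r >= prev - 1e-9
            prev = r
        assert prev > 0.999

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_direct_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        sim = random_similarity(rng, 8)
        tree = upgma(sim)
        r = cophenetic_correlation(tree, sim)
        coph = tree.cophenetic_similarities().to_numpy()
        obs = sim.loc[tree.labels, tree.labels].to_numpy()
        iu = np.triu_indices(8, 1)
        r_ref = float(np.corrcoef(coph[iu], obs[iu])[0, 1])
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_too_few_leaves_rejected(self):
        sim = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=list("AB"), columns=list("AB"))
        tree = upgma(sim)
        with pytest.raises(ValueError):
            cophenetic_correlation(tree, sim)
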