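"""Band-based similarity and UPGMA dendrograms for SSR fingerprints.

Co-dominant genotypes are flattened to a binary band matrix (one column
per observed (locus, allele-size) band, as read off a capillary trace or
gel).  Pairwise similarity uses the simple-matching (SM) coefficient,
which counts shared *absences* as matches as well as shared presences —
the defining difference from Jaccard, and it changes results, so choose
deliberately.  Trees are built by UPGMA (unweighted pair-group average
linkage) on the distance ``1 - S``; fusion levels are reported back on
the similarity scale.  Dendrogram fit is validated by the cophenetic
correlation between tree-implied and observed similarities.

Tie-breaking during agglomeration is deterministic: sample labels are
sorted lexicographically up front and the tied pair with the smallest
(row, column) cluster indices is fused first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .popgen import GenotypeMatrix

__all__ = [
    "bands_from_genotypes",
    "sm_coefficient",
    "similarity_matrix",
    "Dendrogram",
    "upgma",
    "cophenetic_correlation",
]


def bands_from_genotypes(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Binary samples x bands matrix; a sample's bands are the union of its alleles.

    Columns are labeled ``locus:size`` and ordered by locus then size.
    Missing calls simply contribute no bands (see the fingerprint module
    for the conservative missing-data policy used in discrimination).
    """
    columns: list[str] = []
    for j, locus in enumerate(genotypes.loci):
        sizes = sorted(
            {a for row in genotypes.calls if row[j] is not None for a in row[j]}
        )
        columns.extend(_band_label(locus.name, s) for s in sizes)
    data = pd.DataFrame(0, index=genotypes.samples, columns=columns, dtype=int)
    for i, sample in enumerate(genotypes.samples):
        for j, locus in enumerate(genotypes.loci):
            call = genotypes.calls[i][j]
            if call is None:
                continue
            for allele in call:
                data.loc[sample, _band_label(locus.name, allele)] = 1
    return data


def _band_label(locus: str, size: float) -> str:
    size = int(size) if float(size).is_integer() else size
    return f"{locus}:{size}"


def sm_coefficient(x, y) -> float:
    """Simple-matching similarity: (shared presences + shared absences) / length."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(np.mean(x == y))


def similarity_matrix(bands: pd.DataFrame) -> pd.DataFrame:
    """Pairwise SM coefficients between all samples of a band matrix."""
    arr = bands.to_numpy(dtype=int)
    n = arr.shape[0]
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = np.mean(arr[i] == arr[j])
    return pd.DataFrame(sim, index=bands.index, columns=bands.index)


@dataclass
class Dendrogram:
    """A rooted ultrametric tree from UPGMA.

    ``linkage`` follows the scipy convention: row ``m`` fuses clusters
    ``linkage[m, 0]`` and ``linkage[m, 1]`` at distance ``linkage[m, 2]``
    into cluster ``n_leaves + m`` of size ``linkage[m, 3]``.
    ``fusion_similarities`` are the same levels on the similarity scale
    (``1 - d``), in fusion order.
    """

    labels: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def fusion_similarities(self) -> np.ndarray:
        return 1.0 - self.linkage[:, 2]

    def cophenetic_distances(self) -> pd.DataFrame:
        """Tree-implied pairwise distances (fusion level joining each pair)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for m, (a, b, dist, _size) in enumerate(self.linkage):
            left, right = members.pop(int(a)), members.pop(int(b))
            for i in left:
                for j in right:
                    coph[i, j] = coph[j, i] = dist
            members[n + m] = left + right
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def cophenetic_similarities(self) -> pd.DataFrame:
        out = 1.0 - self.cophenetic_distances()
        np.fill_diagonal(out.values, 1.0)
        return out

    def to_newick(self) -> str:
        """Newick with branch lengths on the distance scale (leaf depth = h/2)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: _escape(self.labels[i]) for i in range(n)}
        for m, (a, b, dist, _size) in enumerate(self.linkage):
            a, b = int(a), int(b)
            h = dist / 2.0
            left = f"{node.pop(a)}:{h - height.pop(a):.6g}"
            right = f"{node.pop(b)}:{h - height.pop(b):.6g}"
            node[n + m] = f"({left},{right})"
            height[n + m] = h
        (root,) = node.values()
        return root + ";"


def _escape(label: str) -> str:
    return label.replace(" ", "_")


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """Build a UPGMA dendrogram from an SM similarity matrix.

    The pair with maximum average similarity (minimum distance ``1 - S``)
    is fused at each step; the similarity of a fused cluster to any other
    is the size-weighted arithmetic mean of its members' similarities.

    Raises
    ------
    ValueError
        For non-square, non-symmetric input, values outside [0, 1], a
        non-unit diagonal, or fewer than 2 samples.
    """
    sim = similarity.to_numpy(dtype=float)
    labels = [str(x) for x in similarity.index]
    n = sim.shape[0]
    if sim.shape[0] != sim.shape[1] or n < 2:
        raise ValueError("similarity matrix must be square with >= 2 samples")
    if list(similarity.columns.astype(str)) != labels:
        raise ValueError("row and column labels differ")
    if not np.allclose(sim, sim.T):
        raise ValueError("similarity matrix must be symmetric")
    if sim.min() < 0 or sim.max() > 1 or not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarities must lie in [0,1] with unit diagonal")

    # Deterministic tie rule: operate in lexicographic label order.
    order = sorted(range(n), key=lambda i: labels[i])
    labels_sorted = [labels[i] for i in order]
    dist = 1.0 - sim[np.ix_(order, order)]

    # active cluster id -> (row in dist-like storage) via dict of vectors
    active: dict[int, np.ndarray] = {i: dist[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    col = {i: i for i in range(n)}  # cluster id -> column index in vectors
    linkage = np.zeros((n - 1, 4))

    for m in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, a in enumerate(ids):
            va = active[a]
            for b in ids[ai + 1 :]:
                d = va[col[b]]
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        new = n + m
        wa, wb = sizes[a], sizes[b]
        merged = (wa * active[a] + wb * active[b]) / (wa + wb)
        va_col, vb_col = col[a], col[b]
        del active[a], active[b]
        for cid in active:
            vec = active[cid]
            vec[va_col] = (wa * vec[va_col] + wb * vec[vb_col]) / (wa + wb)
        merged_self = merged.copy()
        for cid in active:
            merged_self[col[cid]] = active[cid][va_col]
        active[new] = merged_self
        sizes[new] = wa + wb
        col[new] = va_col
        linkage[m] = (a, b, d, wa + wb)

    return Dendrogram(labels=labels_sorted, linkage=linkage)


def cophenetic_correlation(tree: Dendrogram, similarity: pd.DataFrame) -> float:
    """Pearson r between tree-implied and observed pairwise similarities.

    Computed over the strict upper triangle after aligning the matrix to
    the tree's leaf order.  Undefined (error) for fewer than 3 leaves.
    """
    if tree.n_leaves < 3:
        raise ValueError("cophenetic correlation needs >= 3 leaves")
    aligned = similarity.loc[tree.labels, tree.labels].to_numpy(dtype=float)
    coph = tree.cophenetic_similarities().to_numpy()
    iu = np.triu_indices(tree.n_leaves, k=1)
    x, y = coph[iu], aligned[iu]
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        # degenerate: one of the vectors is constant
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else float("nan")
    return float(pearsonr(x, y).statistic)
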