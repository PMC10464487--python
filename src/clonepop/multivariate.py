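"""Assumption-light multivariate companions to the Bayesian clustering:
allele-count tables, PCA, DAPC, Nei's genetic distance and the minimum
spanning network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotype_io import GenotypeMatrix

__all__ = [
    "AlleleCountTable",
    "build_count_table",
    "pca",
    "PcaResult",
    "dapc",
    "DapcResult",
    "nei_distance",
    "nei_distance_matrix",
    "minimum_spanning_network",
    "NEI_DISTANCE_CAP",
]

NEI_DISTANCE_CAP = 50.0


@dataclass
class AlleleCountTable:
    """Individuals x (locus, allele) counts in {0, 1, 2}.

    Missing genotypes are mean-imputed per column (population-wide
    mean of the non-missing rows) and flagged in ``imputed``.
    """

    values: np.ndarray            # float (n_individuals, n_columns)
    columns: list[tuple[str, int]]  # (locus name, allele size)
    individuals: list[str]
    populations: list[str]
    imputed: np.ndarray           # bool, same shape as values

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{loc}.{al}" for loc, al in self.columns]
        return pd.DataFrame(self.values, index=self.individuals, columns=cols)


def build_count_table(
    matrix: GenotypeMatrix, missing: str = "mean_impute"
) -> AlleleCountTable:
    """Count each allele per individual per locus (0, 1 or 2 copies)."""
    if missing not in ("mean_impute", "zero"):
        raise ValueError(f"unknown missing policy {missing!r}")
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    imput_blocks: list[np.ndarray] = []
    N = matrix.n_individuals
    for l, locus in enumerate(matrix.loci):
        gen = matrix.calls[:, l, :]
        scored = gen[:, 0] > 0
        alleles = np.unique(gen[scored])
        if alleles.size == 0:
            continue
        block = np.zeros((N, alleles.size))
        for j, a in enumerate(alleles):
            block[:, j] = (gen == a).sum(axis=1)
        imput = np.zeros((N, alleles.size), dtype=bool)
        if (~scored).any():
            if missing == "mean_impute" and scored.any():
                block[~scored] = block[scored].mean(axis=0)
            imput[~scored] = True
        blocks.append(block)
        imput_blocks.append(imput)
        columns.extend((locus.name, int(a)) for a in alleles)
    return AlleleCountTable(
        values=np.hstack(blocks),
        columns=columns,
        individuals=list(matrix.individuals),
        populations=list(matrix.populations),
        imputed=np.hstack(imput_blocks),
    )


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(table: AlleleCountTable, n_axes: int | None = None) -> PcaResult:
    """Centered (unscaled) PCA of the allele-count table."""
    X = table.values
    max_axes = min(X.shape[0] - 1, X.shape[1])
    if n_axes is None:
        n_axes = max_axes
    if n_axes > max_axes:
        raise ValueError(f"n_axes={n_axes} exceeds rank bound {max_axes}")
    model = PCA(n_components=n_axes)
    scores = model.fit_transform(X)
    return PcaResult(
        scores=scores,
        loadings=model.components_.T,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass
class DapcResult:
    coordinates: np.ndarray      # (n_individuals, n_da)
    centroids: dict[str, np.ndarray]
    assignments: list[str]
    reassignment_proportion: float
    n_pca: int
    n_da: int


def dapc(
    table: AlleleCountTable,
    groups: Sequence[str] | None = None,
    n_pca: int | str = "auto",
    n_da: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components.

    Genotype counts are first reduced by PCA (``n_pca='auto'`` keeps
    the axes explaining >= 90% of variance), then Fisher linear
    discriminants maximize between-group over within-group variance.
    The reassignment proportion is the fraction of individuals whose
    nearest predicted group matches their label.
    """
    labels = list(groups) if groups is not None else list(table.populations)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least 2 groups")
    counts = {g: labels.count(g) for g in uniq}
    singletons = [g for g, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(f"groups of size 1 not allowed: {singletons}")
    full = pca(table)
    if n_pca == "auto":
        cum = np.cumsum(full.explained_variance_ratio)
        n_pca = int(np.searchsorted(cum, 0.90) + 1)
    n_pca = min(int(n_pca), full.scores.shape[1])
    max_da = len(uniq) - 1
    if n_da is None:
        n_da = max_da
    if n_da > max_da:
        raise ValueError(f"n_da={n_da} exceeds n_groups - 1 = {max_da}")
    X = full.scores[:, :n_pca]
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    coords = lda.fit_transform(X, labels)
    pred = lda.predict(X)
    centroids = {
        g: coords[np.asarray(labels) == g].mean(axis=0) for g in uniq
    }
    return DapcResult(
        coordinates=coords,
        centroids=centroids,
        assignments=list(pred),
        reassignment_proportion=float(np.mean(np.asarray(pred) == np.asarray(labels))),
        n_pca=n_pca,
        n_da=n_da,
    )


# ---------------------------------------------------------------------------
# Nei distance and minimum spanning network
# ---------------------------------------------------------------------------

def _freq_vectors(matrix: GenotypeMatrix, pop: str) -> list[dict[int, float]]:
    from .popstats import allele_frequencies

    freqs = allele_frequencies(matrix, pop)
    return [freqs.get(loc.name, {}) for loc in matrix.loci]


def nei_distance(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    variant: str = "1972",
) -> float:
    """Nei's standard genetic distance D = -ln I between two populations.

    The identity I averages J_xy, J_x and J_y arithmetically over
    shared scored loci before combining: ``I = mean(Jxy) /
    sqrt(mean(Jx) * mean(Jy))``.  The ``1978`` variant replaces J_x and
    J_y with their small-sample unbiased estimates.  Populations with
    no shared alleles give infinite distance, capped and flagged.
    """
    if variant not in ("1972", "1978"):
        raise ValueError(f"unknown variant {variant!r}")
    fa = _freq_vectors(matrix, pop_a)
    fb = _freq_vectors(matrix, pop_b)
    na = 2 * len(matrix.population_indices(pop_a))
    nb = 2 * len(matrix.population_indices(pop_b))
    jxy, jx, jy = [], [], []
    for pa, pb in zip(fa, fb):
        if not pa or not pb:
            continue
        shared = set(pa) | set(pb)
        jxy.append(sum(pa.get(a, 0.0) * pb.get(a, 0.0) for a in shared))
        sx = sum(v**2 for v in pa.values())
        sy = sum(v**2 for v in pb.values())
        if variant == "1978":
            sx = (na * sx - 1.0) / (na - 1.0)
            sy = (nb * sy - 1.0) / (nb - 1.0)
        jx.append(sx)
        jy.append(sy)
    if not jxy:
        raise ValueError(f"no shared scored loci between {pop_a!r} and {pop_b!r}")
    identity = np.mean(jxy) / np.sqrt(np.mean(jx) * np.mean(jy))
    if identity <= 0.0:
        warnings.warn(
            f"no shared alleles between {pop_a!r} and {pop_b!r}; "
            f"distance capped at {NEI_DISTANCE_CAP}",
            stacklevel=2,
        )
        return NEI_DISTANCE_CAP
    return float(min(-np.log(identity), NEI_DISTANCE_CAP))


def nei_distance_matrix(
    matrix: GenotypeMatrix, variant: str = "1972"
) -> pd.DataFrame:
    pops = matrix.population_names()
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = nei_distance(matrix, pops[i], pops[j], variant)
    return pd.DataFrame(d, index=pops, columns=pops)


def minimum_spanning_network(
    distance_matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    tie_tol: float = 1e-12,
) -> list[tuple[str, str, float]]:
    """Minimum spanning network: an MST that keeps tied alternatives.

    Kruskal's algorithm processed by weight class: within each class of
    (numerically) equal weights, every edge that joins two components
    still separate at the start of the class is retained, so co-minimal
    edges all appear and the result is a network rather than a strict
    tree.  Ties make the total weight equal to the MST optimum.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    edges = sorted(
        ((D[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    out: list[tuple[str, str, float]] = []
    k = 0
    while k < len(edges):
        w = edges[k][0]
        cls = []
        while k < len(edges) and edges[k][0] <= w + tie_tol:
            cls.append(edges[k])
            k += 1
        snapshot = [find(i) for i in range(n)]
        joins = [
            (wt, i, j) for wt, i, j in cls if snapshot[i] != snapshot[j]
        ]
        for wt, i, j in joins:
            out.append((labels[i], labels[j], float(wt)))
        for _, i, j in joins:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    return out
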