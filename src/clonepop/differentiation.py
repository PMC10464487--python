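"""Population differentiation: Weir-Cockerham FST with permutation tests.

theta is the Weir-Cockerham (1984) variance-components estimator of
FST, summed over alleles and loci:
``theta = sum(a) / sum(a + b + c)`` where a, b and c are the among-
population, among-individual and within-individual components.
Negative estimates are reported as computed.  Analyses can run on the
full per-individual dataset or on a per-genotype dataset in which each
clonal group keeps a single representative per population, avoiding
the downward bias clones induce on within-population variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .clonality import ClonePartition
from .genotype_io import GenotypeMatrix

__all__ = [
    "FstResult",
    "to_per_genotype",
    "pairwise_theta",
    "permutation_test",
    "pairwise_fst_matrix",
    "regional_theta",
]


@dataclass
class FstResult:
    labels: list[str]
    theta: np.ndarray      # symmetric, NaN diagonal
    p_perm: np.ndarray | None
    n_perm: int
    dataset_mode: str = "per_individual"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.theta, index=self.labels, columns=self.labels)


def to_per_genotype(
    matrix: GenotypeMatrix, partition: ClonePartition
) -> GenotypeMatrix:
    """Keep one representative of each clonal group per population.

    The representative is the first-sampled member within each
    population, so clone-free matrices pass through unchanged.
    """
    group_of = partition.group_of()
    seen: set[tuple[str, str]] = set()
    keep: list[int] = []
    for i, ind in enumerate(matrix.individuals):
        gid = group_of.get(ind)
        if gid is None:  # unassigned (all-missing) individuals are dropped
            continue
        key = (matrix.populations[i], gid)
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return matrix.subset(keep)


def _wc_components(
    calls_by_pop: list[np.ndarray], n_loci: int
) -> tuple[float, float, float]:
    """Summed W&C (a, b, c) over loci and alleles for r populations."""
    r = len(calls_by_pop)
    A = B = C = 0.0
    for l in range(n_loci):
        per_pop = []
        for calls in calls_by_pop:
            g = calls[:, l, :]
            g = g[g[:, 0] > 0]
            per_pop.append(g)
        ns = np.array([g.shape[0] for g in per_pop], dtype=float)
        if (ns < 2).any():
            continue
        alleles = np.unique(np.concatenate([g.ravel() for g in per_pop]))
        if alleles.size < 2:
            continue  # monomorphic across these populations
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        for a_val in alleles:
            p = np.array([float((g == a_val).mean()) for g in per_pop])
            h = np.array(
                [float(((g[:, 0] == a_val) ^ (g[:, 1] == a_val)).mean()) for g in per_pop]
            )
            pbar = float((ns * p).sum() / (r * nbar))
            s2 = float((ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar))
            hbar = float((ns * h).sum() / (r * nbar))
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2.0
            A += a
            B += b
            C += c
    return A, B, C


def global_theta(matrix: GenotypeMatrix) -> float:
    """Multilocus Weir-Cockerham theta over all populations at once."""
    pops = matrix.population_names()
    if len(pops) < 2:
        raise ValueError("global theta needs at least 2 populations")
    calls = [matrix.calls[matrix.population_indices(p)] for p in pops]
    A, B, C = _wc_components(calls, matrix.n_loci)
    denom = A + B + C
    if denom == 0.0:
        raise ValueError("no polymorphic locus shared across populations")
    return A / denom


def pairwise_theta(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> float:
    """Multilocus Weir-Cockerham theta between two populations."""
    ca = matrix.calls[matrix.population_indices(pop_a)]
    cb = matrix.calls[matrix.population_indices(pop_b)]
    A, B, C = _wc_components([ca, cb], matrix.n_loci)
    denom = A + B + C
    if denom == 0.0:
        raise ValueError(
            f"no shared polymorphic locus between {pop_a!r} and {pop_b!r}"
        )
    return A / denom


def permutation_test(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for theta between two populations.

    Individuals are shuffled between the two populations keeping
    sample sizes; ``p = (1 + #{theta* >= theta_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ia = matrix.population_indices(pop_a)
    ib = matrix.population_indices(pop_b)
    if ia.size + ib.size < 4:
        raise ValueError("need at least 4 individuals combined")
    obs = pairwise_theta(matrix, pop_a, pop_b)
    pool = np.concatenate([ia, ib])
    na = ia.size
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        ca = matrix.calls[perm[:na]]
        cb = matrix.calls[perm[na:]]
        A, B, C = _wc_components([ca, cb], matrix.n_loci)
        denom = A + B + C
        theta = A / denom if denom != 0.0 else 0.0
        if theta >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def pairwise_fst_matrix(
    matrix: GenotypeMatrix,
    n_perm: int = 0,
    seed: int = 0,
    dataset_mode: str = "per_individual",
) -> FstResult:
    """All pairwise thetas (and optional permutation p-values)."""
    pops = matrix.population_names()
    k = len(pops)
    theta = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan) if n_perm else None
    for i in range(k):
        for j in range(i + 1, k):
            theta[i, j] = theta[j, i] = pairwise_theta(matrix, pops[i], pops[j])
            if n_perm:
                pv = permutation_test(
                    matrix, pops[i], pops[j], n_perm=n_perm, seed=seed + i * k + j
                )
                p[i, j] = p[j, i] = pv
    return FstResult(pops, theta, p, n_perm, dataset_mode)


def regional_theta(
    matrix: GenotypeMatrix,
    region_mapping: Mapping[str, str],
    n_perm: int = 0,
    seed: int = 0,
) -> FstResult:
    """Pairwise theta between regions (populations pooled by region)."""
    missing = [p for p in matrix.population_names() if p not in region_mapping]
    if missing:
        raise ValueError(f"populations without region: {missing}")
    regions = [region_mapping[p] for p in matrix.populations]
    if any(
        reg not in set(regions) for reg in set(region_mapping.values())
    ):  # pragma: no cover - mapping values all appear by construction
        raise ValueError("empty region")
    pooled = GenotypeMatrix(
        individuals=list(matrix.individuals),
        populations=regions,
        loci=list(matrix.loci),
        calls=matrix.calls.copy(),
    )
    res = pairwise_fst_matrix(pooled, n_perm=n_perm, seed=seed)
    res.dataset_mode = "regional"
    return res
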