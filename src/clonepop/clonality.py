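"""Clone detection and clonal-structure statistics.

A multilocus genotype (MLG) is the combined allele calls of one
individual over all scored loci; identical MLGs flag putative clonal
ramets of one genet.  MLGs are optionally collapsed into multilocus
lineages (MLLs) under a stepwise-mutation distance threshold, to absorb
somatic mutation and scoring error.  From the partition of a population
into clonal groups the module derives the standard clonality summary:
clonal richness R, Stoddart-Taylor genotypic diversity Go with its
full-sexuality expectation Ge = N, evenness Go / N_MLG, Simpson and
Shannon indices, and a randomization test of the hypothesis that the
observed genotypic diversity arose under purely sexual reproduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genotype_io import GenotypeMatrix

__all__ = [
    "ClonePartition",
    "ClonalStats",
    "PidResult",
    "probability_of_identity",
    "assign_mlg",
    "collapse_mll",
    "mlg_distance",
    "sexual_null_test",
    "clonal_statistics",
    "clonal_stats_from_sizes",
    "diversity_evenness_regression",
]


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

@dataclass
class ClonePartition:
    """Partition of individuals into clonal groups (MLGs or MLLs)."""

    level: Literal["MLG", "MLL"]
    groups: dict[str, list[str]]
    representative: dict[str, str]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = [m for g in self.groups.values() for m in g]
        if len(members) != len(set(members)):
            raise ValueError("groups overlap: an individual appears twice")
        if any(not g for g in self.groups.values()):
            raise ValueError("empty group in partition")
        for gid, rep in self.representative.items():
            if rep not in self.groups[gid]:
                raise ValueError(f"representative {rep!r} not in group {gid!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict[str, str]:
        """Map individual id -> group id."""
        return {m: gid for gid, mem in self.groups.items() for m in mem}

    def group_sizes(self, individuals: Iterable[str] | None = None) -> list[int]:
        """Group sizes, optionally restricted to a subset of individuals."""
        if individuals is None:
            return [len(m) for m in self.groups.values()]
        keep = set(individuals)
        sizes = [sum(1 for m in mem if m in keep) for mem in self.groups.values()]
        return [s for s in sizes if s > 0]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assign_mlg(
    matrix: GenotypeMatrix,
    missing_policy: Literal["observed", "strict"] = "observed",
    min_loci: int = 4,
) -> ClonePartition:
    """Group individuals into multilocus genotypes.

    Under the default ``observed`` policy two individuals share an MLG
    when their calls are equal at every locus where both are scored and
    that overlap covers at least ``min_loci`` loci; matching is closed
    transitively (single linkage), which mirrors manual clone calling
    on incomplete data.  Under ``strict`` only individuals with
    complete data can be co-assigned, and they must match everywhere.
    Individuals missing at every locus are reported as unassigned.
    """
    n = matrix.n_individuals
    miss = matrix.missing_mask
    all_missing = miss.all(axis=1)
    uf = _UnionFind(n)
    scored = np.flatnonzero(~all_missing)
    calls = matrix.calls
    for ii, i in enumerate(scored):
        for j in scored[ii + 1:]:
            both = ~(miss[i] | miss[j])
            if missing_policy == "strict":
                if miss[i].any() or miss[j].any():
                    continue
                if (calls[i] == calls[j]).all():
                    uf.union(i, j)
            else:
                if both.sum() < min(min_loci, matrix.n_loci):
                    continue
                if (calls[i][both] == calls[j][both]).all():
                    uf.union(i, j)

    roots: dict[int, list[int]] = {}
    for i in scored:
        roots.setdefault(uf.find(i), []).append(int(i))
    groups: dict[str, list[str]] = {}
    representative: dict[str, str] = {}
    for k, (root, members) in enumerate(sorted(roots.items()), start=1):
        gid = f"MLG{k:04d}"
        groups[gid] = [matrix.individuals[m] for m in sorted(members)]
        representative[gid] = matrix.individuals[min(members)]
    unassigned = [matrix.individuals[i] for i in np.flatnonzero(all_missing)]
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} individual(s) missing at all loci left unassigned",
            stacklevel=2,
        )
    return ClonePartition("MLG", groups, representative, unassigned)


def mlg_distance(
    g1: np.ndarray, g2: np.ndarray, motif_lengths: Sequence[int]
) -> int:
    """Stepwise-mutation distance between two multilocus genotypes.

    Per locus: the smaller total |size difference| / motif_length over
    the two ways of pairing the alleles; loci missing in either
    genotype contribute zero.  Non-integer step counts (size difference
    not a motif multiple) are rounded to the nearest step with a
    warning.
    """
    total = 0.0
    inexact = False
    for l, m in enumerate(motif_lengths):
        a, b = g1[l], g2[l]
        if (a == 0).all() or (b == 0).all():
            continue
        d1 = abs(int(a[0]) - int(b[0])) + abs(int(a[1]) - int(b[1]))
        d2 = abs(int(a[0]) - int(b[1])) + abs(int(a[1]) - int(b[0]))
        steps = min(d1, d2) / m
        if steps != int(steps):
            inexact = True
        total += steps
    if inexact:
        warnings.warn(
            "size difference not a motif multiple; rounded to nearest step",
            stacklevel=2,
        )
    return int(round(total))


def collapse_mll(
    partition: ClonePartition,
    matrix: GenotypeMatrix,
    threshold_steps: int = 4,
) -> ClonePartition:
    """Collapse MLGs into multilocus lineages.

    MLG representatives whose stepwise-mutation distance is at most
    ``threshold_steps`` are merged by single linkage; the default of
    four steps with one-step mutations absorbs somatic mutation and
    one-off scoring slips without collapsing genuinely sexual
    genotypes.
    """
    if partition.level != "MLG":
        raise ValueError("collapse_mll expects an MLG-level partition")
    idx = {name: i for i, name in enumerate(matrix.individuals)}
    motifs = [loc.motif_length for loc in matrix.loci]
    gids = list(partition.groups)
    reps = [matrix.calls[idx[partition.representative[g]]] for g in gids]
    k = len(gids)
    uf = _UnionFind(k)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for i in range(k):
            for j in range(i + 1, k):
                if mlg_distance(reps[i], reps[j], motifs) <= threshold_steps:
                    uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(k):
        clusters.setdefault(uf.find(i), []).append(i)
    groups: dict[str, list[str]] = {}
    representative: dict[str, str] = {}
    for m, (root, members) in enumerate(sorted(clusters.items()), start=1):
        gid = f"MLL{m:04d}"
        merged = [ind for i in members for ind in partition.groups[gids[i]]]
        groups[gid] = merged
        representative[gid] = partition.representative[gids[min(members)]]
    return ClonePartition("MLL", groups, representative, list(partition.unassigned))


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

@dataclass
class PidResult:
    per_locus: dict[str, float]
    combined: float


def probability_of_identity(
    freqs: Mapping[str, np.ndarray] | Sequence[np.ndarray],
) -> PidResult:
    """Probability that two random sexual genotypes match by chance.

    Per locus ``P_ID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2``; the
    multilocus value is the product over loci (independence).
    """
    if not isinstance(freqs, Mapping):
        freqs = {f"locus{i + 1}": f for i, f in enumerate(freqs)}
    if not freqs:
        raise ValueError("no loci supplied")
    per_locus: dict[str, float] = {}
    for name, p in freqs.items():
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValueError(f"locus {name!r} has no alleles")
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(f"locus {name!r}: frequencies sum to {p.sum()}")
        hom = float((p**4).sum())
        outer = np.outer(p, p)
        het = float((4.0 * outer**2)[np.triu_indices(p.size, k=1)].sum())
        per_locus[name] = hom + het
    combined = float(np.prod(list(per_locus.values())))
    return PidResult(per_locus=per_locus, combined=combined)


# ---------------------------------------------------------------------------
# randomization test of sexuality
# ---------------------------------------------------------------------------

def _count_distinct_rows(calls: np.ndarray) -> int:
    flat = calls.reshape(calls.shape[0], -1)
    return np.unique(flat, axis=0).shape[0]


def sexual_null_test(
    matrix: GenotypeMatrix,
    population: str,
    n_rand: int = 999,
    seed: int = 0,
) -> float:
    """Randomization test: could the observed clonal diversity be sexual?

    Alleles are permuted among individuals independently within each
    locus (missing slots stay missing), destroying genotypic but not
    allelic structure; each replicate recounts the number of distinct
    multilocus genotypes.  ``p = (1 + #{N_MLG* <= N_MLG_obs}) /
    (n_rand + 1)``: a small p means the observed number of genotypes is
    too low for random mating, i.e. clonality.  Genotype identity here
    is exact row equality, the same count applied to observed and
    permuted data.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99 for a meaningful p-value")
    idx = matrix.population_indices(population)
    if idx.size < 2:
        raise ValueError(f"population {population!r} has fewer than 2 individuals")
    calls = matrix.calls[idx].copy()
    n, L, _ = calls.shape
    observed = _count_distinct_rows(calls)
    rng = np.random.default_rng(seed)
    count = 0
    flat = calls.reshape(n, L, 2)
    for _ in range(n_rand):
        perm = flat.copy()
        for l in range(L):
            pool = perm[:, l, :].ravel()
            scored = pool > 0
            vals = pool[scored]
            rng.shuffle(vals)
            pool[scored] = vals
            perm[:, l, :] = np.sort(pool.reshape(n, 2), axis=1)
        if _count_distinct_rows(perm) <= observed:
            count += 1
    return (1 + count) / (n_rand + 1)


# ---------------------------------------------------------------------------
# clonal statistics
# ---------------------------------------------------------------------------

_MODE_THRESHOLDS = {"predominantly_sexual": 0.65, "mostly_sexual": 0.5}


@dataclass
class ClonalStats:
    """Per-population clonal structure summary.

    R = (N_MLG - 1) / (N - 1); Go = 1 / sum((n_i / N)^2) is the
    Stoddart-Taylor observed genotypic diversity; Ge = N its
    expectation when every individual is a distinct genet; G = Go / Ge;
    evenness E_D = Go / N_MLG; simpson_1mD is the unbiased Simpson
    index (N / (N - 1)) * (1 - sum g_i^2); shannon_H uses log base 10.
    """

    population: str
    N: int
    N_MLG: int
    R: float
    Go: float
    Ge: float
    G: float
    E_D: float
    simpson_1mD: float
    shannon_H: float
    mode_label: str

    @property
    def evenness_go_nmlg(self) -> float:
        return self.E_D


def _mode_label(G: float, thresholds: Mapping[str, float] = _MODE_THRESHOLDS) -> str:
    if np.isclose(G, 1.0):
        return "fully_sexual"
    if G >= thresholds["predominantly_sexual"]:
        return "predominantly_sexual"
    if G >= thresholds["mostly_sexual"]:
        return "mostly_sexual"
    return "mixed_clonal"


def clonal_stats_from_sizes(
    group_sizes: Sequence[int],
    population: str = "",
    shannon_bias_correction: bool = False,
) -> ClonalStats:
    """Clonal statistics from explicit clonal group sizes.

    ``shannon_bias_correction`` adds the first-order small-sample
    (Miller-Maddow) correction (S - 1) / (2 N ln 10) to the plug-in
    Shannon index; off by default.
    """
    sizes = np.asarray([s for s in group_sizes if s > 0], dtype=float)
    N = int(sizes.sum())
    if N < 2:
        raise ValueError("need at least 2 individuals for clonal statistics")
    n_mlg = sizes.size
    g = sizes / N
    sum_g2 = float((g**2).sum())
    Go = 1.0 / sum_g2
    Ge = float(N)
    G = Go / Ge
    R = (n_mlg - 1) / (N - 1)
    E_D = Go / n_mlg
    simpson = (N / (N - 1)) * (1.0 - sum_g2)
    shannon = float(-(g * np.log10(g)).sum())
    if shannon_bias_correction:
        shannon += (n_mlg - 1) / (2.0 * N * np.log(10.0))
    return ClonalStats(
        population=population,
        N=N,
        N_MLG=int(n_mlg),
        R=R,
        Go=Go,
        Ge=Ge,
        G=G,
        E_D=E_D,
        simpson_1mD=simpson,
        shannon_H=shannon,
        mode_label=_mode_label(G),
    )


def clonal_statistics(
    matrix: GenotypeMatrix,
    partition: ClonePartition,
    population: str,
    shannon_bias_correction: bool = False,
) -> ClonalStats:
    """Clonal statistics for one population under a clone partition."""
    idx = matrix.population_indices(population)
    members = [matrix.individuals[i] for i in idx]
    sizes = partition.group_sizes(members)
    if not sizes:
        raise ValueError(f"no assigned individuals in population {population!r}")
    return clonal_stats_from_sizes(
        sizes, population=population, shannon_bias_correction=shannon_bias_correction
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def diversity_evenness_regression(
    stats_list: Sequence[ClonalStats],
) -> RegressionResult:
    """OLS of genotypic diversity G on evenness Go / N_MLG across populations.

    A tight positive relationship indicates that departures from full
    sexuality are driven by a few expanded clones rather than uniform
    clonal replication.  The p-value is the F test of the slope with
    (1, n - 2) degrees of freedom.
    """
    if len(stats_list) < 3:
        raise ValueError("need at least 3 populations for the regression")
    x = np.array([s.E_D for s in stats_list], dtype=float)
    y = np.array([s.G for s in stats_list], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in evenness; regression undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(stats_list),
    )
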