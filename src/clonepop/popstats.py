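"""Per-population, per-locus summary statistics.

Covers allele frequencies, mean allelic richness and private alleles,
observed/expected heterozygosity, the within-population inbreeding
coefficient FIS as a Weir-Cockerham variance-components estimator with
a bootstrap-over-loci confidence interval, Hardy-Weinberg exact tests
(Levene's conditional distribution, full enumeration or Monte Carlo),
and a homozygote-excess screen for null alleles with a
Chakraborty-style null frequency estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln
from scipy.stats import false_discovery_control

from .genotype_io import GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "allelic_richness_and_private",
    "heterozygosity",
    "fis",
    "FisResult",
    "hwe_exact",
    "HweResult",
    "null_allele_screen",
    "NullAlleleResult",
    "hwe_fdr",
]


def _pop_calls(matrix: GenotypeMatrix, population: str) -> np.ndarray:
    return matrix.calls[matrix.population_indices(population)]


def allele_frequencies(
    matrix: GenotypeMatrix, population: str
) -> dict[str, dict[int, float]]:
    """Allele frequency table per locus, over non-missing calls.

    Loci with zero scored calls in the population are excluded with a
    warning.
    """
    calls = _pop_calls(matrix, population)
    out: dict[str, dict[int, float]] = {}
    for l, locus in enumerate(matrix.loci):
        alleles = calls[:, l, :].ravel()
        alleles = alleles[alleles > 0]
        if alleles.size == 0:
            warnings.warn(
                f"locus {locus.name} has no scored calls in {population}; excluded",
                stacklevel=2,
            )
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        out[locus.name] = {
            int(v): float(c) / alleles.size for v, c in zip(vals, counts)
        }
    return out


def allelic_richness_and_private(
    matrix: GenotypeMatrix,
) -> dict[str, dict[str, float]]:
    """Mean alleles per locus (Na +/- SE) and private alleles (Np +/- SE).

    A private allele is observed in exactly one population.  SE is the
    standard deviation over loci divided by sqrt(n_loci).
    """
    pops = matrix.population_names()
    if len(pops) < 2:
        raise ValueError("private alleles need at least 2 populations")
    L = matrix.n_loci
    # which alleles each population carries, per locus
    carried: dict[str, list[set[int]]] = {}
    for p in pops:
        calls = _pop_calls(matrix, p)
        carried[p] = [
            set(int(a) for a in calls[:, l, :].ravel() if a > 0) for l in range(L)
        ]
    out: dict[str, dict[str, float]] = {}
    for p in pops:
        na = np.array([len(carried[p][l]) for l in range(L)], dtype=float)
        np_counts = np.array(
            [
                sum(
                    1
                    for a in carried[p][l]
                    if not any(a in carried[q][l] for q in pops if q != p)
                )
                for l in range(L)
            ],
            dtype=float,
        )
        out[p] = {
            "Na_mean": float(na.mean()),
            "Na_se": float(na.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0,
            "Np_mean": float(np_counts.mean()),
            "Np_se": float(np_counts.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0,
        }
    return out


def heterozygosity(
    matrix: GenotypeMatrix, population: str
) -> dict[str, float]:
    """Observed and expected heterozygosity, averaged over scored loci.

    ``He_biased`` is the plug-in 1 - sum(p^2); ``He_unbiased`` applies
    Nei's 2n/(2n - 1) small-sample factor per locus.
    """
    calls = _pop_calls(matrix, population)
    ho, he_b, he_u = [], [], []
    for l in range(matrix.n_loci):
        gen = calls[:, l, :]
        scored = gen[:, 0] > 0
        if not scored.any():
            continue
        g = gen[scored]
        ho.append(float((g[:, 0] != g[:, 1]).mean()))
        alleles = g.ravel()
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / alleles.size
        h = 1.0 - float((p**2).sum())
        he_b.append(h)
        n2 = alleles.size  # 2n gene copies
        he_u.append(h * n2 / (n2 - 1) if n2 > 1 else h)
    if not ho:
        raise ValueError(f"no scored loci in population {population!r}")
    return {
        "Ho": float(np.mean(ho)),
        "He_biased": float(np.mean(he_b)),
        "He_unbiased": float(np.mean(he_u)),
    }


# ---------------------------------------------------------------------------
# FIS (Weir & Cockerham within-population f)
# ---------------------------------------------------------------------------

@dataclass
class FisResult:
    f: float
    ci_low: float
    ci_high: float
    n_loci: int


def _fis_components(calls: np.ndarray, loci_idx: np.ndarray) -> tuple[float, float]:
    """Summed (c, b + c) variance components over the given loci."""
    sum_c = 0.0
    sum_bc = 0.0
    for l in loci_idx:
        gen = calls[:, l, :]
        g = gen[gen[:, 0] > 0]
        n = g.shape[0]
        if n < 2:
            continue
        alleles = g.ravel()
        for a in np.unique(alleles):
            p = float((alleles == a).mean())
            h = float(((g[:, 0] == a) ^ (g[:, 1] == a)).mean())
            b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
            c = h / 2.0
            sum_c += c
            sum_bc += b + c
    return sum_c, sum_bc


def fis(
    matrix: GenotypeMatrix,
    population: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> FisResult:
    """Multilocus inbreeding coefficient f with bootstrap-over-loci 95% CI.

    Weir-Cockerham variance components are summed over alleles and
    loci: ``f = 1 - sum(c) / sum(b + c)``.  Negative f means
    heterozygote excess.  Monomorphic populations have no within-locus
    variance and yield NaN.
    """
    calls = _pop_calls(matrix, population)
    all_loci = np.arange(matrix.n_loci)
    sum_c, sum_bc = _fis_components(calls, all_loci)
    if sum_bc == 0.0:
        warnings.warn(
            f"population {population!r} monomorphic; FIS undefined", stacklevel=2
        )
        return FisResult(float("nan"), float("nan"), float("nan"), matrix.n_loci)
    f = 1.0 - sum_c / sum_bc
    if matrix.n_loci < 2 or n_boot < 1:
        return FisResult(f, float("nan"), float("nan"), matrix.n_loci)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        pick = rng.integers(matrix.n_loci, size=matrix.n_loci)
        c_, bc_ = _fis_components(calls, pick)
        if bc_ > 0:
            reps.append(1.0 - c_ / bc_)
    lo, hi = (
        np.percentile(reps, [2.5, 97.5]) if reps else (float("nan"),) * 2
    )
    return FisResult(f, float(lo), float(hi), matrix.n_loci)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene)
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    p_two_sided: float
    p_het_deficit: float
    method: str
    n_arrays: int | None = None


def _log_array_prob(
    het_counts: np.ndarray, hom_counts: np.ndarray, log_const: float
) -> float:
    """Log conditional probability of one genotype array (Levene).

    P = n! 2^H prod(m_a!) / ( (2n)! prod(n_ij!) ) split as a constant
    part (passed in) plus the array-dependent part.
    """
    H = het_counts.sum()
    return float(
        log_const
        + H * np.log(2.0)
        - gammaln(het_counts + 1).sum()
        - gammaln(hom_counts + 1).sum()
    )


def _enumerate_arrays(allele_counts: np.ndarray):
    """Yield (hom_counts, het_counts_matrix_upper) genotype arrays.

    Enumerates all symmetric genotype-count arrays consistent with the
    allele counts via recursion over alleles.
    """
    K = allele_counts.size

    def rec(a: int, remaining: np.ndarray, homs: list[int], hets: list[tuple[int, int, int]]):
        if a == K:
            yield np.array(homs), hets
            return
        m = remaining[a]
        if m < 0:
            return
        for n_aa in range(m // 2, -1, -1):
            rest = m - 2 * n_aa
            # distribute `rest` copies among het pairs (a, b>a)
            partners = [b for b in range(a + 1, K)]

            def dist(pi: int, left: int, acc: list[tuple[int, int, int]]):
                if pi == len(partners):
                    if left == 0:
                        rem2 = remaining.copy()
                        rem2[a] = 0
                        for (_, b, c) in acc:
                            rem2[b] -= c
                        yield from rec(a + 1, rem2, homs + [n_aa], hets + acc)
                    return
                b = partners[pi]
                cap = min(left, remaining[b])
                for c in range(cap, -1, -1):
                    yield from dist(pi + 1, left - c, acc + [(a, b, c)] if c else acc)

            yield from dist(0, rest, [])

    yield from rec(0, allele_counts.copy(), [], [])


def hwe_exact(
    matrix: GenotypeMatrix,
    population: str,
    locus: str,
    mode: Literal["auto", "enumerate", "mc"] = "auto",
    n_mc: int = 10000,
    seed: int = 0,
    max_enum_arrays: int = 200_000,
) -> HweResult:
    """Exact Hardy-Weinberg test conditional on allele counts.

    Uses Levene's conditional distribution of genotype arrays given the
    allele counts.  The two-sided p sums the probabilities of all
    arrays no more probable than the observed one; the heterozygote-
    deficit p uses the number of heterozygotes as a one-sided
    statistic (small = deficit).  Small tables are fully enumerated;
    larger ones fall back to Monte-Carlo permutation of allele copies.
    """
    li = [loc.name for loc in matrix.loci].index(locus)
    calls = _pop_calls(matrix, population)[:, li, :]
    g = calls[calls[:, 0] > 0]
    if g.shape[0] == 0:
        raise ValueError(f"locus {locus} unscored in population {population!r}")
    alleles_obs = np.unique(g)
    if alleles_obs.size < 2:
        warnings.warn(f"locus {locus} monomorphic in {population!r}; p = 1", stacklevel=2)
        return HweResult(1.0, 1.0, "degenerate")
    remap = {int(a): i for i, a in enumerate(alleles_obs)}
    gi = np.vectorize(remap.get)(g)
    K = alleles_obs.size
    n = gi.shape[0]
    allele_counts = np.bincount(gi.ravel(), minlength=K)
    log_const = (
        gammaln(n + 1) + gammaln(allele_counts + 1).sum() - gammaln(2 * n + 1)
    )

    def array_stats(gen: np.ndarray) -> tuple[float, int]:
        """(log prob, het count) of a sample of genotypes (n, 2)."""
        het = gen[:, 0] != gen[:, 1]
        hom_counts = np.bincount(gen[~het, 0], minlength=K)
        pair_ids = gen[het, 0] * K + gen[het, 1]
        het_counts = np.bincount(pair_ids, minlength=K * K)
        het_counts = het_counts[het_counts > 0]
        lp = _log_array_prob(het_counts, hom_counts, log_const)
        return lp, int(het.sum())

    gs = np.sort(gi, axis=1)
    lp_obs, het_obs = array_stats(gs)

    if mode == "auto":
        # crude size guard: enumerate only genuinely small tables
        mode = "enumerate" if (n <= 12 and K <= 4) else "mc"

    if mode == "enumerate":
        p_two = 0.0
        p_def = 0.0
        count = 0
        for homs, hets in _enumerate_arrays(allele_counts):
            count += 1
            if count > max_enum_arrays:
                raise RuntimeError(
                    "enumeration bound exceeded; use mode='mc'"
                )
            het_counts = np.array([c for (_, _, c) in hets], dtype=np.int64)
            lp = _log_array_prob(het_counts, homs, log_const)
            H = int(het_counts.sum()) if het_counts.size else 0
            pr = np.exp(lp)
            if lp <= lp_obs + 1e-12:
                p_two += pr
            if H <= het_obs:
                p_def += pr
        return HweResult(min(p_two, 1.0), min(p_def, 1.0), "enumerate", count)

    rng = np.random.default_rng(seed)
    pool = gi.ravel().copy()
    hits_two = 0
    hits_def = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        gen = np.sort(pool.reshape(n, 2), axis=1)
        lp, H = array_stats(gen)
        if lp <= lp_obs + 1e-12:
            hits_two += 1
        if H <= het_obs:
            hits_def += 1
    return HweResult(
        (1 + hits_two) / (n_mc + 1), (1 + hits_def) / (n_mc + 1), "mc"
    )


def hwe_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a family of HWE tests."""
    return false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


# ---------------------------------------------------------------------------
# null allele screen
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleResult:
    flagged: bool
    p_het_deficit: float
    null_freq_estimate: float
    Ho: float
    He: float


def null_allele_screen(
    matrix: GenotypeMatrix,
    population: str,
    locus: str,
    alpha: float = 0.05,
    n_mc: int = 5000,
    seed: int = 0,
) -> NullAlleleResult:
    """Flag a locus whose homozygote excess suggests a null allele.

    The one-sided heterozygote-deficit exact test provides the p-value;
    the null frequency is estimated as r = (He - Ho) / (He + Ho)
    (Chakraborty), clipped at 0.
    """
    res = hwe_exact(matrix, population, locus, mode="auto", n_mc=n_mc, seed=seed)
    li = [loc.name for loc in matrix.loci].index(locus)
    calls = _pop_calls(matrix, population)[:, li, :]
    g = calls[calls[:, 0] > 0]
    if g.shape[0] == 0:
        raise ValueError(f"locus {locus} unscored in {population!r}")
    ho = float((g[:, 0] != g[:, 1]).mean())
    alleles = g.ravel()
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / alleles.size
    he = 1.0 - float((p**2).sum())
    r = (he - ho) / (he + ho) if (he + ho) > 0 else 0.0
    return NullAlleleResult(
        flagged=res.p_het_deficit < alpha,
        p_het_deficit=res.p_het_deficit,
        null_freq_estimate=max(0.0, r),
        Ho=ho,
        He=he,
    )
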