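"""Bayesian admixture-model clustering and Evanno Delta-K selection.

The model: each of K clusters has its own allele-frequency profile P;
each diploid individual i has membership proportions Q[i] and every
allele copy originates from cluster k with probability Q[i, k].  A
collapsed Gibbs sampler alternates (i) sampling the cluster origin Z
of every allele copy given (Q, P), (ii) Dirichlet updates of P given
Z, (iii) Dirichlet updates of Q given Z, and (iv) a Metropolis
random-walk on the shared admixture parameter alpha.  The estimated
log probability of the data uses the standard harmonic adjustment
``lnPD = mean(l) - var(l) / 2`` over post-burn-in log-likelihood
samples, and the number of clusters is chosen by the Delta-K method:
the second-order rate of change of lnPD across K, normalized by the
replicate standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import GenotypeMatrix

__all__ = [
    "AdmixtureRun",
    "DeltaKTable",
    "UNASSIGNED",
    "run_admixture",
    "evanno_delta_k",
    "assign_clusters",
    "align_replicates",
]

UNASSIGNED = -1


@dataclass
class AdmixtureRun:
    K: int
    Q: np.ndarray                 # (n_individuals, K) posterior-mean memberships
    P: np.ndarray                 # (K, n_loci, max_alleles) posterior-mean frequencies
    alpha: float                  # posterior-mean admixture parameter
    lnPD: float
    seed: int
    burnin: int
    iters: int
    locprior_used: bool = False
    individuals: list[str] = field(default_factory=list)
    z_trace: np.ndarray | None = None  # (kept sweeps, copies) when collected


def _encode(matrix: GenotypeMatrix):
    """Flatten non-missing allele copies to (ind, locus, allele-index)."""
    L = matrix.n_loci
    allele_maps: list[dict[int, int]] = []
    n_alleles = np.zeros(L, dtype=int)
    for l in range(L):
        vals = np.unique(matrix.calls[:, l, :])
        vals = vals[vals > 0]
        allele_maps.append({int(v): i for i, v in enumerate(vals)})
        n_alleles[l] = len(vals)
    ind_idx, locus_idx, allele_idx = [], [], []
    for i in range(matrix.n_individuals):
        for l in range(L):
            a, b = matrix.calls[i, l]
            if a == 0:
                continue
            for v in (a, b):
                ind_idx.append(i)
                locus_idx.append(l)
                allele_idx.append(allele_maps[l][int(v)])
    return (
        np.asarray(ind_idx),
        np.asarray(locus_idx),
        np.asarray(allele_idx),
        n_alleles,
        allele_maps,
    )


def _sample_dirichlet_rows(rng, shape_param: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Sample Dirichlet rows via gamma draws; invalid cells forced to 0."""
    g = rng.gamma(np.where(valid, shape_param, 1.0))
    g = np.where(valid, g, 0.0)
    tot = g.sum(axis=-1, keepdims=True)
    tot[tot == 0.0] = 1.0
    return g / tot


def run_admixture(
    matrix: GenotypeMatrix,
    K: int,
    burnin: int = 2000,
    iters: int = 10000,
    alpha_init: float = 1.0,
    lambda_: float = 1.0,
    locprior: bool = False,
    locprior_r: float = 1.0,
    freq_model: Literal["independent", "correlated"] = "independent",
    freq_f: float = 0.05,
    update_alpha: bool = True,
    collect_z: bool = False,
    seed: int = 0,
) -> AdmixtureRun:
    """Run one Gibbs chain of the admixture model.

    ``iters`` is the total number of sweeps; the first ``burnin`` are
    discarded.  ``locprior`` enables a simplified location-informed
    prior in which individuals of one population share a Dirichlet
    prior mean on Q (strength ``locprior_r * K``).  ``freq_model =
    'correlated'`` ties cluster frequencies to a sampled ancestral
    profile with drift parameter ``freq_f`` (a simplified F-model);
    the default keeps cluster frequencies independent.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")

    rng = np.random.default_rng(seed)
    ind_idx, locus_idx, allele_idx, n_alleles, _ = _encode(matrix)
    N, L = matrix.n_individuals, matrix.n_loci
    Amax = int(n_alleles.max())
    valid = np.arange(Amax)[None, :] < n_alleles[:, None]          # (L, Amax)
    valid_klA = np.broadcast_to(valid, (K, L, Amax))

    pops = np.asarray(matrix.populations)
    pop_labels = matrix.population_names()
    pop_of = np.array([pop_labels.index(p) for p in pops])
    S = len(pop_labels)

    alpha = float(alpha_init)
    Q = np.full((N, K), 1.0 / K)
    P = _sample_dirichlet_rows(rng, np.full((K, L, Amax), lambda_), valid_klA)
    eta = np.full((S, K), 1.0 / K)
    anc = _sample_dirichlet_rows(rng, np.full((L, Amax), lambda_), valid)

    M = ind_idx.size
    q_mean = np.zeros_like(Q)
    p_mean = np.zeros_like(P)
    alpha_sum = 0.0
    ll_samples = np.empty(iters - burnin)
    z_trace = np.empty((iters - burnin, M), dtype=np.int8) if collect_z else None
    kept = 0

    log_alpha_sd = 0.05
    alpha_max = 10.0

    for sweep in range(iters):
        # (i) cluster origin of each allele copy
        prob = Q[ind_idx] * P[:, locus_idx, allele_idx].T         # (M, K)
        tot = prob.sum(axis=1, keepdims=True)
        tot[tot == 0.0] = 1.0
        if K == 1:
            z = np.zeros(M, dtype=np.int64)
        else:
            cum = np.cumsum(prob, axis=1)
            r = rng.random(M) * cum[:, -1]
            z = (cum < r[:, None]).sum(axis=1)

        # (ii) cluster allele frequencies
        cnt = np.zeros((K, L, Amax))
        np.add.at(cnt, (z, locus_idx, allele_idx), 1.0)
        if freq_model == "correlated":
            pooled = cnt.sum(axis=0)
            anc = _sample_dirichlet_rows(rng, lambda_ + pooled, valid)
            prior = anc * (1.0 - freq_f) / freq_f
            P = _sample_dirichlet_rows(rng, prior[None] + cnt, valid_klA)
        else:
            P = _sample_dirichlet_rows(rng, lambda_ + cnt, valid_klA)

        # (iii) individual memberships
        qc = np.zeros((N, K))
        np.add.at(qc, (ind_idx, z), 1.0)
        if locprior:
            for s in range(S):
                mask = pop_of == s
                eta[s] = rng.dirichlet(1.0 + qc[mask].sum(axis=0) / 2.0 + 1e-9)
            prior_q = alpha * locprior_r * K * eta[pop_of]
        else:
            prior_q = np.full((N, K), alpha)
        Q = rng.gamma(prior_q + qc)
        Q /= Q.sum(axis=1, keepdims=True)

        # (iv) Metropolis update of the shared admixture parameter
        if update_alpha and K > 1 and not locprior:
            prop = float(np.exp(np.log(alpha) + rng.normal(0.0, log_alpha_sd)))
            if 0.0 < prop < alpha_max:
                logq = np.log(np.maximum(Q, 1e-300)).sum()

                def dir_ll(a: float) -> float:
                    from scipy.special import gammaln

                    return N * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * logq

                if np.log(rng.random()) < dir_ll(prop) - dir_ll(alpha):
                    alpha = prop

        if sweep >= burnin:
            mix = (Q[ind_idx] * P[:, locus_idx, allele_idx].T).sum(axis=1)
            ll_samples[kept] = float(np.log(np.maximum(mix, 1e-300)).sum())
            q_mean += Q
            p_mean += P
            alpha_sum += alpha
            if collect_z:
                z_trace[kept] = z
            kept += 1

    q_mean /= kept
    p_mean /= kept
    lnPD = float(ll_samples.mean() - ll_samples.var(ddof=0) / 2.0)
    return AdmixtureRun(
        K=K,
        Q=q_mean,
        P=p_mean,
        alpha=alpha_sum / kept,
        lnPD=lnPD,
        seed=seed,
        burnin=burnin,
        iters=iters,
        locprior_used=locprior,
        individuals=list(matrix.individuals),
        z_trace=z_trace,
    )


# ---------------------------------------------------------------------------
# Delta-K model selection
# ---------------------------------------------------------------------------

@dataclass
class DeltaKTable:
    K: list[int]
    mean_lnPD: list[float]
    sd_lnPD: list[float]
    delta_K: dict[int, float]
    optimal_K: int | None


def evanno_delta_k(runs: Sequence[AdmixtureRun]) -> DeltaKTable:
    """Delta-K table over replicate runs at consecutive K values.

    ``L''(K) = |L(K+1) - 2 L(K) + L(K-1)|`` with L the replicate mean
    of lnPD; ``Delta K = L''(K) / sd(lnPD at K)``, defined for interior
    K with replicate sd > 0.  The full table is reported, not only the
    argmax: secondary peaks are themselves informative.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnPD)
    ks = sorted(by_k)
    if len(ks) < 3 or any(k2 - k1 != 1 for k1, k2 in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need >= 2 replicates at every K")
    means = [float(np.mean(by_k[k])) for k in ks]
    sds = [float(np.std(by_k[k], ddof=1)) for k in ks]
    delta: dict[int, float] = {}
    for i, k in enumerate(ks[1:-1], start=1):
        second = abs(means[i + 1] - 2 * means[i] + means[i - 1])
        if sds[i] == 0.0:
            warnings.warn(f"sd(lnPD) = 0 at K={k}; Delta K undefined", stacklevel=2)
            continue
        delta[k] = second / sds[i]
    optimal = max(delta, key=delta.get) if delta else None
    return DeltaKTable(ks, means, sds, delta, optimal)


def assign_clusters(Q: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Per-individual cluster index, or UNASSIGNED when no membership
    exceeds the threshold."""
    Q = np.asarray(Q, dtype=float)
    best = Q.argmax(axis=1)
    out = np.where(Q.max(axis=1) > threshold, best, UNASSIGNED)
    return out.astype(np.int64)


def align_replicates(runs: Sequence[AdmixtureRun]) -> list[AdmixtureRun]:
    """Resolve label switching across replicate runs at the same K.

    Columns of every run are permuted to best match the first run,
    maximizing the summed Pearson correlation of matched Q columns
    (optimal one-to-one matching).
    """
    if not runs:
        return []
    K = runs[0].K
    n = runs[0].Q.shape[0]
    for r in runs:
        if r.K != K or r.Q.shape[0] != n:
            raise ValueError("runs must share K and individuals")
    ref = runs[0].Q
    out = [runs[0]]
    for r in runs[1:]:
        if K == 1:
            out.append(r)
            continue
        corr = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                sa, sb = ref[:, a].std(), r.Q[:, b].std()
                if sa == 0.0 or sb == 0.0:
                    corr[a, b] = 0.0
                else:
                    corr[a, b] = float(np.corrcoef(ref[:, a], r.Q[:, b])[0, 1])
        rows, cols = linear_sum_assignment(-corr)
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        out.append(
            AdmixtureRun(
                K=r.K,
                Q=r.Q[:, perm],
                P=r.P[perm],
                alpha=r.alpha,
                lnPD=r.lnPD,
                seed=r.seed,
                burnin=r.burnin,
                iters=r.iters,
                locprior_used=r.locprior_used,
                individuals=r.individuals,
            )
        )
    return out
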