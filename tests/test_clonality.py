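"""Clone detection, clonal statistics and the sexuality randomization test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonepop.clonality import (
    assign_mlg,
    clonal_stats_from_sizes,
    clonal_statistics,
    collapse_mll,
    diversity_evenness_regression,
    mlg_distance,
    probability_of_identity,
    sexual_null_test,
)
from clonepop.examples import CLONE_GROUP_SIZES, worked_example_stats
from clonepop.genotype_io import GenotypeMatrix, LocusMeta
from clonepop.synthetic import SimConfig, simulate_dataset


def _matrix(rows, pops=None, motif=2):
    rows = np.asarray(rows)
    n, L = rows.shape[:2]
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        pops or ["P"] * n,
        [LocusMeta(f"L{j}", motif) for j in range(L)],
        rows,
    )


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def test_pid_closed_forms():
    res = probability_of_identity([np.array([0.5, 0.5])])
    assert res.per_locus["locus1"] == pytest.approx(0.375)
    assert res.combined == pytest.approx(0.375)
    mono = probability_of_identity([np.array([1.0])])
    assert mono.combined == pytest.approx(1.0)


def test_pid_matches_exhaustive_genotype_pair_enumeration():
    """P_ID equals the brute-force match probability of two HW genotypes."""
    p = np.array([0.25, 0.25, 0.25, 0.25])

    def geno_probs(freq):
        out = {}
        k = len(freq)
        for i in range(k):
            for j in range(i, k):
                pr = freq[i] ** 2 if i == j else 2 * freq[i] * freq[j]
                out[(i, j)] = pr
        return out

    gp = geno_probs(p)
    brute = sum(v**2 for v in gp.values())
    res = probability_of_identity([p, p])
    assert res.per_locus["locus1"] == pytest.approx(brute, abs=1e-12)
    assert res.combined == pytest.approx(brute**2, abs=1e-12)


@given(
    st.lists(
        st.lists(st.floats(0.05, 1.0), min_size=2, max_size=5), min_size=1, max_size=4
    )
)
@settings(max_examples=50, deadline=None)
def test_pid_decreases_as_loci_added(raw):
    freqs = [np.array(r) / np.sum(r) for r in raw]
    combined = [
        probability_of_identity(freqs[: k + 1]).combined for k in range(len(freqs))
    ]
    assert all(b <= a + 1e-12 for a, b in zip(combined, combined[1:]))
    assert combined[-1] <= min(
        probability_of_identity(freqs).per_locus.values()
    ) + 1e-12


# ---------------------------------------------------------------------------
# MLG assignment
# ---------------------------------------------------------------------------

def test_identical_genotypes_share_mlg_one_allele_splits():
    g = [[[100, 102], [150, 152], [200, 200], [130, 134], [98, 98], [170, 172]]]
    rows = np.array(g * 2 + g)
    rows[2, 0, 1] = 104  # one allele differs at one locus
    part = assign_mlg(_matrix(rows))
    gof = part.group_of()
    assert gof["i0"] == gof["i1"]
    assert gof["i2"] != gof["i0"]
    assert part.n_groups == 2


def test_mlg_recovers_simulator_truth(clonal_dataset):
    ds = clonal_dataset
    part = assign_mlg(ds.genotypes)
    assert part.n_groups == ds.n_founders
    gof = part.group_of()
    inds = ds.genotypes.individuals
    for i in np.flatnonzero(ds.is_clone):
        assert gof[inds[i]] == gof[inds[ds.parent[i]]]


def test_missing_policies():
    rows = np.array(
        [
            [[100, 102], [150, 152], [200, 202], [130, 134], [98, 98]],
            [[100, 102], [150, 152], [200, 202], [130, 134], [0, 0]],
        ]
    )
    obs = assign_mlg(_matrix(rows), missing_policy="observed", min_loci=4)
    assert obs.n_groups == 1  # 4 shared scored loci match
    strict = assign_mlg(_matrix(rows), missing_policy="strict")
    assert strict.n_groups == 2
    short = assign_mlg(_matrix(rows), missing_policy="observed", min_loci=5)
    assert short.n_groups == 2  # overlap too small to co-assign


def test_all_missing_individual_unassigned():
    rows = np.array([[[100, 100]], [[0, 0]]])
    with pytest.warns(UserWarning, match="unassigned"):
        part = assign_mlg(_matrix(rows))
    assert part.unassigned == ["i1"]
    assert part.n_groups == 1


# ---------------------------------------------------------------------------
# MLL collapsing under the stepwise mutation model
# ---------------------------------------------------------------------------

def test_mll_distance_and_threshold():
    base = [[100, 102], [150, 152], [200, 200]]
    one_step = [[100, 104], [150, 152], [200, 200]]     # 102 -> 104: 1 step
    far = [[100, 114], [150, 162], [200, 200]]          # 6 + 5 steps away
    rows = np.array([base, one_step, far])
    m = _matrix(rows)
    assert mlg_distance(rows[0], rows[1], [2, 2, 2]) == 1
    assert mlg_distance(rows[0], rows[2], [2, 2, 2]) == 11
    assert mlg_distance(rows[1], rows[2], [2, 2, 2]) == 10
    part = assign_mlg(m)
    mll = collapse_mll(part, m, threshold_steps=4)
    gof = mll.group_of()
    assert gof["i0"] == gof["i1"]
    assert gof["i2"] != gof["i0"]


def test_mll_distance_uses_best_allele_pairing():
    # (100, 104) vs (104, 108): identity pairing costs 4 bp + 4 bp = 4 steps,
    # cross pairing costs |100-108| + |104-104| = 8 bp = 4 steps; both 4 -> 2+2?
    a = np.array([[100, 104]])
    b = np.array([[102, 104]])
    # best pairing matches the shared 104 allele: one 2-bp step
    assert mlg_distance(a, b, [2]) == 1


def test_mll_single_linkage_chain():
    base = np.array([[100, 100], [150, 150], [200, 200]])
    b = base.copy(); b[0] = [100, 106]      # 3 steps from base
    c = base.copy(); c[0] = [106, 106]      # 3 steps from b, 6 from base
    m = _matrix(np.array([base, b, c]))
    assert mlg_distance(base, b, [2, 2, 2]) == 3
    assert mlg_distance(b, c, [2, 2, 2]) == 3
    assert mlg_distance(base, c, [2, 2, 2]) == 6
    mll = collapse_mll(assign_mlg(m), m, threshold_steps=4)
    assert mll.n_groups == 1


def test_mll_missing_locus_contributes_zero_and_rounding_warns():
    a = np.array([[100, 102], [0, 0]])
    b = np.array([[100, 102], [150, 158]])
    assert mlg_distance(a, b, [2, 2]) == 0
    with pytest.warns(UserWarning, match="motif multiple"):
        d = mlg_distance(
            np.array([[100, 103]]), np.array([[100, 100]]), [2]
        )
    assert d == 2  # 3 bp at a dinucleotide -> rounds to 2 steps


def test_mll_threshold_zero_equals_mlg_partition(structured_dataset):
    m = structured_dataset.genotypes
    part = assign_mlg(m)
    mll = collapse_mll(part, m, threshold_steps=0)
    assert sorted(map(sorted, mll.groups.values())) == sorted(
        map(sorted, part.groups.values())
    )


# ---------------------------------------------------------------------------
# randomization test of sexuality
# ---------------------------------------------------------------------------

def test_sexual_null_monoclonal_hits_lower_bound():
    geno = [[100, 102], [150, 152], [200, 204], [130, 136]]
    rows = np.array([geno] * 10)
    # give the pool allelic diversity: perturb none, but alleles within
    # loci are heterozygous, so permutation breaks up the shared MLG
    p = sexual_null_test(_matrix(rows), "P", n_rand=99, seed=1)
    assert p == pytest.approx(1 / 100)


def test_sexual_null_all_unique_is_insignificant():
    high = 0
    for seed in range(10):
        ds = simulate_dataset(
            SimConfig(n_demes=1, deme_sizes=20, alleles_per_locus=8, seed=seed)
        )
        p = sexual_null_test(ds.genotypes, "D1", n_rand=99, seed=seed)
        high += p > 0.5
    assert high >= 9


def test_sexual_null_degenerate_and_errors():
    rows = np.array([[[100, 100]]] * 5)  # monomorphic
    p = sexual_null_test(_matrix(rows), "P", n_rand=99, seed=0)
    assert p == 1.0
    one = _matrix(np.array([[[100, 102]]]))
    with pytest.raises(ValueError, match="fewer than 2"):
        sexual_null_test(one, "P", n_rand=99, seed=0)
    with pytest.raises(ValueError, match="n_rand"):
        sexual_null_test(_matrix(rows), "P", n_rand=10, seed=0)


# ---------------------------------------------------------------------------
# clonal statistics
# ---------------------------------------------------------------------------

def test_all_singletons_population():
    s = clonal_stats_from_sizes([1] * 14, population="KNA")
    assert s.Go == pytest.approx(14.0)
    assert s.G == pytest.approx(1.0)
    assert s.R == pytest.approx(1.0)
    assert s.simpson_1mD == pytest.approx(1.0)
    assert s.mode_label == "fully_sexual"


def test_mixed_partition_formula_oracle():
    # 7 singletons + 3 doubles: Go = N^2 / sum(n_i^2) = 169/19
    s = clonal_stats_from_sizes([1] * 7 + [2] * 3)
    assert s.Go == pytest.approx(169 / 19, abs=1e-12)
    assert s.R == pytest.approx(9 / 12)
    assert s.simpson_1mD == pytest.approx((13 / 12) * (1 - 19 / 169), abs=1e-12)
    assert s.mode_label == "predominantly_sexual"


def test_shannon_log10_and_bias_flag():
    s = clonal_stats_from_sizes([1] * 19)
    assert s.shannon_H == pytest.approx(np.log10(19), abs=1e-12)
    plain = clonal_stats_from_sizes([1] * 7 + [2] * 3)
    corr = clonal_stats_from_sizes([1] * 7 + [2] * 3, shannon_bias_correction=True)
    assert corr.shannon_H > plain.shannon_H


def test_clonal_statistics_end_to_end(clonal_dataset):
    ds = clonal_dataset
    part = assign_mlg(ds.genotypes)
    s = clonal_statistics(ds.genotypes, part, "D1")
    truth_founders = int((~ds.is_clone[:30]).sum())
    assert s.N == 30
    assert s.N_MLG == truth_founders
    assert s.R == pytest.approx((truth_founders - 1) / 29)


@given(st.lists(st.integers(1, 6), min_size=2, max_size=15))
@settings(max_examples=100, deadline=None)
def test_clonal_stats_invariants(sizes):
    s = clonal_stats_from_sizes(sizes)
    assert 1.0 - 1e-9 <= s.Go <= s.N + 1e-9
    singletons = all(x == 1 for x in sizes)
    assert (abs(s.Go - s.N) < 1e-9) == singletons
    assert (abs(s.simpson_1mD - 1.0) < 1e-9) == singletons
    assert (abs(s.G - 1.0) < 1e-9) == singletons
    assert 0.0 <= s.R <= 1.0
    assert 0.0 < s.E_D <= 1.0 + 1e-9


def test_stats_errors():
    with pytest.raises(ValueError, match="at least 2"):
        clonal_stats_from_sizes([1])


# ---------------------------------------------------------------------------
# diversity-evenness regression
# ---------------------------------------------------------------------------

def test_regression_collinear_points():
    stats = [
        clonal_stats_from_sizes(sz)
        for sz in ([1] * 5, [1] * 3 + [2], [1, 2, 2], [2, 2, 2])
    ]
    # G and E_D are deterministic transforms; force exact collinearity instead
    import dataclasses

    pts = [(0.2, 0.4), (0.5, 0.7), (0.9, 1.1)]
    fake = [
        dataclasses.replace(stats[0], E_D=x, G=y) for x, y in pts
    ]
    res = diversity_evenness_regression(fake)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(1.0)


def test_regression_worked_example():
    """Across the nine example populations, diversity tracks evenness."""
    stats = list(worked_example_stats().values())
    res = diversity_evenness_regression(stats)
    assert res.r_squared == pytest.approx(0.8993, abs=0.005)
    assert res.p_value < 0.001


def test_regression_permuted_x_mean_r2():
    """Under shuffling, E[R^2] = 1/(n-1) for a single regressor."""
    stats = list(worked_example_stats().values())
    x = np.array([s.E_D for s in stats])
    y = np.array([s.G for s in stats])
    rng = np.random.default_rng(0)
    import dataclasses

    r2s = []
    for _ in range(400):
        xs = rng.permutation(x)
        if np.allclose(xs * (y - y.mean()), 0):
            continue
        fake = [
            dataclasses.replace(stats[0], E_D=xv, G=yv) for xv, yv in zip(xs, y)
        ]
        r2s.append(diversity_evenness_regression(fake).r_squared)
    assert np.mean(r2s) == pytest.approx(1 / (len(stats) - 1), abs=0.04)


def test_regression_errors():
    stats = list(worked_example_stats().values())
    with pytest.raises(ValueError, match="3 populations"):
        diversity_evenness_regression(stats[:2])
    import dataclasses

    flat = [dataclasses.replace(s, E_D=0.5) for s in stats]
    with pytest.raises(ValueError, match="zero variance"):
        diversity_evenness_regression(flat)
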