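"""Per-population statistics: heterozygosity, FIS, HWE exact test, nulls."""

import itertools
from collections import Counter

import numpy as np
import pytest

from clonepop.genotype_io import GenotypeMatrix, LocusMeta
from clonepop.popstats import (
    allele_frequencies,
    allelic_richness_and_private,
    fis,
    heterozygosity,
    hwe_exact,
    hwe_fdr,
    null_allele_screen,
)
from clonepop.synthetic import SimConfig, simulate_dataset


def _matrix(rows, pops=None):
    rows = np.asarray(rows)
    n, L = rows.shape[:2]
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        pops or ["P"] * n,
        [LocusMeta(f"L{j}", 2) for j in range(L)],
        rows,
    )


def test_allele_frequencies_basic():
    m = _matrix([[[100, 100]]] * 5)
    assert allele_frequencies(m, "P") == {"L0": {100: 1.0}}
    m2 = _matrix([[[100, 100]], [[100, 102]]])
    assert allele_frequencies(m2, "P")["L0"] == {100: 0.75, 102: 0.25}


def test_allele_frequencies_excludes_unscored_locus():
    m = _matrix([[[0, 0], [100, 102]], [[0, 0], [100, 100]]])
    with pytest.warns(UserWarning, match="no scored calls"):
        f = allele_frequencies(m, "P")
    assert "L0" not in f and "L1" in f


def test_frequencies_converge_to_simulated_truth():
    cfg = SimConfig(n_demes=1, deme_sizes=500, n_loci=3, alleles_per_locus=4, seed=8)
    ds = simulate_dataset(cfg)
    f = allele_frequencies(ds.genotypes, "D1")
    for l in range(3):
        truth = ds.deme_frequencies[0, l]
        sizes = ds.allele_sizes[l]
        est = np.array([f[f"L{l+1}"].get(int(s), 0.0) for s in sizes])
        assert np.abs(est - truth).max() < 0.05


def test_private_alleles():
    a = [[[100, 100]]] * 3
    b = [[[102, 102]]] * 3
    m = _matrix(a + b, pops=["A"] * 3 + ["B"] * 3)
    res = allelic_richness_and_private(m)
    assert res["A"]["Np_mean"] == 1.0 and res["B"]["Np_mean"] == 1.0
    assert res["A"]["Na_mean"] == 1.0  # monomorphic within A
    same = _matrix(a + a, pops=["A"] * 3 + ["B"] * 3)
    res2 = allelic_richness_and_private(same)
    assert res2["A"]["Np_mean"] == 0.0 and res2["B"]["Np_mean"] == 0.0


def test_private_alleles_single_population_error():
    with pytest.raises(ValueError, match="2 populations"):
        allelic_richness_and_private(_matrix([[[100, 102]]] * 3))


def test_heterozygosity_extremes():
    all_het = _matrix([[[100, 102]]] * 6)
    h = heterozygosity(all_het, "P")
    assert h["Ho"] == 1.0 and h["He_biased"] == pytest.approx(0.5)
    all_hom = _matrix([[[100, 100]]] * 6)
    h0 = heterozygosity(all_hom, "P")
    assert h0["Ho"] == 0.0 and h0["He_biased"] == 0.0


def test_heterozygosity_unbiased_geq_biased():
    for seed in range(5):
        ds = simulate_dataset(SimConfig(n_demes=1, deme_sizes=15, seed=seed))
        h = heterozygosity(ds.genotypes, "D1")
        assert 0.0 <= h["He_biased"] <= h["He_unbiased"] <= 1.0


def test_ho_tracks_he_under_hardy_weinberg():
    ds = simulate_dataset(SimConfig(n_demes=1, deme_sizes=400, seed=31))
    h = heterozygosity(ds.genotypes, "D1")
    assert abs(h["Ho"] - h["He_unbiased"]) < 0.04


# ---------------------------------------------------------------------------
# FIS
# ---------------------------------------------------------------------------

def test_fis_all_heterozygote_limit():
    m = _matrix([[[100, 102]]] * 200)
    res = fis(m, "P", n_boot=0)
    assert res.f == pytest.approx(-1.0, abs=0.02)


def test_fis_matches_brute_force_components():
    """Independent scalar recomputation of the W&C within-population f."""
    rows = [
        [[100, 102], [150, 150]],
        [[100, 100], [150, 152]],
        [[102, 102], [152, 152]],
        [[100, 102], [150, 152]],
        [[102, 104], [150, 150]],
    ]
    m = _matrix(rows)
    res = fis(m, "P", n_boot=0)

    num = den = 0.0
    for l in range(2):
        genos = [tuple(r[l]) for r in rows]
        n = len(genos)
        alleles = [a for g in genos for a in g]
        for a in sorted(set(alleles)):
            p = alleles.count(a) / (2 * n)
            h = sum(1 for g in genos if (g[0] == a) != (g[1] == a)) / n
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c = h / 2
            num += c
            den += b + c
    assert res.f == pytest.approx(1 - num / den, abs=1e-12)


def test_fis_near_zero_under_hw_with_ci():
    ds = simulate_dataset(SimConfig(n_demes=1, deme_sizes=150, seed=77))
    res = fis(ds.genotypes, "D1", n_boot=300, seed=1)
    assert abs(res.f) < 0.08
    assert res.ci_low <= 0.0 <= res.ci_high


def test_fis_monomorphic_undefined():
    m = _matrix([[[100, 100]]] * 5)
    with pytest.warns(UserWarning, match="monomorphic"):
        res = fis(m, "P", n_boot=0)
    assert np.isnan(res.f)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _pairing_oracle(genotypes):
    """Exact Levene p-values by enumerating all pairings of allele copies."""
    pool = [a for g in genotypes for a in g]
    n = len(genotypes)

    def all_pairings(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k in range(len(rest)):
            pair = (first, rest[k]) if first <= rest[k] else (rest[k], first)
            for tail in all_pairings(rest[:k] + rest[k + 1:]):
                yield [pair] + tail

    arrays = Counter()
    for pairing in all_pairings(pool):
        arrays[tuple(sorted(pairing))] += 1
    total = sum(arrays.values())
    obs = tuple(sorted(tuple(sorted(g)) for g in genotypes))
    p_obs = arrays[obs] / total
    het_obs = sum(1 for a, b in obs if a != b)
    p_two = sum(c for arr, c in arrays.items() if c / total <= p_obs + 1e-12) / total
    p_def = (
        sum(c for arr, c in arrays.items()
            if sum(1 for a, b in arr if a != b) <= het_obs) / total
    )
    return p_two, p_def


@pytest.mark.parametrize(
    "genotypes",
    [
        [(1, 1), (1, 2), (2, 2), (1, 2)],
        [(1, 2), (1, 2), (1, 2)],
        [(1, 1), (2, 2), (3, 3), (1, 2)],
        [(1, 2), (2, 3), (1, 3), (1, 1)],
    ],
)
def test_hwe_enumeration_matches_pairing_oracle(genotypes):
    rows = np.array([[[10 + a, 10 + b]] for a, b in genotypes])
    m = _matrix(rows)
    res = hwe_exact(m, "P", "L0", mode="enumerate")
    p_two, p_def = _pairing_oracle(genotypes)
    assert res.p_two_sided == pytest.approx(p_two, abs=1e-9)
    assert res.p_het_deficit == pytest.approx(p_def, abs=1e-9)


def test_hwe_forced_table_p_one():
    # n=2, allele counts (2, 2): with counts 2A/2B the possible arrays are
    # {AB, AB} and {AA, BB}; observed more probable or tied -> p covers all
    rows = np.array([[[10, 11]], [[10, 11]]])
    res = hwe_exact(_matrix(rows), "P", "L0", mode="enumerate")
    assert res.p_two_sided <= 1.0
    mono = _matrix(np.array([[[10, 10]]] * 4))
    with pytest.warns(UserWarning, match="monomorphic"):
        res2 = hwe_exact(mono, "P", "L0")
    assert res2.p_two_sided == 1.0


def test_hwe_mc_agrees_with_enumeration():
    rng = np.random.default_rng(4)
    alleles = rng.integers(0, 2, size=(8, 2)) + 10
    rows = alleles[:, None, :]
    m = _matrix(np.sort(rows, axis=2))
    enum = hwe_exact(m, "P", "L0", mode="enumerate")
    mc = hwe_exact(m, "P", "L0", mode="mc", n_mc=20000, seed=0)
    assert mc.p_two_sided == pytest.approx(enum.p_two_sided, abs=0.02)
    assert mc.p_het_deficit == pytest.approx(enum.p_het_deficit, abs=0.02)


def test_hwe_p_roughly_uniform_under_null():
    """Under HW sampling the exact-test p-values are not anti-conservative."""
    ps = []
    for seed in range(40):
        ds = simulate_dataset(
            SimConfig(n_demes=1, deme_sizes=40, n_loci=1, alleles_per_locus=3,
                      seed=2000 + seed)
        )
        ps.append(
            hwe_exact(ds.genotypes, "D1", "L1", mode="mc", n_mc=500, seed=seed
                      ).p_two_sided
        )
    assert np.mean(np.asarray(ps) <= 0.05) <= 0.125
    assert np.mean(ps) > 0.3


def test_hwe_fdr_monotone():
    adj = hwe_fdr([0.01, 0.04, 0.5])
    assert (np.diff(adj) >= 0).all() and adj[0] >= 0.01


# ---------------------------------------------------------------------------
# null allele screen
# ---------------------------------------------------------------------------

def test_null_screen_r_zero_when_ho_equals_he():
    # Ho = 0.5, He = 0.5: two alleles at 50/50 with half heterozygotes
    rows = np.array(
        [[[10, 11]], [[10, 11]], [[10, 10]], [[11, 11]]]
    )
    res = null_allele_screen(_matrix(rows), "P", "L0", n_mc=500, seed=0)
    assert res.null_freq_estimate == pytest.approx(0.0, abs=1e-12)


def test_null_screen_flags_simulated_null_locus():
    ds = simulate_dataset(
        SimConfig(n_demes=1, deme_sizes=100, null_allele_freq=0.25,
                  null_allele_locus=0, seed=55)
    )
    res = null_allele_screen(ds.genotypes, "D1", "L1", n_mc=2000, seed=0)
    assert res.flagged
    assert res.null_freq_estimate > 0.05
    clean = null_allele_screen(ds.genotypes, "D1", "L4", n_mc=2000, seed=0)
    assert not clean.flagged
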