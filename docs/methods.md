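# Methods

This note documents the statistical models implemented in `clonepop`,
the defaults and why they were chosen, what the simulator does and
does not emulate, and the package's known limitations.

## Clone detection

Two individuals share a multilocus genotype (MLG) when their allele
pairs agree at every locus scored in both.  With missing data this
relation is not transitive, so under the default `observed` policy
matches are closed by single linkage and require at least `min_loci`
(default 4 of 6) jointly scored loci; the `strict` policy only
co-assigns individuals with complete data.  Individuals unscored at
every locus are reported unassigned rather than silently dropped.

Multilocus lineages (MLLs) absorb somatic mutation and scoring slips:
the distance between two MLGs is the summed number of single-motif
steps, per locus taking the cheaper of the two ways of pairing the
alleles, with loci missing in either genotype contributing zero.  MLGs
within `threshold_steps` (default 4) are merged by single linkage.  A
size difference that is not a motif multiple is rounded to the nearest
step with a warning — such calls indicate off-ladder alleles or size
homoplasy and deserve manual review.

## Clonality statistics

With clone group sizes *n_i* in a population of *N* individuals and
*g_i* = *n_i*/*N*:

- richness R = (N_MLG − 1)/(N − 1);
- Stoddart–Taylor diversity Go = 1/Σ g_i²; its expectation under full
  sexuality is Ge = N (every individual its own genet), so
  G = Go/N ∈ (0, 1];
- evenness E_D = Go/N_MLG;
- unbiased Simpson 1 − D = (N/(N−1))(1 − Σ g_i²), which equals 1
  exactly when all groups are singletons;
- Shannon–Wiener H′ = −Σ g_i log₁₀ g_i.  Base 10 is deliberate: it is
  what the established clonality software reports, and for an
  all-singleton population gives H′ = log₁₀ N.  An optional
  first-order small-sample correction (+(S−1)/(2N ln 10), Miller–
  Maddow) is available but off by default.

Reproductive-mode labels follow G: `fully_sexual` at G = 1,
`predominantly_sexual` for 0.65 ≤ G < 1, `mostly_sexual` for
0.5 ≤ G < 0.65, else `mixed_clonal`.  The thresholds are descriptive
conventions, not tests.

The randomization test of sexuality permutes allele copies among
individuals independently within each locus (missing slots fixed) and
recounts distinct genotypes; p = (1 + #{N*_MLG ≤ N_MLG}) / (B + 1)
with the add-one convention so p is never zero.  Genotype identity in
this test is exact row equality for both the observed and permuted
data, keeping the statistic comparable across replicates.

The probability of identity per locus is Σ p⁴ + Σ_{i<j} (2 p_i p_j)²
and multiplies across loci under independence; it bounds the chance
that two distinct sexual genets share an MLG.

## Per-population statistics

Expected heterozygosity is reported both as the plug-in 1 − Σp² and
with Nei's 2n/(2n − 1) small-sample factor.  F_IS is the
Weir–Cockerham within-population f from variance components summed
over alleles and loci (not the naive 1 − Ho/He, which differs
noticeably at field sample sizes); its 95% CI is a percentile
bootstrap over loci, which is honest only with a reasonable number of
loci — with six loci the CI is wide by construction.  Monomorphic
populations have undefined f and return NaN with a warning.

The Hardy–Weinberg exact test uses Levene's distribution of genotype
arrays conditional on allele counts.  Small tables (n ≤ 12 and ≤ 4
alleles by default) are fully enumerated; larger ones use Monte-Carlo
permutation of allele copies with add-one p-values.  The two-sided
test sums probabilities of arrays no more probable than the observed
one; the heterozygote-deficit test uses the heterozygote count as a
one-sided statistic.  Benjamini–Hochberg adjustment is provided for
families of tests; raw p-values are always reported too.

The null-allele screen flags a locus when the one-sided deficit test
is significant (default α = 0.05) and estimates the null frequency as
r = (He − Ho)/(He + Ho).  It is a deliberately simple homozygote-
excess screen: it cannot distinguish null alleles from inbreeding,
Wahlund structure or stutter scoring, all of which also depress Ho.

## Differentiation

θ is the Weir–Cockerham (1984) estimator: per locus and allele the
among-population (a), among-individual (b) and within-individual (c)
components are computed from sample sizes, allele frequencies and
observed heterozygote frequencies, and θ = Σa / Σ(a+b+c) over all
alleles and loci.  Loci monomorphic across the compared populations
contribute nothing; missing calls are excluded per locus
(pairwise-complete).  Negative estimates are reported as computed —
truncation at zero is left to downstream consumers (the IBD module
flags them at linearization).  Permutation p-values shuffle
individuals between the two populations keeping sample sizes, with
add-one correction.  Clone truncation (`to_per_genotype`) keeps the
first-sampled member of each clonal group per population; clones
otherwise shrink within-population variance and inflate θ.

## Admixture clustering

The model is the standard admixture mixture: each allele copy of
individual *i* originates from cluster *k* with probability Q[i,k]
and then shows allele *a* at locus *l* with probability P[k,l,a].
One Gibbs sweep samples all copy origins Z given (Q, P), then
P | Z ~ Dirichlet(λ + counts) per cluster and locus, then
Q[i] | Z ~ Dirichlet(α + copy counts), then updates the single shared
α by a Metropolis random walk on log α (proposal sd 0.05, uniform
prior on (0, 10)).  Missing calls are simply skipped.  The estimated
log probability of the data is the standard harmonic adjustment
lnPD = mean(ℓ) − var(ℓ)/2 over post-burn-in log-likelihood samples.
The sampler was validated against the exact collapsed posterior on an
enumerable two-individual toy (co-assignment probabilities within
Monte-Carlo error) and against the closed-form Dirichlet-multinomial
marginal at K = 1.

Cluster frequencies are independent across clusters by default.  A
`correlated` option ties them to a Gibbs-updated ancestral profile
with a fixed drift parameter (`freq_f`); it is a simplification of
the full F-model (which samples per-cluster drift) and is off by
default — ΔK-based selection of K on well-separated data is
insensitive to this choice.  The `locprior` option shares a
Dirichlet prior mean on Q among individuals of the same sampling
location with fixed strength `locprior_r`; it is likewise a
documented simplification of the full location-prior parameterization.

Desk-scale defaults are burn-in 2 000 and 10 000 total sweeps with 3
replicates per K; longer published schedules (10⁵ burn-in, 10⁶
sweeps, 5 replicates, K up to 10) remain configurable.

ΔK follows Evanno: L″(K) = |L(K+1) − 2L(K) + L(K−1)| over replicate
means, divided by the replicate standard deviation of lnPD at K.  The
full table is reported, not only the argmax, because ΔK is known to
favour the uppermost level of hierarchical structure: on simulated
three-deme data where chance placed one deme pair much closer than
the others, ΔK legitimately peaks at K = 2.  Replicate sd estimated
from 3 runs is itself noisy; treat single-peak margins < ~2x with
caution and inspect lnPD directly.

Label switching across replicates is resolved by permuting columns to
maximize the summed Pearson correlation of matched Q columns via
optimal one-to-one assignment.  Cluster membership calls use the
argmax with a 0.75 threshold by default; individuals below it are
UNASSIGNED.

## Multivariate companions

Allele counts per individual (0/1/2 per allele column) feed a
centered, unscaled PCA; missing genotypes are mean-imputed per column
and flagged.  DAPC reduces to the axes explaining ≥ 90% variance by
default (the count table is always rank-deficient since each locus
block sums to two) and then fits Fisher discriminants; the in-sample
reassignment proportion is reported and a cross-validation recipe is
shown in the tests.  Nei's distance aggregates J_xy, J_x, J_y
arithmetically over loci before I = J_xy/√(J_x J_y), D = −ln I, with
a 1978 unbiased variant; populations sharing no alleles get a capped
distance (50) with a warning.  The minimum spanning network is
Kruskal processed by weight class: all edges that join still-separate
components at the start of a tied class are retained, so co-minimal
alternatives appear and the result is a network rather than a strict
tree; with distinct weights it is exactly the MST.

## Isolation by distance

θ is linearized as θ/(1 − θ) and regressed on pairwise geographic
distance in km.  Over-water distances should be supplied as a labeled
matrix — great-circle (haversine, R = 6371 km) distance is only a
fallback since coastal taxa disperse around, not across, landmasses.
Significance is reported two ways (their distinction is often left
implicit in the literature): the OLS F-test of the slope and a Mantel
test permuting rows/columns of one matrix simultaneously (999
permutations by default, add-one, one-sided for positive
association).

## The simulator

`simulate_dataset` draws ancestral allele frequencies from a
symmetric Dirichlet (concentration 1.0 by default) on a shared
fragment-size ladder (base 100 bp, one motif step apart), then deme
frequencies from Dirichlet(p̄(1 − F)/F), which has expected
Weir–Cockerham FST equal to `target_F` — the analytic handle the
validation studies rely on.  `stepping_stone` mode instead drifts
demes serially along a line with a per-step F solved so the mean
deme-to-ancestor divergence matches the target, giving monotone
isolation by distance.  Within a deme, ⌈(1 − c)n⌉ founders are
Hardy–Weinberg draws; the remaining individuals copy a uniformly
chosen founder (clones are a star around their genet, never copies of
copies) and optionally mutate by ±1 motif step per locus with
probability `somatic_step_prob`.  Null alleles at a designated locus
make carrier heterozygotes look homozygous and null homozygotes
missing; independent missingness is applied last.  The truth layer
(founder/copy flags, parent ids, sampling frequencies) is recorded
before corruption.

Defaults (3 demes x 30 diploids, 6 loci, 8 alleles per locus,
F = 0.1) mirror a mid-size microsatellite survey of a brooding coral:
tens of colonies per site and a handful of moderately polymorphic
loci.  What the simulator does *not* emulate: linkage, selection,
coalescent pedigree structure, genotyping artifacts beyond simple
null alleles (stutter, large-allele dropout, >2-peak triploid or
chimeric samples), or uneven spatial sampling.  Passing recovery
tests therefore shows the estimators are correct under the stated
models, not that real data meet those models.

## Validation problem sizes

The recovery studies run at sizes chosen to give tight Monte-Carlo
error on a single CPU: island FST recovery uses 8 demes x 20
diploids x 10 loci over 100-200 replicate datasets per target; the
ΔK study uses the fixed three-deme fixture (90 individuals, 8 loci)
with K ∈ [1,5], 3 replicate chains of 5 000 sweeps (1 000 burn-in) and
five independent MCMC seed sets; clonality recovery uses single demes
of 100 at c ∈ {0, 0.25, 0.5, 0.75}; both permutation tests are
calibrated over 200 simulated null datasets.

## Known limitations

- The worked example bundles the published clone partition (group
  sizes) of the nine-population survey, not the raw genotypes, which
  are not redistributed here; quantities that need the raw calls
  (pairwise FST between the real populations, the real combined
  P_ID, the real K) are out of scope and validated on simulations
  instead.
- The MLG observed-overlap rule is single-linkage and can chain
  through intermediates when missingness is extreme.
- The exact estimator behind published F_IS tables can rarely be
  confirmed without raw data; this package standardizes on
  Weir-Cockerham f and says so.
- `locprior` and the correlated-frequency model are simplified
  variants (fixed hyperparameters) of their full parameterizations.
- ΔK cannot, by construction, support K = 1; inspect mean lnPD when
  no structure is plausible.
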