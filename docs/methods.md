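# Methods

This note documents the statistical model, the simulator, the outlier
screen, and the numerical and design choices behind `ldpopsize`.

## The LD-Ne model

**Estimand.** The contemporary effective population size Ne of a closed,
random-mating diploid population, from the weak correlation that genetic
drift induces between alleles at unlinked neutral loci.

**Composite disequilibrium.** Gametic phase is unknown in diploid genotype
data, so association between allele j at locus A and allele k at locus B is
measured by the Burrows composite statistic. Writing x and y for the
per-individual copy numbers (0/1/2) of j and k among the n_AB individuals
typed at both loci, the composite pairing count per individual is
P̃ = Σ x·y / (2 n_AB) ∈ [0, 2] and

    Δ̂_jk = (n_AB / (n_AB − 1)) · (P̃ − 2 p̂_j p̂_k),

with allele frequencies p̂ computed on the jointly typed subset so each
pairwise statistic is internally consistent under missing data. The
n/(n−1) factor is the classical small-sample correction of the composite
estimator; with it, the sampling expectation quoted below holds to within
Monte-Carlo error (verified by simulation at S = 100), while without it
estimates at small S are biased upward by ≈ (n/(n−1))². Setting
`small_sample=False` gives the raw moment estimator, for which r̂ below is
*exactly* the Pearson correlation of dosages — an identity the test suite
uses as an independent oracle.

The squared correlation uses Hardy–Weinberg-deviation-corrected variances
(D̂ = observed homozygote frequency − p̂²):

    r̂²_jk = Δ̂²_jk / ([p̂_j(1−p̂_j)+D̂_A][p̂_k(1−p̂_k)+D̂_B]).

Allele columns with zero dosage variance (monomorphic, or everyone
heterozygous for the allele) have a zero denominator; such pairs are
flagged undefined, excluded, and counted.

**Pcrit filtering and weighting.** Rare alleles make r̂² noisy and biased,
so allele pairs enter the mean only if both frequencies are ≥ Pcrit (a
frequency exactly equal to the threshold is retained; Pcrit = 0 keeps every
observed allele). Each retained r̂² is weighted by n_AB. The effective
sample size S_eff is the harmonic mean of n_AB over contributing locus
pairs, and the sampling bias E(r̂²) = 1/S_eff + 3.19/S_eff² is subtracted
to leave the drift component r̂²′.

**Inversion.** r̂²′ is equated to the drift expectation
1/(3Ne) − 0.69/Ne² and solved:

    N̂e = [1/3 + √(1/9 − 2.76 r̂²′)] / (2 r̂²′).

The minus sign under the radical is the form that exactly inverts the drift
expectation (round-trip verified to 1e−9 relative error over
Ne ∈ [50, 10⁶]); the sign conventions in the surrounding literature are not
uniform. If r̂²′ > 1/24.84 ≈ 0.0403 (outside the estimator's sensible
range) the radicand is negative and the first-order estimate 1/(3 r̂²′) is
returned with a warning flag. r̂²′ = 0 maps to an infinite (undefined)
estimate, and a negative r̂²′ to a negative N̂e — reported as-is, meaning
"Ne too large to resolve with this sample".

**Uncertainty.** A delete-one-locus-pair jackknife on the weighted mean r̂²
gives a standard error; a normal-approximation interval on r̂²′ is mapped
through the (monotone decreasing) inversion, so the lower Ne bound comes
from the upper r̂²′ bound and a non-positive bound maps to infinity. This
is the package's own construction — the original software lineage documents
only "a jackknife method" — and a chi-square variant could be added without
touching the rest. At least 3 locus pairs are required.

**Aggregation.** Harmonic means across replicates/iterations are taken over
positive finite estimates only; the number excluded is reported alongside
so either convention (signed reciprocals vs. exclusion) can be
reconstructed.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `pcrit` | 0.01 | minimum sample allele frequency (unitless); 0.01–0.001 minimises replicate SD in the simulated designs |
| `small_sample` | True | n/(n−1) factor on Δ̂ (see above) |
| `divisor` | "individuals" | composite-count normalisation; "gametes" (divide by 2n) is a compatibility reading under which Δ̂ does not vanish for independent loci and which is not used by the estimator |
| `threshold` (CA) | 2.0 | \|PC1\|+\|PC2\| cutoff on row principal coordinates |
| `max_iter` (CA) | 10 | cap on cleaning rounds |
| `terminal_ib` | 8 | individual-based generations at the end of a hybrid run (≥ 4 needed for the r̂² asymptote; 8 adds margin) |

## The Wright–Fisher simulator

Discrete non-overlapping generations at constant even N; the first N/2
individuals of a generation are female, the rest male (positional, not
random); each offspring draws a mother and father independently with
replacement and one uniformly chosen allele per locus from each parent;
loci are unlinked; no mutation or selection. Under this mating scheme
Ne ≈ N, so simulations with known N are parameter-recovery experiments for
the estimator (replicate medians within 15% of N at N = 100 and 1000 are
part of the test suite).

**Founders** are drawn allele-by-allele from a frequency table (linkage and
Hardy–Weinberg equilibrium in expectation, r̂² ≈ sampling floor), so LD
must re-accumulate by drift; sampling at generation ≥ 4 is enough for r̂²
to approach its asymptote (the approach rate for unlinked loci is a factor
~4 per generation).

**Hybrid fast path.** Divergence horizons of hundreds to thousands of
generations only need the allele *frequencies* to drift; genotypic LD
depends on the recent pedigree. `drift_frequencies` resamples 2N allele
copies per locus multinomially per generation; `evolve_population` chains
g − 8 generations of that with a founding draw plus 7 individual-based
generations. A Kolmogorov–Smirnov test in the suite checks the replicate
distribution of mean r̂² is indistinguishable from a fully individual-based
run. A 2000-generation, N = 10,000 evolution takes well under a second.

**Sampling** is simple random without replacement ("plan 2": sampled
individuals stay in the breeding pool — an interpretation issue, not a
mechanical one). Where a design asks for more genotypes than the
population holds (e.g. samples of 5413 from N = 3000), the sample is capped
at N; sampling the whole population is the only phase-honest reading.

**Immigrant mixtures** replace m uniformly chosen focal sample members with
m uniformly chosen donors (both without replacement) and record the planted
positions as ground truth for detection scoring.

**Nontarget-species surrogate.** Contamination experiments found an
independent population from an independently synthesized spectrum, offset
its allele codes so they are private to the contaminants (real congener
panels share primers, not allele pools), and blank two loci entirely
(the nontarget species amplifies at five of the seven loci). This is a
synthetic stand-in constructed for the design, not real congener data.

## Synthetic allele-frequency spectra and missingness

`mackerel_spectrum()` encodes the seven-locus empirical panel marginals: per
locus the allele count (24–38), the maximum allele frequency (0.127–0.735)
and the fraction of alleles at frequency ≤ 0.01 (overall ≈ 65%).
`synthesize_spectrum` pins the head allele at the target maximum and builds
the tail from two geometric series — "common" alleles spaced between 0.01
and the head, "rare" alleles decaying from just below 0.01 — jittered by a
single Dirichlet draw (concentration 2000, chosen to give visible
between-replicate variation without violating the marginals) and
reject-resampled until the realised maximum stays at the head and the
low-frequency fraction is within ±10 percentage points of target.
Infeasible targets (max < 1/Na) are rejected before sampling. Output is
bit-reproducible for a fixed seed.

`mackerel_missingness()` reproduces the empirical missing-data structure.
Independent per-locus Bernoulli rates taken from the per-locus sample sizes
cannot be the right model: they would leave only ~57% of individuals fully
typed, whereas the data show 71%/12%/10%/7% typed at 7/6/5/4 loci. Both
marginals are jointly consistent (the per-locus missing rates sum to
≈ 0.53, the expected number of missing locus-slots per individual), so the
default is a deterministic donor-mask table realising the typed-count
distribution exactly, with which loci go missing chosen
largest-remainder-proportionally to the per-locus rates. Masks are
resampled with replacement per simulated individual, which also preserves
any within-individual correlation structure the table encodes. A pure
probability mode remains available.

## The CA outlier screen

Individuals are rows of a dosage table with one column per (locus, allele)
observed in the *current* dataset (columns are rebuilt after every removal
round); missing loci contribute zero dosage, and CA's row-mass
normalisation absorbs the resulting row-sum differences. Correspondence
analysis — divide by the grand total, centre by the outer product of row
and column masses, scale by inverse square-root masses, SVD — embeds
individuals under the chi-square metric, which up-weights rare columns:
precisely the private or near-private alleles that genotypes from another
species or a diverged population carry. Row *principal* coordinates
(U·σ/√row-mass) are used: per-axis inertia of a many-allele dosage table is
small, so the bulk of a homogeneous sample sits well inside ±1 and a fixed
threshold of 2 on |PC1| + |PC2| flags only genuine outliers (on clean
simulated samples of 5413 it removes a fraction of a percent). Axis signs
are normalised (largest-magnitude column loading positive); a rank-deficient
second axis is reported as zeros with a flag. Removal is permanent across
iterations; the loop stops at the first empty flag set or after `max_iter`
rounds, and errors out rather than removing everyone.

The L1 combination of axes (and the threshold itself) is configurable; the
printed rule this reproduces is sign-convention-dependent as stated, and a
distance from the origin is the only reading consistent with "furthest from
the central cluster".

## Weir–Cockerham FST

Two-population θ (1984) with variance components a, b, c computed per
allele from sample sizes, allele frequencies and heterozygote-carrier
frequencies on the per-locus typed subsets, summed over alleles and loci
before the ratio. Monomorphic loci contribute nothing; θ is undefined
(raised) without a shared polymorphic locus. Tests pin θ against a
hand-worked biallelic variance-component oracle to 1e−10 and against the
closed-form pure-drift expectation FST ≈ 1 − (1 − 1/(2N))^g across
replicate populations. FST in the experiment drivers is computed on the
drawn samples (at these sample sizes the difference from population values
is negligible).

## Experiment drivers and problem sizes

`run_divergence_experiment` evolves n_pops populations from a common
founder with per-population cumulative frequency-drift state (checkpointed
across horizons; the individual-based tail is branched per horizon),
samples each, applies missingness, and computes FST, per-population Ne,
immigrant mixtures with before/after-cleaning Ne and detection counts.
`run_contamination_experiment` adds nested contaminant sets progressively
and scores a final cleaning pass. `run_ne_distribution` produces replicate
estimate distributions across Pcrit with the pooled-tail histogram
convention (estimates below −20,000 and above +40,000 collapse into the
end bins).

Replication defaults are desk-scale choices: the acceptance script uses 10
populations (45 FST pairs), 10 no-immigrant estimates and 20 mixtures; the
test suite uses 6/6; distribution studies default to 200 replicates. All
counts are explicit parameters, so full-size designs (90 mixtures,
10,000 replicates) are reachable by argument. With the hybrid fast path the
full acceptance run takes ~20 s on one CPU.

## What the synthetic data does and does not show

The generator reproduces the empirical panel's *marginal* allele-frequency
structure and missingness, under ideal Wright–Fisher assumptions: no
mutation over the divergence horizons (real divergence at 2000 generations
would be larger), no selection, no genotyping error, no null alleles, no
age structure, and contaminants whose alleles are fully private. Passing
tests therefore demonstrate the estimator and the screen behave correctly
*under the stated model* — they do not certify behaviour under genotyping
artefacts or weak, recent structure, where the CA screen's detection rate
degrades smoothly with FST (the divergence series quantifies this).

## Known limitations

- The jackknife interval is a normal approximation on r̂²′; coverage for
  small locus counts (the minimum of 3 pairs) is optimistic.
- S_eff as an unweighted harmonic mean over locus pairs is one defensible
  choice among several; alternatives differ at the sub-percent level for
  the missingness patterns considered here.
- The CA threshold of 2 is calibrated for samples of hundreds to thousands
  of individuals at this panel size; very small samples concentrate mass
  per row and need a re-examined threshold.
- Within-locus (Hardy–Weinberg) testing, temporal/sibship Ne methods,
  linked loci and admixture-proportion estimation are out of scope.
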