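# Methods

## The demographic model

The model is a two-population structured coalescent. A wild population of
constant scaled diversity θ_W = 4N_Wµ per bp gives rise to a domestic
population t generations ago (one generation per year for an annual
plant). Looking forward in time, the domestic population starts at
bottleneck diversity θ_D0 and grows exponentially to its present θ_D1;
the constraint θ_D0 ≤ min(θ_D1, θ_W) makes every draw a bottleneck
followed by expansion. Gene flow may act in both directions at scaled
rates 4Nm (wild→domestic and domestic→wild) between the present and the
domestication time; at that time, looking backward, all domestic lineages
merge into the wild population and migration ceases. Per-bp recombination
is ρ = 4N_W r. Time is reported in units of 4N_W generations,
T = tµ/θ_W.

msprime generates the genealogies. We run it with haploid (ploidy-1)
populations sized so that a population of size N has pairwise diversity
2Nµ: the wild simulator size is θ_W/(2µ) (numerically equal to 2N_e of
the diploid convention), the domestic growth rate is ln(θ_D1/θ_D0)/t per
generation, backward migration rates are M/(2·θ_W/(2µ)) and the per-bp
recombination rate ρ/(2·θ_W/(2µ)). In this scaling the single-population
constant-size limit reproduces E[π_total] = θ·L and E[S] = θ·L·a_n
exactly (checked at 2,000 replicates in the test suite).

Assumptions inherited from the study design: a single domestication
event; constant wild population size; mutation and recombination rates
shared across loci; free recombination between loci (independent
genealogies); one sequenced haplotype per individual (haploid samples).

### Priors

| parameter | prior | default bounds |
|---|---|---|
| θ_W | log-uniform | 10⁻³ … 1 |
| θ_D1 | log-uniform | 10⁻⁸ … 1 |
| θ_D0 | log-uniform, conditional | 10⁻⁵·m … m, m = min(θ_D1, θ_W) |
| ρ | log-uniform | 10⁻⁵⁰ … 1 |
| 4Nm (each direction) | uniform | 0 … 100 (with-migration scenario) |
| t | uniform | 3,000 … 12,000 generations |
| µ | log-normal | log-mean −17.7, log-sd 1 (median ≈ 2.04×10⁻⁸) |

The t window is the archaeological bracket for Sahelian agriculture; the
µ prior covers published grass mutation-rate estimates and their
uncertainty. The two migration rates are independent draws; a
configuration switch collapses them to a single shared rate. The ρ
lower bound is retained as given and sampled in log space; its posterior
is expected to track the prior.

## Summary statistics

Per locus and population: He (haplotype gene diversity, n(1−Σp²)/(n−1)),
π per site, exclusive-polymorphism count, variance of pairwise
differences (population variance over the n(n−1)/2 pair counts), and
Tajima's D; additionally for the domestic population (whose history is
richer): frequency of the most common haplotype, number of singletons,
and Harpending's raggedness of the mismatch distribution. Two-population
statistics: pooled He, minimum/mean/variance of between-population
pairwise distances, and Wakeley–Hey counts of fixed differences, shared
and exclusive polymorphisms. Three spatial statistics summarize the
arrangement of site classes along the sequence: RS is the Wald–Wolfowitz
standardized run count of the left-to-right sequence of exclusive-site
labels, and Wx1s2 / Wx2s1 are the mean distances (in bp, normalized by
analyzed length; 1 when no shared site exists) from each exclusive site
of one population to the nearest shared polymorphism. These three are
explicit stand-ins for an unpublished statistic family with the same
intent (sensitivity to the presence and direction of gene flow) and are
pluggable (`twopop.spatial_stat_fns`) without touching the ABC layer.

The multi-locus feature vector holds, in a fixed named order (48
entries), the across-locus mean and variance of each statistic, except
that each spatial statistic contributes its across-locus mean and the
one-sample Kolmogorov–Smirnov D of its z-scored per-locus values against
the standard normal ("normalized" is read as z-scoring by the
across-locus sample mean and SD). Per-locus undefined values (D with
S = 0; spatial statistics lacking the required site classes) are imputed
with the across-locus mean of defined values before the mean/variance are
taken; a statistic undefined at every locus is flagged and the flagged
entry is dropped from distance computations consistently for observed and
simulated data. Inside a reference table, dataset-level flagged entries
are imputed with the column mean over datasets where the entry is
defined, so a finished table has no undefined entries.

Variances across loci use the sample (n−1) variance. Singletons are
defined by minor-allele count 1 — no outgroup exists to orient alleles —
and F* accordingly uses the total-singleton (η_s) form with the corrected
variance constants; multi-allelic sites count as segregating once, each
extra allele as an extra mutation (η), and each differing column
contributes 1 to pairwise differences. Gap/ambiguity handling is complete
deletion: columns containing '-' or 'N' in any sequence are excluded and
the analyzed length L_eff is reported alongside.

## ABC

Rejection uses a Euclidean distance on summaries standardized entry-wise
by the MAD estimated from the reference table (SD when the MAD is zero;
zero-scale columns are dropped with a warning). Acceptance is specified
by a kept-simulation count; the study's geometry (closest 10% of the
pooled tables) is the default guidance. Ties are broken by row index so
results are reproducible.

Scenario choice pools both tables, keeps the overall-closest rows and
fits a logistic regression of the scenario indicator on the standardized
summaries, weighted by an Epanechnikov kernel on distance and centered at
the observation; the fitted probability at the observed vector is the
scenario posterior. If the retained set is single-scenario the
probabilities degenerate to {1, 0} with a warning.

Parameter adjustment operates on transformed parameters so adjusted
draws respect the prior support: log-uniform parameters are mapped by a
logit of their position inside the log bounds, uniform parameters by a
logit inside their bounds, and µ (unbounded log-normal) by a plain log.
θ_D0's bounds are conditional on min(θ_D1, θ_W); its back-transform is
applied after θ_W and θ_D1 so the bottleneck ordering holds for adjusted
draws by construction. Local-linear adjustment is a weighted linear
regression (Epanechnikov weights) with residuals re-attached to the fit
at the observation. The nonlinear variant fits a single-hidden-layer
network (10 units, LBFGS) for the conditional mean and a second network
on log squared residuals for the conditional spread, rescaling residuals
by the spread ratio (clipped to [0.1, 10] for stability); because the
network implementation does not accept per-sample weights, these two fits
are unweighted over the accepted set, while the kernel weights are kept
as posterior weights. Singular or non-finite fits fall back to plain
rejection with a warning.

Point estimates are weighted medians (midpoint interpolation at exact
0.5 mass); 95% HPD intervals are the shortest contiguous window of the
weighted sorted sample holding ≥95% of the mass — an empirical-sample
definition chosen over kernel density estimation for determinism.
Derived quantities use posterior medians: domestication time in years
t = T·θ_W/µ, bottleneck severity θ_D0/θ_W, expansion θ_D1/θ_D0; when a
full sample is available the per-draw distributions are returned too
(the ratio of medians and the median of ratios differ for heavy-tailed
posteriors — both are available).

## Posterior-predictive neutrality tests

For a candidate locus with observed segregating-site count S, each null
replicate draws one parameter vector from the weighted posterior,
simulates the two-population genealogy at the locus's sample sizes, and
places exactly S mutations on branches of the focal subsample's marginal
genealogy with probability proportional to branch length — the fixed-S
conditioning of classic coalescent simulators, restricted to the tested
group so every simulated site is polymorphic within it. D and F* are
computed from the derived-allele counts. Landrace subgroups (early/late)
are tested by treating each as the domestic sample of the fitted model.
ρ is drawn from the posterior like every other parameter (its posterior
essentially equals the prior); a `rho_zero` switch forces ρ = 0.

Reported p-values are one-sided in the direction of the observed
statistic's sign, with the +1/+1 correction (never 0). Two calibration
facts matter for interpreting them. First, this sign-directed p folds the
two tails: under the null it is uniform on (0, 0.5], not (0, 1], and
rejects at roughly 2α — calibration checks therefore use the one-sided
lower-tail probability (`neutrality.tail_pvalue`), which is verified to
be uniform by simulation. Second, fixing S on the unconditioned genealogy
is not the same null as conditioning the genealogy on S; empirically the
tail probability is uniform to within KS sampling error for posteriors
of realistic width, and drawing parameters from the full posterior rather
than a point estimate makes the test conservative (checked as a trend in
the suite).

## Synthetic data

The generator emulates the study design: eight unlinked STS-shaped loci
with the published per-locus sample sizes (domestic 29–61, wild 12–22)
and lengths (440–1,995 bp), simulated under the domestication model. The
default truth is the reported posterior medians; migration (not point
estimated in the study — its posterior tracks the uniform 0–100 prior)
defaults to a moderate 4Nm = 1 in each direction, and ρ defaults to θ_W,
a plausible ratio for an outcrossing grass. Binary haplotypes are encoded
as nucleotides with one ancestral and one derived base per site
(infinite-sites, biallelic) over a per-locus random reference;
continuous coordinates map to distinct integer bp (collisions resampled).
No indels, sequencing error or PCR artifacts are synthesized, so complete
deletion keeps every site (L_eff = L) and alignment statistics equal the
simulated-matrix statistics exactly — which is what the round-trip tests
assert. Passing tests on these data therefore validate the pipeline's
computations and calibration, not robustness to alignment error,
missing data or phasing uncertainty in real sequences.

Control loci provide directional truths: the star-genealogy locus
assigns every mutation to a single random leaf (all variants singletons
— the caricature of a completed sweep; strongly negative D and F*), and
the intermediate-frequency locus puts every variant at frequency ⌊n/2⌋
(positive D, the balancing-selection caricature).

## Numerical and implementation choices

- **Batched simulation.** msprime's per-call setup dominates
  single-locus runtimes, so `simulate_dataset` makes one call with
  `num_replicates = n_loci` at the maximal (n_wild, n_dom, L)
  configuration and carves each locus out by subsampling lineages
  (exchangeability of the coalescent) and restricting mutations and
  sequence to [0, L_i) (spatial consistency of the ancestral
  recombination graph) — distributionally identical to per-locus calls
  and several-fold faster. The per-locus path remains available
  (`batch=False`) and the two are checked against each other.
- **Degenerate statistics** raise a typed error rather than returning 0:
  D and F* with S = 0, D's zero-variance case (n = 3, S = 1), Fst with
  π_between = 0. Aggregators record them as missing.
- **Scales in the suite.** The recovery study uses a 20,000-row
  reference table, 500 kept, 20 pseudo-observed datasets; neutrality
  calibration uses 200 replicates at 1,000 null simulations; simulator
  calibration 2,000 replicates. The acceptance script defaults to a
  lighter 8,000-row / 12-dataset recovery and 100×400 calibration.
  These sizes are the package's chosen desk-scale study; precision
  scales with them in the usual √n way.
- **Determinism.** Every stochastic routine takes a seed or Generator;
  msprime seeds are drawn from the caller's generator, so identical
  seeds give bitwise-identical simulations, tables and fixtures.

## Known limitations

- The spatial statistics are stand-in definitions; inference that leans
  on gene-flow direction should treat them as one reasonable choice
  among several (they are swappable).
- Local-linear adjustment can under-cover for parameters weakly
  constrained by the summaries; the recovery test's 14/20 threshold is a
  binomial tolerance around nominal 95% coverage at 20 replicates, not a
  claim of exact calibration.
- The model ignores population structure within groups, multiple
  domestications, wild-size changes, and locus-to-locus rate variation.
- Haplotype-based He was chosen where the study's table did not state
  the definition; per-site He would differ.
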