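# Methods

This note documents the statistical procedures implemented in `msatpop`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data validation does and does not establish.

## Data model

A `GenotypeMatrix` holds N diploid sampling units × L microsatellite loci.
Calls are unordered pairs of positive integers on an additive scale (repeat
numbers or fragment sizes); (a,b) ≡ (b,a) everywhere. A genotype with any
non-positive allele is treated as missing at that locus. Missing data is
handled by pairwise per-locus deletion: a genotype missing at a locus
contributes nothing to any statistic at that locus. Genepop files in 2- or
3-digit encoding are read (auto-detected, recorded on the matrix); writing
always emits 3-digit codes, which bounds representable allele sizes at 999.

## Clonal lineage discrimination

Samples with identical multilocus genotypes share an MLG (missing calls
match only missing calls unless the wildcard option is set). The distance
between two MLGs is summed per locus as 2 minus the allele-multiset
intersection (shared heterozygote 0; Aa vs AA 1; AA vs BB 2), skipping loci
missing in either. MLLs are the connected components of the graph joining
MLG pairs at distance ≤ a threshold (single linkage), default 2 — up to one
stepwise slip on each of two loci, the usual magnitude of somatic mutation
or scoring error. The result is invariant to sample order and monotone in
the threshold. Downstream analyses run on all sampling units by default; the
ABC stage keeps one representative per MLL (lowest-sorted sample id, for
determinism), since coalescent models describe genets, not ramets. The
probability-of-identical-genotypes statistic (p_sex) is out of scope: only
the MLG→MLL counts are needed here.

## Diversity and differentiation

* Unbiased gene diversity: H_E = (2n/(2n−1))(1 − Σ p̂²) with n the scored
  genotypes. Multi-locus summaries are unweighted means over informative
  loci.
* Allelic richness: hypergeometric rarefaction to g gene copies,
  Σₐ [1 − C(N_c−N_a, g)/C(N_c, g)]. g defaults per locus to the smallest
  per-population scored copy count (≥ 2), so populations of different sizes
  are comparable.
* Weir–Cockerham components: per allele, with the standard unequal-size
  weights (n̄, n_c, p̄, s², h̄), a = among populations, b = among individuals
  within populations, c = within individuals. Multi-locus estimators are
  ratios of summed components (never means of ratios): θ = Σa / Σ(a+b+c)
  over informative loci; the single-population f = 1 − Σc / Σ(b+c) uses the
  r=1 reduction (the s² and (r−1)/r terms vanish). Loci monomorphic across
  the included populations, or with fewer than two scored populations, or
  with mean sample size ≤ 1, are uninformative and excluded. Negative θ and
  f are reported as computed.
* Permutation tests are one-sided (excess structure / heterozygote deficit)
  with p = (#{perm ≥ obs} + 1)/(B + 1), so p is never 0 and the smallest
  attainable value is 1/(B+1) — B must exceed 1/α′ for a Bonferroni level
  α′ to be reachable (the default B = 10,000 reaches .000758; examples use
  smaller B and say so). The F_IS scheme shuffles gene copies among
  individuals within the population (allele frequencies are invariant, so
  only the heterozygote count varies — exploited for speed); the θ scheme
  shuffles whole multilocus genotypes between the two populations, batched
  as matrix products over permutations. Both schemes are driven by a single
  numpy Generator; a seed fully determines the stream.
* Bonferroni: α′ = α / n_tests, taken explicitly — 66 pairwise tests among
  12 populations give .000758.

## Ordination

Individuals are coded 0/1/2 on one column per (locus, allele); missing loci
contribute zero counts (the row keeps reduced mass rather than being
dropped, so sample sets stay identical across modules). Simple
correspondence analysis: P = X/total, masses r and c, standardized residuals
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, SVD, row principal coordinates
F = D_r^{-1/2} U Σ. Eigenvalues are squared singular values; axis signs are
canonicalized by making the largest-magnitude column loading positive, so
runs are reproducible and row order is irrelevant. Default 3 retained axes.
Population centroids are mass-weighted means of member coordinates.

## Divergence scenarios

A scenario is a backward-time event list over named demes: MERGE(time,
source→target) moves all lineages of the source into the target;
SIZE_CHANGE(time, deme, size) switches an effective size. Event times and
sizes are named parameters with priors — log-uniform over a printed range by
default (ranges are the only reproducible anchor when only bounds are
published), truncated log-normal available. Joint draws are rejected until
the declared order constraints hold (t0 < t2 < t3). Validation sweeps the
merge sequence symbolically and requires exactly one surviving deme;
events are ordered by the constraint graph, so file order is irrelevant.

The shipped `scenario13` has four sampled demes (N, NE, NW, CW with sizes
Ne1..Ne4), CW merging into NW at t2, and NW and NE merging into N at t3 —
modeled as two simultaneous merges, the simplest topology consistent with a
single old three-way divergence — after which N takes the ancestral size
Na. The t3 prior is 10–2×10⁶ generations, Ne priors 10–10⁷, Na 10–10⁵.
The t0 parameter (prior 10–10⁴) is implemented as a size change on CW from
Ne4 to Na backward in time — forward: CW founded at the small ancestral
size and expanding at t0. Its biological role is not resolved; the config
flags it `interpretation: unresolved`, and it is retained so the parameter
vector matches the published prior table. `scenario13_alternative` is the
exact deme relabeling N↔NW, NE↔CW of scenario 13 (the t0 size change moves
to the merging deme NE): a true topology permutation with identical priors,
so model choice between the two is a symmetric, well-posed problem. Other
scenarios can be written in the same YAML grammar.

Times are in generations; a generation interval of 3 years converts to
calendar dates (e.g. 2790 generations → 8370 years).

## Coalescent simulation and mutation

Genealogies come from msprime's continuous-time Kingman coalescent
(pair-coalescence rate k(k−1)/(4Ne) per generation for diploid Ne), one
independent tree per locus, with merges as total mass migrations and size
changes as population-parameter changes. The generalized stepwise mutation
model is applied in-package on the tree: each branch receives
Poisson(μ·length) mutations; each mutation steps the repeat number ±k with
k ~ geometric(P) (P=0 is the strict SMM), direction symmetric, reflected at
the bounds of a 200-state allele ladder whose midpoint is the ancestral
state (a numba kernel walks the tree root-down, applying mutations in
sequence so reflection is exact). Repeat states map to positive genepop
codes by an affine offset. Per-locus rates are drawn around the mean rate
from a Gamma with shape 2 (locus heterogeneity); the mean-rate prior is
log-uniform on [10⁻⁴, 10⁻³] and the GSM parameter P uniform on [0, 0.3] —
standard microsatellite values, both config-exposed. Gene copies are paired
into diploids within demes at random (no selfing: the ABC models genets as
outbred individuals).

Consequences worth knowing: at these mutation rates homoplasy caps θ well
below 1 (θ saturates once divergence times exceed a few Ne), so very old
split times are only bounded from below by the data — visible as wide t3
posteriors.

## ABC

Summary panel (fixed order): per deme the mean number of alleles per locus
and the mean unbiased gene diversity; per deme pair the multilocus θ —
4+4+6 = 14 statistics for four demes. Uninformative entries are set to 0
and masked out of distances. The reference table stores raw statistics with
each scenario's parameter draw (including the mutation nuisance parameters);
row seeds derive from (seed, scenario, row), so the table can be built in
batches and is bit-reproducible.

Rejection standardizes each statistic by its median absolute deviation
across the table (zero-MAD columns are dropped) and keeps the
⌈fraction·rows⌉ closest by Euclidean distance; default retain fraction
0.01. Scenario choice: the direct estimate is the scenario composition of
the n_δ closest rows (default 500, or all retained); the logistic estimate
fits a ridge-penalized (10⁻⁶) multinomial regression of scenario id on
standardized deviations, Epanechnikov-weighted, and evaluates it at
deviation zero. With a single scenario among the retained the direct
estimate is returned with a degeneracy flag.

Parameter posteriors (per scenario): retained draws are weighted by an
Epanechnikov kernel on distance; each parameter is mapped to the real line
by a logit on its prior bounds, regressed on the standardized deviations
(weighted least squares), and the residuals-at-zero are back-transformed —
the Beaumont local-linear adjustment, which respects the prior support by
construction. Summaries: weighted median and central 95% interval by the
weighted empirical CDF; the mode from a weighted Gaussian KDE on the
transformed scale, back-transformed (for priors spanning decades the
transformed scale is the natural one for density estimation). A
rank-deficient regression falls back to unadjusted weighted quantiles, with
a flag. The posterior predictive check resamples retained draws by weight,
re-simulates, and reports per statistic the two-sided tail probability
min(p, 1−p)·2 of the observed value.

The published analysis ran ~10⁷ simulations per scenario; the defaults here
target minutes on one core, and every size is a config key.

## Synthetic study-shaped data

`make_study_like` emulates the sampling design: 12 meadow labels at the
published sizes (331 sampling units at scale 1) nested in the four regional
demes plus a small distant Cyprus-like deme, 18 loci. Meadows within a deme
are drawn from the same simulated deme — within-deme substructure is
deliberately absent so truth stays unambiguous; within-deme θ is therefore
≈ 0, unlike real meadow mosaics. The Cyprus-like deme is attached by a
merge into the surviving N lineage at t4 = 30,000 generations with
NeC = 2×10⁴ (it splits off earliest, matching its outlier position in the
ordination). Generating parameters are the published point estimates for
the deme sizes and split times (Ne1 = 2.67×10⁴, Ne2 = 1.27×10⁴,
Ne3 = 9.15×10³, Ne4 = 1.53×10⁵, t2 = 1530, t3 = 9270), with Na = 5×10⁴,
t0 = 324 and mean mutation rate 10⁻⁴ chosen once so that between-deme θ
spans roughly the observed 0.02–0.30 and gene diversity is moderate
(~0.7); these are fixed constants, not tuning knobs.

Artifacts are then injected with an exact ledger: null alleles per locus
(frequency ~ U(0, 0.15); null/null → missing, null/visible → apparent
homozygote), which depress H_obs and push F_IS positive at realistic
magnitude; and 3 clone pairs (a same-meadow sample overwritten by a
near-copy with ≤ 2 single-step edits on scored loci), so the clonality
stage must report exactly N − 3 lineages. Passing the truth round-trip
shows the pipeline recovers known structure under these idealized
conditions; it does not establish robustness to real-data features the
generator omits (within-meadow patchiness, allele binning errors, linked
loci, migration after divergence).

## Validation problem sizes and operating points

Chosen for single-core runtimes, and fixed:

* Permutation-test calibration: two pools of 50 from one panmictic gene
  pool, 5 loci, B = 1000, 500 replicates; the empirical type-I rate at
  nominal 0.05 must lie in [0.04, 0.06]. (The exact test guarantees
  P(p ≤ 0.05) = 50/1001 under exchangeability.)
* Simulator moments: pairwise TMRCA = 2Ne (10⁴ replicates, ±5%); SMM
  between-deme (δμ)² = 2μτ (2000 loci, unbounded ladder, ±10%); SMM
  equilibrium gene diversity 1 − 1/√(1+8Neμ) (500 loci, ±10%).
* Scenario recovery: 20,000-row reference table over scenario 13 and its
  topology permutation; four demes × 15 diploids, 10 loci; pseudo-observed
  data from scenario 13 at the mid-prior operating point, defined as the
  marginal medians of the joint (constraint-respecting) prior —
  Ne = 10⁴, Na = 10³, t0 = 95, t2 = 3150, t3 = 1.29×10⁵ generations.
  Per-parameter log-midpoints are not usable here: they put t2 and t3
  within a factor 1.4, where the two topologies are statistically
  indistinguishable and the check would be vacuous.
* Parameter recovery: 8,000-row scenario-13 table, 50 pseudo-observed
  datasets with generating parameters drawn from the prior; 95% CI coverage
  for t2 and t3 must sit in [0.85, 0.99] (prior-draw truths make this a
  Bayesian calibration check) and posterior medians must track truth with
  Spearman ρ > 0.7 on the log scale.

## Known limitations

* No migration or admixture after divergence in the scenario grammar (the
  tested histories are pure splits).
* The summary panel is the three-family panel (allele counts, gene
  diversities, θ), not a full microsatellite panel with allele-size
  variances; allele-size-based statistics would add power for old splits.
* Single-threaded reference-table builds; table sizes in the millions are
  out of intended range.
* The FCA keeps all-missing individuals at zero mass rather than dropping
  them; their coordinates are 0, which can visually suggest centrality.
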