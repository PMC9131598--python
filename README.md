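# msatpop

Population-genetic analysis and coalescent-based demographic inference for
diploid microsatellite data from partially clonal organisms — built around
the kind of study design used for Mediterranean seagrass meadows: a dozen
sampled meadows grouped into a few regional demes, a panel of ~18
microsatellite loci, rare clonal replicates, and divergence histories tested
by approximate Bayesian computation (ABC).

## What it computes

Given diploid allele-size genotypes (genepop or TSV), the library runs the
full analysis chain:

1. **Clonality** — samples with identical multilocus genotypes (MLGs) are
   grouped, and MLGs differing by at most a small allele distance are
   collapsed into multilocus lineages (MLLs) by single-linkage clustering
   (somatic mutation / scoring error tolerance).
2. **Diversity** (per population): unbiased expected heterozygosity
   H_E = (2n/(2n−1))(1 − Σₐ p̂ₐ²), observed heterozygosity, rarefied allelic
   richness Σₐ [1 − C(N_c−N_a, g)/C(N_c, g)], and the Weir–Cockerham
   within-population fixation index f (F_IS), with a one-sided permutation
   test (alleles shuffled among individuals within the population).
3. **Differentiation**: pairwise θ (F_ST) from the Weir–Cockerham variance
   components a, b, c — multi-locus values as ratios of summed components —
   with genotype-permutation p-values and Bonferroni-adjusted nominal levels
   (α′ = α / #tests; 66 pairwise tests among 12 populations give
   α′ ≈ .000758).
4. **Ordination**: factorial correspondence analysis of individuals coded
   0/1/2 per (locus, allele), with population centroids — the basis for
   pooling meadows into regional demes.
5. **Demographic inference (ABC)**: coalescent simulation (msprime) under
   declarative divergence scenarios with a generalized stepwise mutation
   model (Poisson mutations per branch; step size k ~ geometric(P),
   reflected at the allele-ladder bounds), a reference table of summary
   statistics (allele numbers, gene diversities, pairwise θ), rejection
   sampling, scenario choice by direct frequency and multinomial logistic
   regression, and Beaumont-style local-linear regression posteriors for
   the parameters (effective sizes Ne, ancestral size Na, divergence times
   t in generations; 3 years per generation for calendar dates).

A `synthetic` module generates complete study-shaped datasets with known
truth (generating parameters, injected null alleles, injected clone pairs),
so every stage can be validated end to end.

## Worked example

```python
import msatpop as mp
from msatpop.synthetic import make_study_like

bundle = make_study_like(seed=11, scale=0.25)   # 12 meadows, 18 loci
gm = bundle.corrupted                            # with nulls + 3 clone pairs

part = mp.identify_mlg(gm)
coll = mp.collapse_mll(part, gm, threshold=2)
print(gm.n_samples, coll.n_mlg, coll.n_mll)      # -> 83 82 80

div = mp.diversity_table(gm, B=1000, seed=1)
print(div[["pop", "H_exp", "H_obs", "F_is"]].head(3).round(3))
#    pop  H_exp  H_obs   F_is
#    LEM  0.565  0.528  0.095
#    IME  0.729  0.673  0.083
#    FAN  0.794  0.757  0.049
```

`83 82 80` reads: 83 sampling units, 82 distinct multilocus genotypes, 80
lineages after collapsing — i.e. exactly the 3 injected clone pairs were
recovered. The diversity rows show the null-allele-driven heterozygote
deficit (H_obs < H_exp, F_IS > 0). The `examples/` directory has one short
script per capability (I/O, clonality, diversity/F_ST, ordination, scenario
simulation, ABC inference); each prints its numbers with a line on what
they mean. A thin CLI (`msatpop run|synth|stats|abc`) drives the same
pipeline from YAML configs.

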