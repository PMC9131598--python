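"""Divergence scenarios, priors, and coalescent simulation with stepwise
mutation.

Loads the shipped best-supported scenario (CW merges into NW at t2; NW and
NE merge into N at t3, which takes the ancestral size Na), draws parameters
from the priors, and simulates a diploid microsatellite dataset. Pairwise
theta mirrors the split order: the demes that diverged most recently (NW,
CW) are the least differentiated.
"""

import numpy as np

import msatpop as mp
from msatpop.simulate import SimConfig

scn = mp.scenario13()
print("parameters and priors:")
for name, spec in scn.priors.items():
    print(f"  {name:4s} {spec.shape:12s} [{spec.low:g}, {spec.high:g}]")

draws = scn.sample_priors(5, seed=1)
print("\nfive joint prior draws (order constraint t0 < t2 < t3 enforced):")
print(draws.round(1).to_string(index=False))

params = dict(Ne1=2.7e4, Ne2=1.3e4, Ne3=9.2e3, Ne4=1.5e5,
              Na=5e4, t0=324, t2=1530, t3=9270)
cfg = SimConfig(sample_sizes={"N": 30, "NE": 30, "NW": 30, "CW": 30}, n_loci=18)
ds = mp.simulate_dataset(scn, params, cfg, seed=7,
                         mu_locus=np.full(18, 1e-4), gsm_p=0.1)

print(f"\nsimulated {ds.gm.n_samples} diploids x {ds.gm.n_loci} loci")
pops = ds.gm.populations
print("pairwise theta under the generating history:")
for i, a in enumerate(pops):
    for b in pops[i + 1:]:
        print(f"  {a}-{b}: {mp.pairwise_theta(ds.gm, a, b):.3f}")
print("(NW-CW split most recently at t2, so their theta is smallest)")
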