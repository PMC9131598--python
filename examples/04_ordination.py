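"""Factorial correspondence analysis of individuals coded by allele counts.

Individuals are coded 0/1/2 per (locus, allele) column and ordinated by
simple correspondence analysis; meadow centroids on the first two axes
recover the regional grouping (meadows of the same deme plot together),
which is how meadows are pooled into demes for the demographic analysis.
"""

import numpy as np

import msatpop as mp
from msatpop.fca import allele_count_coding, correspondence_analysis, population_centroids
from msatpop.synthetic import MEADOW_TO_DEME, make_study_like

gm = make_study_like(seed=11, scale=0.25).clean

table = allele_count_coding(gm)
res = correspondence_analysis(table, k_axes=3)
cent = population_centroids(res, gm.pop_labels)

print("percent inertia of axes 1-3:", np.round(res.percent_inertia, 2))
print("\nmeadow centroids (axes 1-2) with their regional deme:")
for pop, row in cent.iterrows():
    print(f"  {pop:4s} deme={MEADOW_TO_DEME[pop]:3s} "
          f"axis1={row['axis1']:+.3f} axis2={row['axis2']:+.3f}")

within, between = [], []
pops = list(cent.index)
for i, a in enumerate(pops):
    for b in pops[i + 1:]:
        d = np.linalg.norm(cent.loc[a] - cent.loc[b])
        (within if MEADOW_TO_DEME[a] == MEADOW_TO_DEME[b] else between).append(d)
print(f"\nmean centroid distance within demes:  {np.mean(within):.3f}")
print(f"mean centroid distance between demes: {np.mean(between):.3f}")
print("same-deme meadows cluster:", np.mean(within) < np.mean(between))
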