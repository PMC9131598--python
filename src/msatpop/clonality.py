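"""Multilocus genotype (MLG) identification and multilocus lineage (MLL) collapse.

In partially clonal organisms, samples with identical multilocus genotypes are
putative ramets of one genet; genotypes differing by only a few allele calls
(somatic mutation or scoring slippage) are grouped into multilocus lineages by
single-linkage clustering at an allele-difference threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class MLLPartition:
    """sample -> MLG -> MLL assignment, plus per-population counts."""

    mlg_of: np.ndarray  # (N,) int, MLG index per sample
    mll_of: np.ndarray  # (n_mlg,) int, MLL index per MLG
    distance_threshold: int
    gm: GenotypeMatrix

    @property
    def n_mlg(self) -> int:
        return int(self.mll_of.shape[0])

    @property
    def n_mll(self) -> int:
        return int(np.unique(self.mll_of).shape[0])

    def mll_of_sample(self) -> np.ndarray:
        return self.mll_of[self.mlg_of]

    def counts(self) -> pd.DataFrame:
        """Per population: N, #MLG, #MLL (the Table-1-style clonal columns)."""
        rows = []
        mll_sample = self.mll_of_sample()
        for pop in self.gm.populations:
            m = self.gm.pop_mask(pop)
            rows.append(
                {
                    "pop": pop,
                    "N": int(m.sum()),
                    "MLG": int(np.unique(self.mlg_of[m]).shape[0]),
                    "MLL": int(np.unique(mll_sample[m]).shape[0]),
                }
            )
        return pd.DataFrame(rows)

    def representatives(self) -> np.ndarray:
        """One sample index per MLL: the lexicographically lowest sample id."""
        mll_sample = self.mll_of_sample()
        reps = {}
        for i in np.argsort(np.asarray(self.gm.sample_ids, dtype=object)):
            reps.setdefault(int(mll_sample[i]), int(i))
        return np.array(sorted(reps.values()))

    def to_tsv(self, path) -> None:
        mll_sample = self.mll_of_sample()
        df = pd.DataFrame(
            {
                "sample": self.gm.sample_ids,
                "pop": self.gm.pop_labels,
                "mlg": self.mlg_of,
                "mll": mll_sample,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def allele_distance(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int]:
    """Allele difference between two multilocus genotypes over shared loci.

    Per locus, the distance is the number of allele slots not matched between
    the two allele multisets (2 minus the multiset intersection size): a shared
    heterozygote counts 0, (100,120) vs (100,100) counts 1, (100,100) vs
    (120,120) counts 2. Distances are summed over loci scored in both.
    Loci missing in either genotype are skipped; returns (distance, n_skipped).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape or g1.ndim != 2 or g1.shape[1] != 2:
        raise ValueError("genotypes must share the same (L, 2) locus layout")
    ok = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    if not ok.any() and g1.shape[0] > 0:
        raise ValueError("genotypes share no scored locus")
    a, b = g1[ok], g2[ok]
    # pairs stored sorted, so per-locus multiset difference has a closed form
    same = (a == b).all(axis=1)
    one_shared = (
        (a[:, 0] == b[:, 0]) | (a[:, 1] == b[:, 1])
        | (a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])
    )
    per_locus = np.where(same, 0, np.where(one_shared, 1, 2))
    return int(per_locus.sum()), int((~ok).sum())


def identify_mlg(gm: GenotypeMatrix, missing_matches: bool = False) -> MLLPartition:
    """Exact-match partition of samples into multilocus genotypes.

    With missing_matches=False (default) a missing call only matches another
    missing call; with True, missing acts as a wildcard (grouped greedily in
    sample order against earlier group representatives).
    """
    n = gm.n_samples
    mlg = np.full(n, -1, dtype=int)
    if not missing_matches:
        keys: dict[bytes, int] = {}
        for i in range(n):
            k = gm.calls[i].tobytes()
            mlg[i] = keys.setdefault(k, len(keys))
    else:
        reps: list[int] = []
        miss = gm.missing_mask()
        for i in range(n):
            for gi, r in enumerate(reps):
                ok = ~(miss[i] | miss[r])
                if (gm.calls[i, ok] == gm.calls[r, ok]).all():
                    mlg[i] = gi
                    break
            else:
                mlg[i] = len(reps)
                reps.append(i)
    n_mlg = int(mlg.max()) + 1
    return MLLPartition(
        mlg_of=mlg,
        mll_of=np.arange(n_mlg),
        distance_threshold=0,
        gm=gm,
    )


def collapse_mll(
    part: MLLPartition, gm: GenotypeMatrix, threshold: int
) -> MLLPartition:
    """Join MLGs within `threshold` allele differences by single linkage.

    Connected components of the graph whose edges link MLG pairs with
    allele_distance <= threshold. threshold=0 leaves the partition unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n_mlg = part.n_mlg
    # one representative genotype per MLG (identical by construction)
    rep = np.zeros(n_mlg, dtype=int)
    for i in range(gm.n_samples - 1, -1, -1):
        rep[part.mlg_of[i]] = i
    parent = np.arange(n_mlg)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if threshold > 0:
        for i in range(n_mlg):
            for j in range(i + 1, n_mlg):
                d, _ = allele_distance(gm.calls[rep[i]], gm.calls[rep[j]])
                if d <= threshold:
                    parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n_mlg)])
    # renumber components by first appearance
    _, mll = np.unique(roots, return_inverse=True)
    order = {}
    canon = np.empty_like(mll)
    for i, m in enumerate(mll):
        canon[i] = order.setdefault(int(m), len(order))
    return MLLPartition(
        mlg_of=part.mlg_of,
        mll_of=canon,
        distance_threshold=threshold,
        gm=gm,
    )
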