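"""Per-population diversity and pairwise differentiation for codominant loci.

Implements the Weir & Cockerham (1984) variance-component estimators: the
among-population component a, the among-individual-within-population
component b and the within-individual component c, computed per allele with
the standard unequal-sample-size weights and combined across alleles and loci
as ratios of sums. theta = a/(a+b+c) estimates F_ST; f = 1 - c/(b+c) within a
single population estimates F_IS (positive under heterozygote deficit).

Gene diversity is the small-sample-unbiased expected heterozygosity
(2n/(2n-1)) * (1 - sum p^2); allelic richness is the hypergeometric expected
allele count in a rarefied draw of g gene copies.

Significance is by permutation: alleles permuted among individuals within a
population for f, whole multilocus genotypes permuted between two populations
for theta, with the (k+1)/(B+1) one-sided p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "allelic_richness",
    "wc_components",
    "within_components",
    "multilocus_fis",
    "pairwise_theta",
    "permutation_test",
    "adjusted_nominal_level",
    "diversity_table",
    "fst_matrix",
    "FstMatrix",
]


# ---------------------------------------------------------------------------
# basic per-locus quantities
# ---------------------------------------------------------------------------


def _locus_index(gm: GenotypeMatrix, locus) -> int:
    return locus if isinstance(locus, (int, np.integer)) else gm.loci.index(locus)


def _pop_locus_calls(gm: GenotypeMatrix, pop: str, locus) -> np.ndarray:
    """(n, 2) non-missing calls of one population at one locus."""
    l = _locus_index(gm, locus)
    calls = gm.calls[gm.pop_mask(pop), l]
    return calls[calls[:, 0] != MISSING]


def observed_heterozygosity(gm: GenotypeMatrix, pop: str, locus) -> float:
    c = _pop_locus_calls(gm, pop, locus)
    if c.shape[0] == 0:
        raise ValueError(f"no scored genotypes for {pop} at {locus}")
    return float((c[:, 0] != c[:, 1]).mean())


def unbiased_expected_heterozygosity(gm: GenotypeMatrix, pop: str, locus) -> float:
    """Nei's gene diversity with the 2n/(2n-1) small-sample correction."""
    c = _pop_locus_calls(gm, pop, locus)
    n = c.shape[0]
    if n < 2:
        raise ValueError(f"need >=2 scored genotypes for {pop} at {locus}")
    copies = c.ravel()
    _, counts = np.unique(copies, return_counts=True)
    p = counts / counts.sum()
    return float(2 * n / (2 * n - 1) * (1.0 - (p**2).sum()))


def allelic_richness(gm: GenotypeMatrix, pop: str, locus, g: int) -> float:
    """Expected number of distinct alleles among g gene copies drawn without
    replacement from the observed copies (hypergeometric rarefaction)."""
    c = _pop_locus_calls(gm, pop, locus)
    copies = c.ravel()
    n_c = copies.shape[0]
    if not 1 <= g <= n_c:
        raise ValueError(f"rarefaction size g={g} outside [1, {n_c}]")
    _, counts = np.unique(copies, return_counts=True)
    p_absent = hypergeom.pmf(0, n_c, counts, g)
    return float((1.0 - p_absent).sum())


def n_alleles(gm: GenotypeMatrix, pop: str, locus) -> int:
    c = _pop_locus_calls(gm, pop, locus)
    return int(np.unique(c.ravel()).shape[0])


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------


def _pop_allele_summaries(gm: GenotypeMatrix, pops, locus):
    """Per population at a locus: n_i, allele count vector, het-carrier vector.

    Returns (alleles, n, counts, hets) with counts/hets shaped (r, n_alleles);
    populations with no scored genotype are dropped.
    """
    l = _locus_index(gm, locus)
    per_pop = []
    for pop in pops:
        c = gm.calls[gm.pop_mask(pop), l]
        c = c[c[:, 0] != MISSING]
        if c.shape[0] > 0:
            per_pop.append((pop, c))
    if not per_pop:
        return np.array([]), np.array([]), np.zeros((0, 0)), np.zeros((0, 0))
    alleles = np.unique(np.concatenate([c.ravel() for _, c in per_pop]))
    aidx = {a: j for j, a in enumerate(alleles)}
    r = len(per_pop)
    counts = np.zeros((r, alleles.size))
    hets = np.zeros((r, alleles.size))
    n = np.zeros(r)
    for i, (_, c) in enumerate(per_pop):
        n[i] = c.shape[0]
        for a1, a2 in c:
            counts[i, aidx[a1]] += 1
            counts[i, aidx[a2]] += 1
            if a1 != a2:
                hets[i, aidx[a1]] += 1
                hets[i, aidx[a2]] += 1
    return alleles, n, counts, hets


def wc_components(gm: GenotypeMatrix, pops, locus):
    """(a, b, c) variance components summed over alleles at one locus.

    Returns None when the locus is uninformative: fewer than two populations
    scored, monomorphic across the included populations, or average sample
    size <= 1 individual.
    """
    alleles, n, counts, hets = _pop_allele_summaries(gm, pops, locus)
    r = n.shape[0]
    if r < 2 or alleles.size < 2:
        return None
    nbar = n.mean()
    if nbar <= 1:
        return None
    nsum = n.sum()
    nc = (nsum - (n**2).sum() / nsum) / (r - 1)
    p_i = counts / (2 * n[:, None])
    h_i = hets / n[:, None]
    pbar = (n[:, None] * p_i).sum(axis=0) / nsum
    s2 = (n[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h_i).sum(axis=0) / nsum
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def wc_pair_from_counts(n1, c1, h1, n2, c2, h2):
    """Two-population (a, a+b+c) for one locus from count summaries.

    n1, n2: scored individuals per population; c1, c2: allele count vectors on
    a shared allele index; h1, h2: per-allele heterozygote-carrier counts.
    Returns None for uninformative input (one allele, or mean n <= 1).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if n1 < 1 or n2 < 1:
        return None
    nonzero = (c1 + c2) > 0
    if nonzero.sum() < 2:
        return None
    nsum = n1 + n2
    nbar = nsum / 2
    if nbar <= 1:
        return None
    nc = nsum - (n1**2 + n2**2) / nsum
    p1 = c1 / (2 * n1)
    p2 = c2 / (2 * n2)
    pbar = (c1 + c2) / (2 * nsum)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (h1 + h2) / nsum
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a.sum()), float((a + b + c).sum())


def within_components(gm: GenotypeMatrix, pop: str, locus):
    """Single-population (b, c) components for the within-population f.

    The among-population terms vanish for one population; per allele
    b = n/(n-1) * (p(1-p) - (2n-1)/(4n) * hbar), c = hbar/2.
    Returns None for uninformative loci (monomorphic or n < 2).
    """
    alleles, n, counts, hets = _pop_allele_summaries(gm, [pop], locus)
    if n.shape[0] == 0 or alleles.size < 2 or n[0] < 2:
        return None
    nn = n[0]
    p = counts[0] / (2 * nn)
    hbar = hets[0] / nn
    b = (nn / (nn - 1)) * (p * (1 - p) - (2 * nn - 1) / (4 * nn) * hbar)
    c = hbar / 2
    return float(b.sum()), float(c.sum())


def multilocus_fis(gm: GenotypeMatrix, pop: str) -> float:
    """Weir-Cockerham f over all informative loci, ratio of summed components."""
    B = C = 0.0
    for l in range(gm.n_loci):
        bc = within_components(gm, pop, l)
        if bc is not None:
            B += bc[0]
            C += bc[1]
    denom = B + C
    if denom == 0:
        return float("nan")
    return 1.0 - C / denom


def pairwise_theta(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus theta between two populations (ratio of summed components)."""
    A = D = 0.0
    for l in range(gm.n_loci):
        abc = wc_components(gm, [pop_a, pop_b], l)
        if abc is not None:
            A += abc[0]
            D += abc[0] + abc[1] + abc[2]
    if D == 0:
        return float("nan")
    return A / D


# ---------------------------------------------------------------------------
# permutation tests (vectorized over permutations)
# ---------------------------------------------------------------------------


def _fis_perm_stats(gm: GenotypeMatrix, pop: str, B: int, rng) -> np.ndarray:
    """f for B within-population gene-copy shuffles.

    Allele frequencies are invariant under shuffling copies among individuals,
    so only the per-locus heterozygote count varies; f is recomputed from it.
    """
    per_locus = []
    for l in range(gm.n_loci):
        c = _pop_locus_calls(gm, pop, l)
        nn = c.shape[0]
        if nn < 2:
            continue
        copies = c.ravel()
        _, counts = np.unique(copies, return_counts=True)
        if counts.size < 2:
            continue
        p = counts / (2 * nn)
        sum_p1p = float((p * (1 - p)).sum())
        per_locus.append((nn, copies, sum_p1p))
    f = np.zeros(B)
    num = np.zeros(B)  # sum of c components
    den = np.zeros(B)  # sum of b + c components
    for nn, copies, sum_p1p in per_locus:
        m = copies.shape[0]
        ranks = rng.random((B, m)).argsort(axis=1)
        shuffled = copies[ranks]
        het_count = (shuffled[:, 0::2] != shuffled[:, 1::2]).sum(axis=1)
        sum_hbar = 2.0 * het_count / nn  # sum over alleles of h_a
        b = (nn / (nn - 1)) * (sum_p1p - (2 * nn - 1) / (4 * nn) * sum_hbar)
        c = sum_hbar / 2
        num += c
        den += b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - num / den
    return f


def _theta_perm_stats(
    gm: GenotypeMatrix, pop_a: str, pop_b: str, B: int, rng, chunk: int = 2000
) -> np.ndarray:
    """theta for B shuffles of multilocus genotypes between two populations."""
    mask_a, mask_b = gm.pop_mask(pop_a), gm.pop_mask(pop_b)
    idx = np.flatnonzero(mask_a | mask_b)
    n_ind = idx.size
    n_a = int(mask_a.sum())
    # per-locus one-hot structures over the pooled individuals
    loci_data = []
    for l in range(gm.n_loci):
        calls = gm.calls[idx, l]
        valid = calls[:, 0] != MISSING
        if valid.sum() < 2:
            continue
        alleles = np.unique(calls[valid].ravel())
        if alleles.size < 2:
            continue
        X = np.zeros((n_ind, alleles.size), dtype=np.float64)
        H = np.zeros_like(X)
        aidx = {a: j for j, a in enumerate(alleles)}
        for i in np.flatnonzero(valid):
            a1, a2 = calls[i]
            X[i, aidx[a1]] += 1
            X[i, aidx[a2]] += 1
            if a1 != a2:
                H[i, aidx[a1]] += 1
                H[i, aidx[a2]] += 1
        loci_data.append((X, H, valid.astype(np.float64)))
    thetas = np.empty(B)
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        ranks = rng.random((nb, n_ind)).argsort(axis=1).argsort(axis=1)
        Z = (ranks < n_a).astype(np.float64)  # membership in pop A
        num = np.zeros(nb)
        den = np.zeros(nb)
        for X, H, valid in loci_data:
            tot_n = valid.sum()
            tot_counts = X.sum(axis=0)
            tot_hets = H.sum(axis=0)
            nA = Z @ valid
            nB = tot_n - nA
            ok = (nA >= 1) & (nB >= 1)
            nA = np.where(ok, nA, np.nan)
            cA = Z @ X
            hA = Z @ H
            cB = tot_counts[None, :] - cA
            hB = tot_hets[None, :] - hA
            nsum = nA + nB
            nbar = nsum / 2
            with np.errstate(invalid="ignore", divide="ignore"):
                nc = nsum - (nA**2 + nB**2) / nsum
                pA = cA / (2 * nA[:, None])
                pB = cB / (2 * nB[:, None])
                pbar = (cA + cB) / (2 * nsum[:, None])
                s2 = (
                    nA[:, None] * (pA - pbar) ** 2 + nB[:, None] * (pB - pbar) ** 2
                ) / nbar[:, None]
                hbar = (hA + hB) / nsum[:, None]
                aa = (nbar / nc)[:, None] * (
                    s2
                    - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)[:, None]
                )
                bb = (nbar / (nbar - 1))[:, None] * (
                    pbar * (1 - pbar)
                    - s2 / 2
                    - ((2 * nbar - 1) / (4 * nbar))[:, None] * hbar
                )
                cc = hbar / 2
            contrib_a = np.nan_to_num(aa.sum(axis=1))
            contrib_d = np.nan_to_num((aa + bb + cc).sum(axis=1))
            usable = ok & (nbar > 1)
            num += np.where(usable, contrib_a, 0.0)
            den += np.where(usable, contrib_d, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            thetas[done : done + nb] = num / den
        done += nb
    return thetas


def permutation_test(
    gm: GenotypeMatrix,
    scheme: str,
    B: int = 10000,
    seed=None,
    pop: str | None = None,
    pops: tuple[str, str] | None = None,
    rng=None,
):
    """One-sided permutation test; returns (observed statistic, p-value).

    scheme='fis': alleles permuted among individuals within `pop`, testing an
    excess of homozygotes (f > 0). scheme='theta': multilocus genotypes
    permuted between the two `pops`, testing theta > 0. The p-value is
    (#{perm >= obs} + 1) / (B + 1), never exactly zero.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if scheme == "fis":
        if pop is None:
            raise ValueError("scheme 'fis' needs pop=")
        obs = multilocus_fis(gm, pop)
        perms = _fis_perm_stats(gm, pop, B, rng)
    elif scheme == "theta":
        if pops is None:
            raise ValueError("scheme 'theta' needs pops=(a, b)")
        obs = pairwise_theta(gm, *pops)
        perms = _theta_perm_stats(gm, pops[0], pops[1], B, rng)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if np.isnan(obs):
        return obs, float("nan")
    k = int(np.sum(perms[~np.isnan(perms)] >= obs))
    return obs, (k + 1) / (B + 1)


def adjusted_nominal_level(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted nominal significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------


def _rarefaction_sizes(gm: GenotypeMatrix) -> dict[int, int]:
    """Per locus: smallest per-population non-missing gene-copy count (>=2)."""
    sizes = {}
    for l in range(gm.n_loci):
        counts = []
        for pop in gm.populations:
            c = _pop_locus_calls(gm, pop, l)
            if c.shape[0] > 0:
                counts.append(2 * c.shape[0])
        g = min(counts) if counts else 0
        if g >= 2:
            sizes[l] = g
    return sizes


def diversity_table(
    gm: GenotypeMatrix,
    B: int = 10000,
    alpha: float = 0.05,
    n_tests: int | None = None,
    seed=None,
) -> pd.DataFrame:
    """Per-population diversity summary (one row per population).

    Columns: N, H_exp, H_obs, allelic_richness, n_alleles, F_is, p_Fis,
    significant. Heterozygosities, richness and allele counts are unweighted
    means over informative loci; F_is is the multi-locus ratio of sums; the
    significance flag applies the Bonferroni level alpha/n_tests (default
    n_tests = number of populations).
    """
    rng = np.random.default_rng(seed)
    pops = gm.populations
    if n_tests is None:
        n_tests = len(pops)
    alpha_adj = adjusted_nominal_level(alpha, n_tests)
    g_of = _rarefaction_sizes(gm)
    rows = []
    for pop in pops:
        hexp, hobs, rich, nall = [], [], [], []
        for l in range(gm.n_loci):
            c = _pop_locus_calls(gm, pop, l)
            if c.shape[0] < 2:
                continue
            hobs.append(observed_heterozygosity(gm, pop, l))
            hexp.append(unbiased_expected_heterozygosity(gm, pop, l))
            nall.append(n_alleles(gm, pop, l))
            if l in g_of and g_of[l] <= 2 * c.shape[0]:
                rich.append(allelic_richness(gm, pop, l, g_of[l]))
        f, p = permutation_test(gm, "fis", B=B, pop=pop, rng=rng)
        rows.append(
            {
                "pop": pop,
                "N": int(gm.pop_mask(pop).sum()),
                "H_exp": float(np.mean(hexp)) if hexp else np.nan,
                "H_obs": float(np.mean(hobs)) if hobs else np.nan,
                "allelic_richness": float(np.mean(rich)) if rich else np.nan,
                "n_alleles": float(np.mean(nall)) if nall else np.nan,
                "F_is": f,
                "p_Fis": p,
                "significant": bool(p < alpha_adj) if np.isfinite(p) else False,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha_adjusted"] = alpha_adj
    return df


@dataclass
class FstMatrix:
    """Pairwise theta with permutation p-values and a Bonferroni mask."""

    theta: pd.DataFrame
    pvalues: pd.DataFrame
    alpha_adjusted: float

    @property
    def significant(self) -> pd.DataFrame:
        mask = self.pvalues < self.alpha_adjusted
        np.fill_diagonal(mask.values, False)
        return mask

    def to_tsv(self, path) -> None:
        """Lower-triangular layout, significant values marked with '*'."""
        pops = list(self.theta.index)
        with open(path, "w") as fh:
            fh.write("pop\t" + "\t".join(pops[:-1]) + "\n")
            for i, p in enumerate(pops):
                cells = []
                for j in range(len(pops) - 1):
                    if j < i:
                        v = self.theta.iloc[i, j]
                        star = "*" if self.significant.iloc[i, j] else ""
                        cells.append(f"{v:.4f}{star}")
                    elif j == i:
                        cells.append("0")
                    else:
                        cells.append("")
                fh.write(p + "\t" + "\t".join(cells) + "\n")


def fst_matrix(
    gm: GenotypeMatrix,
    B: int = 10000,
    alpha: float = 0.05,
    seed=None,
) -> FstMatrix:
    """All pairwise theta values with permutation p-values (Table-2 shape)."""
    rng = np.random.default_rng(seed)
    pops = gm.populations
    k = len(pops)
    n_tests = k * (k - 1) // 2
    theta = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            t, p = permutation_test(gm, "theta", B=B, pops=(pops[i], pops[j]), rng=rng)
            theta[i, j] = theta[j, i] = t
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(pops, name="pop")
    return FstMatrix(
        theta=pd.DataFrame(theta, index=idx, columns=idx),
        pvalues=pd.DataFrame(pval, index=idx, columns=idx),
        alpha_adjusted=adjusted_nominal_level(alpha, n_tests),
    )
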