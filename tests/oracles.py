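"""Independent brute-force oracles used only by the test suite.

These are deliberately naive transcriptions (scalar loops, exhaustive
enumeration) kept separate from the package's vectorized implementations.
"""

from itertools import combinations

import numpy as np


def wc_components_oracle(genotypes_by_pop):
    """Weir-Cockerham (1984) per-allele variance components, scalar loops.

    genotypes_by_pop: list of (n_i, 2) integer arrays, one per population,
    no missing data. Returns (a, b, c) summed over alleles.
    """
    pops = [np.asarray(g) for g in genotypes_by_pop if len(g) > 0]
    r = len(pops)
    alleles = sorted(set(int(x) for g in pops for x in np.ravel(g)))
    n = [len(g) for g in pops]
    nbar = sum(n) / r
    nsum = sum(n)
    nc = (nsum - sum(ni**2 for ni in n) / nsum) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p = []
        h = []
        for g in pops:
            cnt = sum(1 for row in g for x in row if int(x) == al)
            het = sum(1 for row in g if row[0] != row[1] and al in (row[0], row[1]))
            p.append(cnt / (2 * len(g)))
            h.append(het / len(g))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def fis_components_oracle(genotypes):
    """Single-population (b, c) components, scalar loops, no missing data."""
    g = np.asarray(genotypes)
    n = len(g)
    alleles = sorted(set(int(x) for x in g.ravel()))
    B = C = 0.0
    for al in alleles:
        cnt = sum(1 for row in g for x in row if int(x) == al)
        het = sum(1 for row in g if row[0] != row[1] and al in (row[0], row[1]))
        p = cnt / (2 * n)
        hbar = het / n
        B += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        C += hbar / 2
    return B, C


def hexp_pair_counting_oracle(genotypes):
    """Unbiased gene diversity as 1 - (identical pairs / all gene-copy pairs)."""
    copies = [int(x) for row in genotypes for x in row]
    m = len(copies)
    same = sum(1 for i, j in combinations(range(m), 2) if copies[i] == copies[j])
    total = m * (m - 1) // 2
    return 1.0 - same / total


def richness_enumeration_oracle(copies, g):
    """Expected distinct alleles over all size-g subsets of the gene copies."""
    copies = list(copies)
    sets = [len({copies[i] for i in sub}) for sub in combinations(range(len(copies)), g)]
    return sum(sets) / len(sets)


def mlg_partition_oracle(calls, missing=-1):
    """All-pairs exact-match MLG partition, O(N^2)."""
    n = calls.shape[0]
    labels = [-1] * n
    nxt = 0
    for i in range(n):
        for j in range(i):
            if np.array_equal(calls[i], calls[j]):
                labels[i] = labels[j]
                break
        else:
            labels[i] = nxt
            nxt += 1
    return labels


def single_linkage_components_oracle(dist, threshold):
    """Connected components of the threshold graph via BFS."""
    n = dist.shape[0]
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in range(n):
                if comp[v] < 0 and dist[u, v] <= threshold:
                    comp[v] = c
                    stack.append(v)
        c += 1
    return comp


def ca_row_coordinates_oracle(X, k):
    """CA row principal coordinates via the reciprocal-averaging eigenproblem.

    Independent route: eigendecomposition of the row-profile transition
    operator D_r^{-1} P D_c^{-1} P^T instead of an SVD of residuals.
    """
    X = np.asarray(X, dtype=float)
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    T = np.diag(1 / r) @ P @ np.diag(1 / c) @ P.T
    w, V = np.linalg.eig(T)
    order = np.argsort(-np.real(w))
    w = np.real(w[order])
    V = np.real(V[:, order])
    # drop the trivial eigenvalue 1 / constant vector
    keep = [i for i in range(len(w)) if not np.isclose(w[i], 1.0)][:k]
    coords = []
    for i in keep:
        v = V[:, i]
        # normalize to principal coordinates: sum r v^2 = eigenvalue
        scale = np.sqrt(w[i] / np.sum(r * v**2))
        coords.append(v * scale)
    return np.column_stack(coords), w[keep]
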