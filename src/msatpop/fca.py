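"""Factorial correspondence analysis of individuals coded by allele counts.

Individuals are coded 0/1/2 on one column per (locus, allele) — the classic
GENETIX-style coding — and ordinated by simple correspondence analysis of
that count table. Population centroids of the individual scores summarise
between-group structure on the leading axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def allele_count_coding(gm: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x (locus:allele) table of allele copy counts (0/1/2).

    A locus missing in an individual contributes zeros across that locus's
    columns; the mask of missing (individual, locus) cells is stored in
    df.attrs['missing_mask'].
    """
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for l, locus in enumerate(gm.loci):
        calls = gm.calls[:, l]
        valid = calls[:, 0] != MISSING
        alleles = np.unique(calls[valid].ravel())
        X = np.zeros((gm.n_samples, alleles.size), dtype=np.int64)
        aidx = {a: j for j, a in enumerate(alleles)}
        for i in np.flatnonzero(valid):
            X[i, aidx[calls[i, 0]]] += 1
            X[i, aidx[calls[i, 1]]] += 1
        blocks.append(X)
        cols.extend(f"{locus}:{a}" for a in alleles)
    df = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gm.sample_ids, name="sample"), columns=cols
    )
    df.attrs["missing_mask"] = gm.missing_mask()
    df.attrs["pop_labels"] = list(gm.pop_labels)
    return df


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # individuals x axes (principal coordinates)
    column_coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_inertia: np.ndarray
    row_masses: np.ndarray

    def to_tsv(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t")


def correspondence_analysis(table: pd.DataFrame, k_axes: int = 3) -> OrdinationResult:
    """Simple CA of a non-negative count table.

    Standard chain: relative frequencies P, row/column masses r, c, matrix of
    standardized (Pearson) residuals S = D_r^{-1/2} (P - r c') D_c^{-1/2},
    SVD of S, principal coordinates F = D_r^{-1/2} U Sigma. Eigenvalues are
    the squared singular values; axes are sign-canonicalized so the
    largest-magnitude column loading on each axis is positive. Zero-mass rows
    (all-missing individuals) get zero coordinates.
    """
    X = np.asarray(table, dtype=float)
    if (X < 0).any():
        raise ValueError("table must be non-negative")
    total = X.sum()
    if total <= 0:
        raise ValueError("table has zero grand total")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_c = c > 0
    if not keep_c.any():
        raise ValueError("no informative columns")
    sr = np.where(r > 0, np.sqrt(r), 1.0)
    sc = np.sqrt(c[keep_c])
    S = (P[:, keep_c] - np.outer(r, c[keep_c])) / sr[:, None] / sc[None, :]
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv.size == 0 or sv[0] < 1e-12:
        raise ValueError("constant table: zero inertia")
    k = min(k_axes, int((sv > 1e-12).sum()))
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
    F = (U * sv[None, :]) / sr[:, None]
    F[r == 0] = 0.0
    G = (Vt.T * sv[None, :]) / sc[:, None]
    # canonical signs: largest-|column loading| positive per axis
    for a in range(k):
        j = np.argmax(np.abs(G[:, a]))
        if G[j, a] < 0:
            G[:, a] *= -1
            F[:, a] *= -1
    eig = sv**2
    total_inertia = (S**2).sum()
    axes = [f"axis{a+1}" for a in range(k)]
    coords = pd.DataFrame(F, index=table.index, columns=axes)
    colcoords = pd.DataFrame(G, index=table.columns[keep_c], columns=axes)
    return OrdinationResult(
        coordinates=coords,
        column_coordinates=colcoords,
        eigenvalues=eig,
        percent_inertia=100 * eig / total_inertia,
        row_masses=r,
    )


def population_centroids(
    res: OrdinationResult, pop_labels: list[str]
) -> pd.DataFrame:
    """Mass-weighted mean individual coordinates per population."""
    labels = np.asarray(pop_labels)
    if labels.shape[0] != res.coordinates.shape[0]:
        raise ValueError("one label per individual required")
    out = {}
    F = res.coordinates.to_numpy()
    w = res.row_masses
    for pop in dict.fromkeys(pop_labels):
        m = labels == pop
        wm = w[m]
        if wm.sum() == 0:
            out[pop] = np.zeros(F.shape[1])
        else:
            out[pop] = (F[m] * wm[:, None]).sum(axis=0) / wm.sum()
    return pd.DataFrame(out, index=res.coordinates.columns).T.rename_axis("pop")


def plot_ordination(res: OrdinationResult, pop_labels, path) -> None:
    """Scatter of axes 1-2 colored by population (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    F = res.coordinates
    labels = np.asarray(pop_labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in dict.fromkeys(pop_labels):
        m = labels == pop
        ax.scatter(F.iloc[m, 0], F.iloc[m, 1], s=12, label=pop, alpha=0.7)
    cent = population_centroids(res, list(pop_labels))
    ax.scatter(cent.iloc[:, 0], cent.iloc[:, 1], marker="x", c="k", s=60)
    ax.set_xlabel(f"axis 1 ({res.percent_inertia[0]:.1f}%)")
    ax.set_ylabel(f"axis 2 ({res.percent_inertia[1]:.1f}%)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
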