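"""Coalescent simulation of diploid microsatellite genotypes.

Genealogies are simulated with msprime (continuous-time Kingman coalescent;
pair-coalescence rate k(k-1)/(4Ne) per generation for diploid Ne) under a
DemographicScenario. Mutations follow the generalized stepwise model (GSM):
per branch a Poisson(mu * length) number of mutations, each stepping the
repeat number by +-k with k geometric(P) (P=0 recovers the strict one-step
SMM), symmetric in direction and reflected at the allele-ladder bounds. The
ancestral state sits at the ladder midpoint. Per-locus mutation rates are
drawn around the mean rate from a Gamma with shape 2 (locus heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
from numba import njit

from .genotype_io import GenotypeMatrix
from .scenario import DemographicScenario

#: default bounded allele ladder: 200 contiguous repeat states
DEFAULT_LADDER = (0, 199)
#: affine offset mapping ladder state -> positive genepop-safe allele code
ALLELE_OFFSET = 1


@dataclass
class SimConfig:
    """Sampling layout and mutation-model priors for simulated datasets."""

    sample_sizes: dict[str, int]  # deme -> diploid individuals
    n_loci: int = 18
    mu_mean_low: float = 1e-4  # log-uniform prior on the mean rate
    mu_mean_high: float = 1e-3
    gsm_p_low: float = 0.0  # uniform prior on the GSM geometric parameter
    gsm_p_high: float = 0.3
    mu_shape: float = 2.0  # Gamma shape of across-locus rate heterogeneity
    ladder: tuple[int, int] = DEFAULT_LADDER

    def __post_init__(self):
        if any(s < 1 for s in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")
        if not (0 < self.mu_mean_low <= self.mu_mean_high < 1):
            raise ValueError("mutation rate prior must sit inside (0, 1)")
        if not (0 <= self.gsm_p_low <= self.gsm_p_high < 1):
            raise ValueError("GSM parameter P must sit inside [0, 1)")
        if self.ladder[1] - self.ladder[0] < 1:
            raise ValueError("allele ladder needs >= 2 states")

    def draw_mutation_params(self, rng: np.random.Generator):
        """One (mu_mean, P, per-locus mu vector) draw from the priors."""
        mu_mean = np.exp(
            rng.uniform(np.log(self.mu_mean_low), np.log(self.mu_mean_high))
        )
        p = rng.uniform(self.gsm_p_low, self.gsm_p_high)
        mu_locus = rng.gamma(self.mu_shape, mu_mean / self.mu_shape, self.n_loci)
        return mu_mean, p, mu_locus


@dataclass
class SimulatedDataset:
    gm: GenotypeMatrix
    params: dict[str, float]
    mu_locus: np.ndarray
    gsm_p: float
    tmrca: np.ndarray | None = None
    total_branch_length: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------


def simulate_genealogy(
    scn: DemographicScenario,
    params: dict[str, float],
    sizes: dict[str, int],
    seed: int,
    num_loci: int = 1,
):
    """Independent single-tree TreeSequences, one per locus.

    Branch lengths are in generations; trees are ultrametric with all sampled
    lineages coalescing into one root (possibly in the ancestral deme).
    """
    dem = scn.to_demography(params)
    reps = msprime.sim_ancestry(
        samples=sizes,
        demography=dem,
        ploidy=2,
        num_replicates=num_loci,
        random_seed=int(seed) % (2**32 - 1) + 1,
    )
    return list(reps)


def _tree_arrays(ts):
    """(order, parent, branch_length) for a single-tree TreeSequence."""
    tables = ts.tables
    time = tables.nodes.time
    parent = np.full(ts.num_nodes, -1, dtype=np.int64)
    parent[tables.edges.child] = tables.edges.parent
    blen = np.where(parent >= 0, time[parent] - time, 0.0)
    order = np.argsort(-time, kind="stable")
    return order, parent, blen


@njit(cache=True)
def _gsm_kernel(order, parent, blen, mu, p, lo, hi, mid, seed):  # pragma: no cover
    np.random.seed(seed)
    n = order.shape[0]
    state = np.empty(n, dtype=np.int64)
    log_p = np.log(p) if p > 0.0 else 0.0
    for ii in range(n):
        u = order[ii]
        par = parent[u]
        if par < 0:
            state[u] = mid
            continue
        s = state[par]
        m = np.random.poisson(mu * blen[u])
        for _ in range(m):
            if p <= 0.0:
                k = 1
            else:
                k = 1 + int(np.floor(np.log(np.random.random()) / log_p))
            if np.random.random() < 0.5:
                k = -k
            s += k
            while s < lo or s > hi:
                if s < lo:
                    s = 2 * lo - s
                else:
                    s = 2 * hi - s
        state[u] = s
    return state


def mutate_gsm(ts, mu: float, p: float, ladder=DEFAULT_LADDER, seed: int = 1):
    """GSM mutation of one genealogy; returns the repeat state per sample node.

    mu is the per-locus per-generation mutation rate; p the geometric step
    parameter (p=0: strict SMM). The ancestral state is the ladder midpoint
    and steps reflect at the bounds.
    """
    lo, hi = int(ladder[0]), int(ladder[1])
    if hi - lo < 1:
        raise ValueError("allele ladder needs >= 2 states")
    order, parent, blen = _tree_arrays(ts)
    mid = (lo + hi) // 2
    state = _gsm_kernel(
        order, parent, blen, float(mu), float(p), lo, hi, mid, int(seed) % (2**31 - 1)
    )
    return state[ts.samples()]


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------


def _sample_layout(ts):
    """(node pairs, pop code per individual) for the diploid sample nodes."""
    node_individual = ts.tables.nodes.individual
    node_pop = ts.tables.nodes.population
    pairs: dict[int, list[int]] = {}
    for u in ts.samples():
        pairs.setdefault(int(node_individual[u]), []).append(int(u))
    ind_ids = sorted(pairs)
    nodes = np.array([pairs[i] for i in ind_ids])
    pop_codes = np.array([node_pop[pairs[i][0]] for i in ind_ids])
    return nodes, pop_codes


def simulate_allele_matrix(
    scn: DemographicScenario,
    params: dict[str, float],
    sizes: dict[str, int],
    n_loci: int,
    mu_locus: np.ndarray,
    gsm_p: float,
    ladder=DEFAULT_LADDER,
    seed: int = 1,
    collect_genealogy_stats: bool = False,
):
    """Fast path: (alleles (N, L, 2) int, pop codes, deme names[, tree stats]).

    Allele values are ladder states shifted by ALLELE_OFFSET so they are
    positive integers suitable for genepop encoding.
    """
    rng = np.random.default_rng(seed)
    ts_list = simulate_genealogy(
        scn, params, sizes, seed=int(rng.integers(1, 2**31 - 1)), num_loci=n_loci
    )
    first = ts_list[0]
    nodes, pop_codes = _sample_layout(first)
    n_ind = nodes.shape[0]
    alleles = np.empty((n_ind, n_loci, 2), dtype=np.int32)
    tmrca = np.empty(n_loci) if collect_genealogy_stats else None
    tbl = np.empty(n_loci) if collect_genealogy_stats else None
    for l, ts in enumerate(ts_list):
        states = mutate_gsm(
            ts,
            mu=float(mu_locus[l]),
            p=gsm_p,
            ladder=ladder,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        by_node = np.full(ts.num_nodes, -1, dtype=np.int64)
        by_node[ts.samples()] = states
        alleles[:, l, 0] = by_node[nodes[:, 0]]
        alleles[:, l, 1] = by_node[nodes[:, 1]]
        if collect_genealogy_stats:
            tree = ts.first()
            tmrca[l] = tree.time(tree.root)
            tbl[l] = tree.total_branch_length
    alleles += ALLELE_OFFSET
    code_to_name = {
        int(c): first.population(int(c)).metadata.get("name", str(c))
        for c in np.unique(pop_codes)
    }
    out = (alleles, pop_codes, code_to_name)
    if collect_genealogy_stats:
        out = out + (tmrca, tbl)
    return out


def simulate_dataset(
    scn: DemographicScenario,
    params: dict[str, float],
    simcfg: SimConfig,
    seed: int,
    mu_locus: np.ndarray | None = None,
    gsm_p: float | None = None,
) -> SimulatedDataset:
    """Simulate one diploid microsatellite dataset under a scenario draw.

    Mutation parameters are drawn from the SimConfig priors unless given
    explicitly. Gene copies are paired into diploids within demes by msprime's
    individual assignment (random with respect to the pedigree).
    """
    rng = np.random.default_rng(seed)
    if mu_locus is None or gsm_p is None:
        _, p_draw, mu_draw = simcfg.draw_mutation_params(rng)
        mu_locus = mu_draw if mu_locus is None else mu_locus
        gsm_p = p_draw if gsm_p is None else gsm_p
    alleles, pop_codes, code_to_name, tmrca, tbl = simulate_allele_matrix(
        scn,
        params,
        simcfg.sample_sizes,
        simcfg.n_loci,
        mu_locus,
        gsm_p,
        ladder=simcfg.ladder,
        seed=int(rng.integers(1, 2**31 - 1)),
        collect_genealogy_stats=True,
    )
    labels = [code_to_name[int(c)] for c in pop_codes]
    gm = GenotypeMatrix(
        sample_ids=[f"{lab}_{i:04d}" for i, lab in enumerate(labels)],
        pop_labels=labels,
        loci=[f"L{l+1:02d}" for l in range(simcfg.n_loci)],
        calls=alleles,
    )
    return SimulatedDataset(
        gm=gm,
        params=dict(params),
        mu_locus=np.asarray(mu_locus),
        gsm_p=float(gsm_p),
        tmrca=tmrca,
        total_branch_length=tbl,
    )
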