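"""Approximate Bayesian computation over divergence scenarios.

The reference table holds (scenario id, parameter draw, summary statistics)
triples simulated from the priors. Observed data is summarised by the same
fixed panel — per deme the mean number of alleles per locus and mean unbiased
gene diversity, per deme pair the multilocus Weir-Cockerham theta — and
compared to the table by Euclidean distance on MAD-standardized statistics.

Scenario choice uses the scenario composition of the closest simulations
(direct estimate) and a weighted multinomial logistic regression of scenario
id on statistic deviations evaluated at deviation zero. Parameter posteriors
use the Beaumont local-linear regression adjustment on logit-transformed
parameters with Epanechnikov weights; point summaries are the weighted KDE
mode, weighted median and central 95% interval. A posterior predictive check
re-simulates data from the fitted posterior and reports two-sided tail
probabilities per statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gaussian_kde, median_abs_deviation

from .genotype_io import MISSING, GenotypeMatrix
from .popstats import wc_pair_from_counts
from .scenario import DemographicScenario
from .simulate import SimConfig, simulate_allele_matrix

__all__ = [
    "SummaryStats",
    "ReferenceTable",
    "Retained",
    "ABCResult",
    "summarize",
    "summarize_alleles",
    "build_reference_table",
    "rejection",
    "model_posterior_direct",
    "model_posterior_logistic",
    "parameter_posterior",
    "posterior_predictive_check",
    "abc_analysis",
]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Fixed-order summary statistic vector with an informativeness mask."""

    names: list[str]
    values: np.ndarray
    mask: np.ndarray  # True where the statistic was computable

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def stat_names(demes: list[str]) -> list[str]:
    names = [f"na_{d}" for d in demes]
    names += [f"hd_{d}" for d in demes]
    for i in range(len(demes)):
        for j in range(i + 1, len(demes)):
            names.append(f"fst_{demes[i]}_{demes[j]}")
    return names


def summarize_alleles(
    alleles: np.ndarray, pop_codes: np.ndarray, demes: list[str] | None = None
) -> SummaryStats:
    """Summary panel from an (n, L, 2) allele array and integer deme codes.

    Demes are indexed by sorted unique code unless `demes` names are given
    (then len(demes) must equal the number of distinct codes, in code order).
    """
    alleles = np.asarray(alleles)
    codes = np.unique(pop_codes)
    k = codes.size
    if demes is None:
        demes = [str(c) for c in codes]
    names = stat_names(list(demes))
    L = alleles.shape[1]
    n_all = np.zeros((k, L))
    h_div = np.full((k, L), np.nan)
    theta_num = np.zeros((k, k))
    theta_den = np.zeros((k, k))
    members = [np.flatnonzero(pop_codes == c) for c in codes]
    for l in range(L):
        col = alleles[:, l, :]
        valid = col[:, 0] != MISSING
        uniq = np.unique(col[valid].ravel())
        aidx = np.searchsorted(uniq, col)
        counts = np.zeros((k, uniq.size))
        hets = np.zeros((k, uniq.size))
        n_ind = np.zeros(k)
        for d in range(k):
            m = members[d][valid[members[d]]]
            n_ind[d] = m.size
            if m.size == 0:
                continue
            counts[d] = np.bincount(aidx[m].ravel(), minlength=uniq.size)
            het = col[m, 0] != col[m, 1]
            if het.any():
                hets[d] = np.bincount(
                    aidx[m[het]].ravel(), minlength=uniq.size
                )
            n_all[d, l] = np.count_nonzero(counts[d])
            n = n_ind[d]
            if n >= 2:
                p = counts[d] / (2 * n)
                h_div[d, l] = 2 * n / (2 * n - 1) * (1 - (p**2).sum())
        for i in range(k):
            for j in range(i + 1, k):
                res = wc_pair_from_counts(
                    n_ind[i], counts[i], hets[i], n_ind[j], counts[j], hets[j]
                )
                if res is not None:
                    theta_num[i, j] += res[0]
                    theta_den[i, j] += res[1]
    values = []
    mask = []
    for d in range(k):
        v = n_all[d][n_all[d] > 0]
        values.append(v.mean() if v.size else 0.0)
        mask.append(v.size > 0)
    for d in range(k):
        v = h_div[d][np.isfinite(h_div[d])]
        values.append(v.mean() if v.size else 0.0)
        mask.append(v.size > 0)
    for i in range(k):
        for j in range(i + 1, k):
            if theta_den[i, j] > 0:
                values.append(theta_num[i, j] / theta_den[i, j])
                mask.append(True)
            else:
                values.append(0.0)
                mask.append(False)
    return SummaryStats(names, np.array(values), np.array(mask))


def summarize(gm: GenotypeMatrix, demes: list[str] | None = None) -> SummaryStats:
    """Summary panel from a GenotypeMatrix pooled to demes.

    Deme order follows first appearance in the matrix unless given.
    """
    if demes is None:
        demes = gm.populations
    if len(demes) < 2:
        raise ValueError("need >= 2 demes for the summary panel")
    code_of = {d: i for i, d in enumerate(demes)}
    codes = np.array([code_of[p] for p in gm.pop_labels])
    return summarize_alleles(gm.calls, codes, demes=demes)


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray  # (M,) str
    params: pd.DataFrame  # (M, n_params) NaN where a scenario lacks a param
    stats: np.ndarray  # (M, S)
    stat_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return int(self.stats.shape[0])

    def save(self, path) -> None:
        """Single TSV with a JSON header line (prefixed '#')."""
        with open(path, "w") as fh:
            fh.write("#" + json.dumps({"stat_names": self.stat_names, **self.meta}))
            fh.write("\n")
            df = self.params.copy()
            df.insert(0, "scenario", self.scenario_ids)
            for i, s in enumerate(self.stat_names):
                df[s] = self.stats[:, i]
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            df = pd.read_csv(fh, sep="\t")
        stat_cols = header.pop("stat_names")
        scen = df.pop("scenario").to_numpy(dtype=str)
        stats = df[stat_cols].to_numpy()
        params = df.drop(columns=stat_cols)
        return cls(scen, params, stats, stat_cols, meta=header)


def _concat_tables(tables: list[ReferenceTable]) -> ReferenceTable:
    first = tables[0]
    return ReferenceTable(
        scenario_ids=np.concatenate([t.scenario_ids for t in tables]),
        params=pd.concat([t.params for t in tables], ignore_index=True),
        stats=np.vstack([t.stats for t in tables]),
        stat_names=first.stat_names,
        meta=first.meta,
    )


def _draw_one_prior(scn: DemographicScenario, rng) -> dict[str, float]:
    for _ in range(10000):
        draw = {p: float(spec.sample(1, rng)[0]) for p, spec in scn.priors.items()}
        if all(draw[a] < draw[b] for a, b in scn.constraints):
            return draw
    raise RuntimeError("prior rejection did not terminate")


def build_reference_table(
    scenarios: dict[str, DemographicScenario],
    simcfg: SimConfig,
    n_per_scenario: int,
    seed: int,
    rows: tuple[int, int] | None = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate the (scenario, parameters, statistics) reference table.

    Row seeds derive from (seed, scenario index, row index), so building the
    table in batches via `rows=(start, stop)` and concatenating reproduces the
    one-shot table bit for bit.
    """
    demes = [d for d, n in simcfg.sample_sizes.items() if n > 0]
    names = stat_names(demes)
    lo, hi = rows if rows is not None else (0, n_per_scenario)
    scen_col, stat_rows, param_rows = [], [], []
    for s_idx, (s_name, scn) in enumerate(scenarios.items()):
        children = np.random.SeedSequence([int(seed), s_idx]).spawn(n_per_scenario)
        for r in range(lo, hi):
            rng = np.random.default_rng(children[r])
            params = _draw_one_prior(scn, rng)
            mu_mean, gsm_p, mu_locus = simcfg.draw_mutation_params(rng)
            alleles, codes, _ = simulate_allele_matrix(
                scn,
                params,
                simcfg.sample_sizes,
                simcfg.n_loci,
                mu_locus,
                gsm_p,
                ladder=simcfg.ladder,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            ss = summarize_alleles(alleles, codes, demes=demes)
            scen_col.append(s_name)
            stat_rows.append(ss.values)
            param_rows.append({**params, "mu_mean": mu_mean, "gsm_p": gsm_p})
            if progress and (r + 1) % 1000 == 0:
                print(f"  {s_name}: {r + 1}/{n_per_scenario}", flush=True)
    meta = {
        "seed": int(seed),
        "sizes": {d: int(n) for d, n in simcfg.sample_sizes.items()},
        "n_loci": int(simcfg.n_loci),
        "scenario_priors": {
            name: {p: [spec.low, spec.high] for p, spec in scn.priors.items()}
            for name, scn in scenarios.items()
        },
        "mutation_priors": {
            "mu_mean": [simcfg.mu_mean_low, simcfg.mu_mean_high],
            "gsm_p": [simcfg.gsm_p_low, simcfg.gsm_p_high],
        },
    }
    return ReferenceTable(
        scenario_ids=np.array(scen_col),
        params=pd.DataFrame(param_rows),
        stats=np.array(stat_rows),
        stat_names=names,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# rejection and model choice
# ---------------------------------------------------------------------------


@dataclass
class Retained:
    ref: ReferenceTable
    indices: np.ndarray
    distances: np.ndarray
    scale: np.ndarray  # per-stat MAD across the table (0 = excluded)
    observed: np.ndarray

    @property
    def scenario_ids(self) -> np.ndarray:
        return self.ref.scenario_ids[self.indices]

    def std_deviations(self) -> np.ndarray:
        """Standardized stat deviations of retained rows from the observed."""
        use = self.scale > 0
        dev = self.ref.stats[self.indices][:, use] - self.observed[use]
        return dev / self.scale[use]

    def weights(self) -> np.ndarray:
        """Epanechnikov weights on the retained distances."""
        dmax = self.distances.max()
        if dmax <= 0:
            return np.ones_like(self.distances)
        return 1.0 - (self.distances / dmax) ** 2


def rejection(
    ref: ReferenceTable, observed: SummaryStats | np.ndarray, retain_fraction: float
) -> Retained:
    """Keep the ceil(fraction * rows) rows closest to the observed vector.

    Distance is Euclidean over statistics standardized by their median
    absolute deviation across the table; zero-MAD statistics (and, when an
    observed mask is available, uninformative observed statistics) are
    excluded from the distance.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    obs = observed.values if isinstance(observed, SummaryStats) else np.asarray(observed)
    scale = median_abs_deviation(ref.stats, axis=0)
    if isinstance(observed, SummaryStats):
        scale = np.where(observed.mask, scale, 0.0)
    use = scale > 0
    if not use.any():
        raise ValueError("no informative statistics to compare")
    dev = (ref.stats[:, use] - obs[use]) / scale[use]
    dist = np.sqrt((dev**2).sum(axis=1))
    n_keep = int(np.ceil(retain_fraction * ref.n_rows))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return Retained(ref, order, dist[order], scale, obs)


def model_posterior_direct(retained: Retained, n_delta: int = 500) -> pd.Series:
    """Scenario frequencies among the n_delta closest retained rows."""
    ids = retained.scenario_ids[:n_delta]
    all_ids = list(dict.fromkeys(retained.ref.scenario_ids))
    freq = pd.Series(0.0, index=all_ids)
    vc = pd.Series(ids).value_counts(normalize=True)
    freq[vc.index] = vc.values
    return freq


def model_posterior_logistic(
    retained: Retained, observed=None, ridge: float = 1e-6
) -> tuple[pd.Series, bool]:
    """Multinomial logistic scenario probabilities at deviation zero.

    Regresses scenario id on the standardized stat deviations of the retained
    rows (Epanechnikov-weighted, ridge-regularized) and evaluates the fitted
    class probabilities at the observed point (deviation 0). Returns
    (probabilities, degenerate_flag); with a single scenario among the
    retained the direct estimate is returned with the flag set.
    """
    from sklearn.linear_model import LogisticRegression

    ids = retained.scenario_ids
    all_ids = list(dict.fromkeys(retained.ref.scenario_ids))
    if np.unique(ids).size < 2:
        warnings.warn("all retained rows from one scenario; logistic degenerate")
        return model_posterior_direct(retained, n_delta=len(ids)), True
    X = retained.std_deviations()
    clf = LogisticRegression(C=1.0 / ridge, max_iter=2000)
    clf.fit(X, ids, sample_weight=retained.weights())
    probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
    out = pd.Series(0.0, index=all_ids)
    for cls, p in zip(clf.classes_, probs):
        out[cls] = p
    return out, False


# ---------------------------------------------------------------------------
# parameter posteriors
# ---------------------------------------------------------------------------


def weighted_quantile(values, q, weights) -> np.ndarray:
    """Inverse of the weighted empirical CDF (midpoint convention)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.atleast_1d(q), cw, v)


def _param_bounds(ref: ReferenceTable, scenario: str) -> dict[str, tuple]:
    bounds = dict(ref.meta["scenario_priors"][scenario])
    bounds.update(ref.meta.get("mutation_priors", {}))
    return {p: tuple(map(float, b)) for p, b in bounds.items()}


def parameter_posterior(
    retained: Retained,
    scenario: str,
    parameters: list[str] | None = None,
    min_rows: int = 10,
) -> pd.DataFrame:
    """Local-linear regression-adjusted posterior summaries for one scenario.

    Retained rows of the scenario are weighted by an Epanechnikov kernel on
    their distance; each parameter is mapped to the real line by a logit on
    its prior bounds, regressed on the standardized stat deviations, the
    residual-at-zero draws back-transformed, and summarised by the weighted
    KDE mode, weighted median and central 95% interval. Falls back to the
    unadjusted weighted quantiles when the regression is rank-deficient
    (flagged in df.attrs['adjusted']).
    """
    sel = retained.scenario_ids == scenario
    if sel.sum() < max(min_rows, 2):
        raise ValueError(
            f"only {int(sel.sum())} retained rows for scenario {scenario!r}"
        )
    bounds = _param_bounds(retained.ref, scenario)
    if parameters is None:
        parameters = [
            p
            for p in retained.ref.params.columns
            if p in bounds and retained.ref.params[p].iloc[retained.indices[sel]].notna().all()
        ]
    X = retained.std_deviations()[sel]
    d = retained.distances[sel]
    dmax = retained.distances.max()
    w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
    w = np.maximum(w, 1e-12)
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    rows = []
    adjusted_flags = {}
    for p in parameters:
        lo, hi = bounds[p]
        theta = retained.ref.params[p].to_numpy()[retained.indices[sel]]
        u = np.clip((theta - lo) / (hi - lo), 1e-10, 1 - 1e-10)
        y = logit(u)
        sw = np.sqrt(w)
        beta, _, rank, _ = np.linalg.lstsq(Xc * sw[:, None], y * sw, rcond=None)
        if rank < Xc.shape[1]:
            y_adj = y
            adjusted_flags[p] = False
        else:
            y_adj = y - X @ beta[1:]
            adjusted_flags[p] = True
        theta_adj = lo + (hi - lo) * expit(y_adj)
        med, q_lo, q_hi = weighted_quantile(theta_adj, [0.5, 0.025, 0.975], w)
        rows.append(
            {
                "parameter": p,
                "mode": _weighted_mode(y_adj, w, lo, hi),
                "median": med,
                "q025": q_lo,
                "q975": q_hi,
                "n": int(sel.sum()),
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    df.attrs["adjusted"] = adjusted_flags
    return df


def _weighted_mode(y: np.ndarray, w: np.ndarray, lo: float, hi: float) -> float:
    """Mode of the adjusted draws: weighted KDE argmax on the logit scale."""
    if np.allclose(y, y[0]):
        return lo + (hi - lo) * expit(y[0])
    try:
        kde = gaussian_kde(y, weights=w)
    except np.linalg.LinAlgError:
        return lo + (hi - lo) * expit(weighted_quantile(y, 0.5, w)[0])
    grid = np.linspace(y.min(), y.max(), 512)
    return float(lo + (hi - lo) * expit(grid[np.argmax(kde(grid))]))


# ---------------------------------------------------------------------------
# posterior predictive check
# ---------------------------------------------------------------------------


def posterior_predictive_check(
    scn: DemographicScenario,
    retained: Retained,
    observed: SummaryStats,
    simcfg: SimConfig,
    n_rep: int = 200,
    seed: int = 1,
) -> pd.Series:
    """Two-sided tail probability of each observed statistic under data
    re-simulated from the fitted posterior (retained draws of the scenario,
    Epanechnikov-weighted resampling)."""
    sel = retained.scenario_ids == scn.name
    if not sel.any():
        raise ValueError(f"no retained draws for scenario {scn.name!r}")
    idx = retained.indices[sel]
    w = retained.weights()[sel]
    if idx.size == 1:
        warnings.warn("degenerate posterior: a single retained draw")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    demes = [d for d, n in simcfg.sample_sizes.items() if n > 0]
    pick = rng.choice(idx.size, size=n_rep, p=w)
    sims = np.empty((n_rep, len(retained.ref.stat_names)))
    for r in range(n_rep):
        row = retained.ref.params.iloc[idx[pick[r]]]
        params = {p: float(row[p]) for p in scn.parameter_names}
        mu_locus = rng.gamma(
            simcfg.mu_shape, float(row["mu_mean"]) / simcfg.mu_shape, simcfg.n_loci
        )
        alleles, codes, _ = simulate_allele_matrix(
            scn,
            params,
            simcfg.sample_sizes,
            simcfg.n_loci,
            mu_locus,
            float(row["gsm_p"]),
            ladder=simcfg.ladder,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        sims[r] = summarize_alleles(alleles, codes, demes=demes).values
    p_le = (sims <= observed.values[None, :]).mean(axis=0)
    tail = np.minimum(np.minimum(p_le, 1 - p_le) * 2, 1.0)
    return pd.Series(tail, index=retained.ref.stat_names)


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class ABCResult:
    reference: ReferenceTable
    retained: Retained
    posterior_direct: pd.Series
    posterior_logistic: pd.Series
    logistic_degenerate: bool
    parameter_posteriors: dict[str, pd.DataFrame]
    predictive_pvalues: pd.Series | None = None

    def best_scenario(self, method: str = "logistic") -> str:
        probs = (
            self.posterior_logistic if method == "logistic" else self.posterior_direct
        )
        return str(probs.idxmax())

    def to_json(self) -> str:
        out = {
            "posterior_direct": self.posterior_direct.to_dict(),
            "posterior_logistic": self.posterior_logistic.to_dict(),
            "logistic_degenerate": self.logistic_degenerate,
            "parameters": {
                s: df.reset_index().to_dict("records")
                for s, df in self.parameter_posteriors.items()
            },
        }
        if self.predictive_pvalues is not None:
            out["predictive_pvalues"] = self.predictive_pvalues.to_dict()
        return json.dumps(out, indent=2, default=float)


def abc_analysis(
    observed: SummaryStats,
    scenarios: dict[str, DemographicScenario],
    simcfg: SimConfig,
    n_per_scenario: int = 5000,
    retain_fraction: float = 0.01,
    n_delta: int = 500,
    seed: int = 1,
    reference: ReferenceTable | None = None,
    predictive_reps: int = 0,
) -> ABCResult:
    """Reference table, rejection, model choice and parameter estimation."""
    ref = reference
    if ref is None:
        ref = build_reference_table(scenarios, simcfg, n_per_scenario, seed)
    ret = rejection(ref, observed, retain_fraction)
    direct = model_posterior_direct(ret, n_delta=n_delta)
    logistic, degen = model_posterior_logistic(ret)
    posts = {}
    for name in scenarios:
        try:
            posts[name] = parameter_posterior(ret, name)
        except ValueError:
            continue
    pred = None
    if predictive_reps > 0:
        best = str(
            (logistic if not degen else direct).idxmax()
        )
        pred = posterior_predictive_check(
            scenarios[best], ret, observed, simcfg, n_rep=predictive_reps,
            seed=seed + 1,
        )
    return ABCResult(
        reference=ref,
        retained=ret,
        posterior_direct=direct,
        posterior_logistic=logistic,
        logistic_degenerate=degen,
        parameter_posteriors=posts,
        predictive_pvalues=pred,
    )
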