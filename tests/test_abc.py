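import numpy as np
import pandas as pd
import pytest

import msatpop as mp
from msatpop import abc as mabc
from msatpop.simulate import SimConfig


@pytest.fixture(scope="module")
def tiny_ref():
    """A small two-scenario reference table shared by the module's tests."""
    scens = {"scenario13": mp.scenario13(), "scenario13_alt": mp.scenario13_alternative()}
    cfg = SimConfig(sample_sizes={"N": 8, "NE": 8, "NW": 8, "CW": 8}, n_loci=6)
    return (
        mabc.build_reference_table(scens, cfg, n_per_scenario=150, seed=99),
        scens,
        cfg,
    )


class TestSummarize:
    def test_panel_size_for_four_demes(self, small_bundle):
        gm = mp.pool_populations(
            small_bundle.clean,
            small_bundle.ledger["meadow_to_deme"],
            drop=["CYP"],
        )
        ss = mabc.summarize(gm)
        assert len(ss.names) == 4 + 4 + 6
        assert ss.values.shape == (14,)
        assert ss.mask.all()

    def test_matches_population_statistics_module(self, small_bundle):
        gm = mp.pool_populations(
            small_bundle.clean, small_bundle.ledger["meadow_to_deme"], drop=["CYP"]
        )
        ss = mabc.summarize(gm).as_series()
        demes = gm.populations
        for i, a in enumerate(demes):
            for b in demes[i + 1:]:
                assert ss[f"fst_{a}_{b}"] == pytest.approx(
                    mp.pairwise_theta(gm, a, b), abs=1e-12
                )
        for d in demes:
            hd = np.mean([
                mp.unbiased_expected_heterozygosity(gm, d, l)
                for l in range(gm.n_loci)
            ])
            assert ss[f"hd_{d}"] == pytest.approx(hd, abs=1e-12)

    def test_identical_demes_near_zero_theta(self, rng):
        calls = rng.integers(1, 6, size=(120, 5, 2)).astype(np.int32)
        codes = np.repeat([0, 1, 2], 40)
        ss = mabc.summarize_alleles(calls, codes).as_series()
        assert max(abs(ss[k]) for k in ss.index if k.startswith("fst")) < 0.03

    def test_idempotent_and_order_stable(self, small_bundle):
        gm = mp.pool_populations(
            small_bundle.clean, small_bundle.ledger["meadow_to_deme"], drop=["CYP"]
        )
        a = mabc.summarize(gm)
        b = mabc.summarize(gm)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)


class TestReferenceTable:
    def test_shape_and_scenario_counts(self, tiny_ref):
        ref, scens, _ = tiny_ref
        assert ref.n_rows == 300
        for s in scens:
            assert (ref.scenario_ids == s).sum() == 150
        assert ref.stats.shape == (300, 14)
        assert {"mu_mean", "gsm_p"} <= set(ref.params.columns)

    def test_batch_resume_equals_one_shot(self, tiny_ref):
        ref, scens, cfg = tiny_ref
        a = mabc.build_reference_table(scens, cfg, 20, seed=99, rows=(0, 12))
        b = mabc.build_reference_table(scens, cfg, 20, seed=99, rows=(12, 20))
        merged = mabc._concat_tables([a, b])
        full = mabc.build_reference_table(scens, cfg, 20, seed=99)
        # same rows regardless of batching, up to ordering
        got = merged.params.sort_index(axis=1)
        want = full.params.sort_index(axis=1)
        reorder = np.lexsort((got["Ne1"].to_numpy(), merged.scenario_ids))
        reorder_f = np.lexsort((want["Ne1"].to_numpy(), full.scenario_ids))
        assert np.allclose(
            got.to_numpy(dtype=float)[reorder],
            want.to_numpy(dtype=float)[reorder_f],
            equal_nan=True,
        )
        assert np.allclose(merged.stats[reorder], full.stats[reorder_f])

    def test_save_load_roundtrip(self, tiny_ref, tmp_path):
        ref, _, _ = tiny_ref
        p = tmp_path / "ref.tsv"
        ref.save(p)
        back = mabc.ReferenceTable.load(p)
        assert back.stat_names == ref.stat_names
        assert np.allclose(back.stats, ref.stats)
        assert list(back.scenario_ids) == list(ref.scenario_ids)
        assert back.meta["scenario_priors"] == ref.meta["scenario_priors"]


class TestRejection:
    def test_exact_row_retained_at_zero_distance(self, tiny_ref):
        ref, _, _ = tiny_ref
        ret = mabc.rejection(ref, ref.stats[17], 0.05)
        assert 17 in ret.indices
        assert ret.distances.min() == pytest.approx(0.0, abs=1e-12)

    def test_retain_fraction_one_keeps_everything(self, tiny_ref):
        ref, _, _ = tiny_ref
        ret = mabc.rejection(ref, ref.stats.mean(axis=0), 1.0)
        assert ret.indices.size == ref.n_rows

    def test_distance_invariant_to_stat_rescaling(self, tiny_ref):
        ref, _, _ = tiny_ref
        obs = ref.stats.mean(axis=0)
        ret1 = mabc.rejection(ref, obs, 0.1)
        scaled = mabc.ReferenceTable(
            ref.scenario_ids, ref.params, ref.stats.copy(), ref.stat_names, ref.meta
        )
        scaled.stats[:, 3] *= 10
        obs2 = obs.copy()
        obs2[3] *= 10
        ret2 = mabc.rejection(scaled, obs2, 0.1)
        assert np.array_equal(ret1.indices, ret2.indices)
        assert np.allclose(ret1.distances, ret2.distances)


class TestModelChoice:
    def test_single_scenario_probability_one(self, tiny_ref):
        ref, _, _ = tiny_ref
        only = ref.scenario_ids == "scenario13"
        sub = mabc.ReferenceTable(
            ref.scenario_ids[only], ref.params[only].reset_index(drop=True),
            ref.stats[only], ref.stat_names, ref.meta,
        )
        ret = mabc.rejection(sub, sub.stats[0], 0.2)
        direct = mabc.model_posterior_direct(ret)
        assert direct["scenario13"] == 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            logi, degen = mabc.model_posterior_logistic(ret)
        assert degen and logi["scenario13"] == 1.0

    def test_probabilities_sum_to_one(self, tiny_ref):
        ref, _, _ = tiny_ref
        ret = mabc.rejection(ref, ref.stats.mean(axis=0), 0.3)
        assert mabc.model_posterior_direct(ret).sum() == pytest.approx(1.0)
        logi, _ = mabc.model_posterior_logistic(ret)
        assert logi.sum() == pytest.approx(1.0)

    def test_separable_toy_logistic_near_certain(self):
        rng = np.random.default_rng(3)
        stats = np.vstack([
            rng.normal(0, 0.3, size=(200, 2)),
            rng.normal(6, 0.3, size=(200, 2)),
        ])
        ref = mabc.ReferenceTable(
            scenario_ids=np.array(["A"] * 200 + ["B"] * 200),
            params=pd.DataFrame({"x": np.ones(400)}),
            stats=stats,
            stat_names=["s1", "s2"],
            meta={"scenario_priors": {"A": {"x": [0.1, 10]}, "B": {"x": [0.1, 10]}}},
        )
        ret = mabc.rejection(ref, np.array([0.0, 0.0]), 1.0)
        logi, degen = mabc.model_posterior_logistic(ret)
        assert not degen
        assert logi["A"] > 0.99

    def test_constant_statistic_is_ignored(self, tiny_ref):
        ref, _, _ = tiny_ref
        aug = mabc.ReferenceTable(
            ref.scenario_ids,
            ref.params,
            np.column_stack([ref.stats, np.full(ref.n_rows, 3.14)]),
            ref.stat_names + ["const"],
            ref.meta,
        )
        obs = np.append(ref.stats.mean(axis=0), 3.14)
        ret0 = mabc.rejection(ref, ref.stats.mean(axis=0), 0.2)
        ret1 = mabc.rejection(aug, obs, 0.2)
        assert np.array_equal(ret0.indices, ret1.indices)
        l0, _ = mabc.model_posterior_logistic(ret0)
        l1, _ = mabc.model_posterior_logistic(ret1)
        assert np.allclose(l0.to_numpy(), l1.to_numpy())

    def test_direct_and_logistic_agree_on_exchangeable_null(self):
        """When both scenarios' statistics come from one distribution the
        observed point carries no information: both estimators sit near 1/2
        and agree."""
        rng = np.random.default_rng(12)
        stats = rng.normal(0, 1, size=(2000, 4))
        ids = np.array(["A", "B"])[rng.integers(0, 2, 2000)]
        ref = mabc.ReferenceTable(
            scenario_ids=ids,
            params=pd.DataFrame({"x": np.ones(2000)}),
            stats=stats,
            stat_names=["s1", "s2", "s3", "s4"],
            meta={"scenario_priors": {s: {"x": [0.1, 10]} for s in "AB"}},
        )
        ret = mabc.rejection(ref, np.zeros(4), 0.25)
        direct = mabc.model_posterior_direct(ret, n_delta=len(ret.indices))
        logi, degen = mabc.model_posterior_logistic(ret)
        assert not degen
        assert direct["A"] == pytest.approx(0.5, abs=0.1)
        assert (direct - logi).abs().max() < 0.15


class TestParameterPosterior:
    def test_ci_ordering_and_bounds(self, tiny_ref):
        ref, _, _ = tiny_ref
        ret = mabc.rejection(ref, np.median(ref.stats, axis=0), 0.5)
        post = mabc.parameter_posterior(ret, "scenario13", parameters=["t2", "t3"])
        for _, row in post.iterrows():
            assert row["q025"] <= row["median"] <= row["q975"]
        assert post.loc["t3", "q975"] <= 2e6
        assert post.loc["t2", "q025"] >= 10

    def test_zero_deviation_adjustment_is_identity(self, tiny_ref):
        """If every retained row matches the observed stats exactly, the
        regression has nothing to adjust and the posterior median equals the
        plain median of the retained draws."""
        ref, _, _ = tiny_ref
        only = np.flatnonzero(ref.scenario_ids == "scenario13")[:120]
        obs = ref.stats.mean(axis=0)
        stats = np.vstack([
            np.tile(obs, (60, 1)),  # retained half: zero deviation
            np.tile(obs + 50.0, (60, 1)),  # far half, provides spread
        ])
        sub = mabc.ReferenceTable(
            ref.scenario_ids[only], ref.params.iloc[only].reset_index(drop=True),
            stats, ref.stat_names, ref.meta,
        )
        ret = mabc.rejection(sub, obs, 0.5)
        post = mabc.parameter_posterior(ret, "scenario13", parameters=["t3"])
        draws = sub.params["t3"].to_numpy()[:60]
        assert post.loc["t3", "median"] == pytest.approx(
            np.median(draws), rel=0.01
        )

    def test_too_few_rows_raises(self, tiny_ref):
        ref, _, _ = tiny_ref
        ret = mabc.rejection(ref, np.median(ref.stats, axis=0), 0.02)
        with pytest.raises(ValueError, match="retained rows"):
            mabc.parameter_posterior(ret, "scenario13", min_rows=10**6)

    def test_weighted_quantile_uniform_weights(self, rng):
        x = rng.normal(size=501)
        w = np.ones_like(x)
        got = mabc.weighted_quantile(x, [0.5], w)[0]
        assert got == pytest.approx(np.median(x), abs=1e-9)


class TestPosteriorPredictive:
    def test_determinism_and_range(self, tiny_ref):
        ref, scens, cfg = tiny_ref
        obs = np.median(ref.stats, axis=0)
        ret = mabc.rejection(ref, obs, 0.3)
        obs_ss = mabc.SummaryStats(ref.stat_names, obs, np.ones(14, dtype=bool))
        p1 = mabc.posterior_predictive_check(
            scens["scenario13"], ret, obs_ss, cfg, n_rep=20, seed=5
        )
        p2 = mabc.posterior_predictive_check(
            scens["scenario13"], ret, obs_ss, cfg, n_rep=20, seed=5
        )
        assert p1.equals(p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_degenerate_posterior_warns(self, tiny_ref):
        ref, scens, cfg = tiny_ref
        obs = ref.stats[0]
        ret = mabc.rejection(ref, obs, 1 / ref.n_rows)
        if ret.indices.size == 1 and ret.scenario_ids[0] in scens:
            scn = scens[str(ret.scenario_ids[0])]
            obs_ss = mabc.SummaryStats(ref.stat_names, obs, np.ones(14, dtype=bool))
            with pytest.warns(UserWarning, match="single retained"):
                mabc.posterior_predictive_check(scn, ret, obs_ss, cfg, n_rep=5, seed=2)
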