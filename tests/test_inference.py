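"""ABC machinery: rejection, scenario choice, adjustment, posterior summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from milletabc.inference import (
    ParamTransforms,
    PosteriorSample,
    ReferenceTable,
    abc_reject,
    build_reference_table,
    derived_quantities,
    model_choice,
    posterior_summary,
    regression_adjust,
    weighted_hpd,
    weighted_median,
)
from milletabc.simulate import LocusSpec, PriorConfig
from milletabc.twopop import MultiLocusSummary

from _oracles import hpd_brute

SPECS = [LocusSpec("a", 4, 6, 200), LocusSpec("b", 5, 8, 300)]


def summary_of(values: np.ndarray, names=None) -> MultiLocusSummary:
    names = names or [f"s{i}" for i in range(len(values))]
    return MultiLocusSummary(
        names=list(names),
        values=np.asarray(values, dtype=float),
        flagged=np.isnan(values),
    )


def synthetic_table(rng, n_rows=200, n_sum=6, prior=None) -> ReferenceTable:
    """A reference table with arbitrary (valid) parameters and summaries."""
    prior = prior or PriorConfig()
    from milletabc.simulate import sample_prior
    from milletabc.inference import PARAM_NAMES

    rows = [sample_prior(prior, rng).as_dict() for _ in range(n_rows)]
    params = pd.DataFrame(rows)[PARAM_NAMES]
    summaries = rng.normal(size=(n_rows, n_sum))
    return ReferenceTable(
        params=params,
        summaries=summaries,
        names=[f"s{i}" for i in range(n_sum)],
        scenario=prior.scenario,
        prior=prior,
    )


class TestReferenceTable:
    def test_deterministic_rebuild(self):
        t1 = build_reference_table(PriorConfig(), SPECS, n_sims=10, seed=4)
        t2 = build_reference_table(PriorConfig(), SPECS, n_sims=10, seed=4)
        pd.testing.assert_frame_equal(t1.params, t2.params)
        assert np.allclose(t1.summaries, t2.summaries, equal_nan=True)

    def test_imputation_leaves_no_partial_nans(self):
        table = build_reference_table(PriorConfig(), SPECS, n_sims=30, seed=1)
        col_all_nan = np.isnan(table.summaries).all(axis=0)
        col_any_nan = np.isnan(table.summaries).any(axis=0)
        assert (col_all_nan == col_any_nan).all()

    def test_parameter_marginals_follow_prior(self):
        table = build_reference_table(PriorConfig(), SPECS, n_sims=150, seed=8)
        lw = np.log(table.params["theta_w"])
        lo, hi = np.log(1e-3), 0.0
        assert kstest((lw - lo) / (hi - lo), "uniform").pvalue > 0.01


class TestRejection:
    def test_exact_match_ranks_first(self, rng):
        table = synthetic_table(rng)
        obs = summary_of(table.summaries[17])
        res = abc_reject(obs, table, n_keep=5)
        assert res.indices[0] == 17
        assert res.distances[0] == pytest.approx(0.0)

    def test_keep_all_is_identity(self, rng):
        table = synthetic_table(rng, n_rows=50)
        obs = summary_of(rng.normal(size=6))
        res = abc_reject(obs, table, n_keep=50)
        assert sorted(res.indices) == list(range(50))

    def test_ranking_matches_brute_force(self, rng):
        table = synthetic_table(rng, n_rows=200)
        obs = summary_of(rng.normal(size=6))
        res = abc_reject(obs, table, n_keep=40)
        med = np.median(table.summaries, axis=0)
        mad = np.median(np.abs(table.summaries - med), axis=0)
        d = np.sqrt(
            (((table.summaries - obs.values) / mad) ** 2).sum(axis=1)
        )
        expect = np.argsort(d, kind="stable")[:40]
        assert np.array_equal(res.indices, expect)

    def test_invariant_to_affine_rescaling(self, rng):
        table = synthetic_table(rng, n_rows=120)
        obs_vals = rng.normal(size=6)
        r1 = abc_reject(summary_of(obs_vals), table, n_keep=30)
        scaled = table.summaries.copy()
        scaled[:, 2] = scaled[:, 2] * 37.0 + 5.0
        table2 = ReferenceTable(
            params=table.params, summaries=scaled, names=table.names,
            scenario=table.scenario, prior=table.prior,
        )
        obs2 = obs_vals.copy()
        obs2[2] = obs2[2] * 37.0 + 5.0
        r2 = abc_reject(summary_of(obs2), table2, n_keep=30)
        assert np.array_equal(r1.indices, r2.indices)


class TestModelChoice:
    def test_identical_tables_give_half(self, rng):
        t1 = synthetic_table(rng, n_rows=150)
        t2 = ReferenceTable(
            params=t1.params.copy(), summaries=t1.summaries.copy(),
            names=t1.names, scenario="without_migration",
            prior=PriorConfig(scenario="without_migration"),
        )
        obs = summary_of(rng.normal(size=6))
        res = model_choice(obs, t1, t2, n_keep=100)
        probs = res.posterior_prob
        assert sum(probs.values()) == pytest.approx(1.0)
        assert probs["with_migration"] == pytest.approx(0.5, abs=0.1)

    def test_probabilities_sum_to_one(self, rng):
        t1 = synthetic_table(rng, n_rows=80)
        rng2 = np.random.default_rng(999)
        t2 = synthetic_table(rng2, n_rows=80)
        t2 = ReferenceTable(
            params=t2.params, summaries=t2.summaries + 1.0, names=t2.names,
            scenario="without_migration",
            prior=PriorConfig(scenario="without_migration"),
        )
        obs = summary_of(rng.normal(size=6))
        res = model_choice(obs, t1, t2, n_keep=60)
        assert sum(res.posterior_prob.values()) == pytest.approx(1.0)
        assert all(p >= 0 for p in res.posterior_prob.values())

    def test_separable_scenarios_favor_the_near_one(self, rng):
        t1 = synthetic_table(rng, n_rows=100)
        t2 = synthetic_table(rng, n_rows=100)
        t2 = ReferenceTable(
            params=t2.params, summaries=t2.summaries + 4.0, names=t2.names,
            scenario="without_migration",
            prior=PriorConfig(scenario="without_migration"),
        )
        obs = summary_of(np.zeros(6))  # on scenario-1's manifold
        res = model_choice(obs, t1, t2, n_keep=120)
        assert res.posterior_prob["with_migration"] > 0.5


class TestRegressionAdjustment:
    def test_rejection_method_keeps_values(self, rng):
        table = synthetic_table(rng)
        obs = summary_of(rng.normal(size=6))
        rej = abc_reject(obs, table, n_keep=30)
        post = regression_adjust(obs, table, rej, method="rejection")
        expect = table.params.iloc[rej.indices].reset_index(drop=True)
        pd.testing.assert_frame_equal(post.params, expect)

    def test_loclinear_recovers_noiseless_linear_map(self, rng):
        """If transformed params depend linearly on summaries, the
        local-linear adjustment collapses the accepted cloud onto the
        generating value at the observed summaries."""
        prior = PriorConfig()
        tr = ParamTransforms(prior)
        n, k = 300, 4
        s = rng.normal(size=(n, k))
        A = rng.normal(size=(k, 8)) * 0.3
        z = s @ A  # 8 transformed parameters, exactly linear in summaries
        params = tr.backward(z, ["theta_w", "theta_d1", "theta_d0", "rho",
                                 "mu", "t_years", "mig_wd", "mig_dw"])
        table = ReferenceTable(
            params=params,
            summaries=s,
            names=[f"s{i}" for i in range(k)],
            scenario=prior.scenario,
            prior=prior,
        )
        s_obs = rng.normal(size=k)
        obs = summary_of(s_obs)
        rej = abc_reject(obs, table, n_keep=100)
        post = regression_adjust(obs, table, rej, method="loclinear")
        z_expect = s_obs @ A
        expect = tr.backward(
            z_expect[None, :], ["theta_w", "theta_d1", "theta_d0", "rho",
                                "mu", "t_years", "mig_wd", "mig_dw"]
        )
        for col in ("theta_w", "mu", "t_years"):
            vals = post.params[col].to_numpy()
            target = expect[col].iloc[0]
            assert np.quantile(np.abs(np.log(vals) - np.log(target)), 0.9) < 1e-6

    def test_adjusted_values_respect_prior_bounds(self, rng):
        table = build_reference_table(PriorConfig(), SPECS, n_sims=60, seed=2)
        obs = summary_of(table.summaries[0] * 1.5, names=table.names)
        obs.flagged = np.isnan(obs.values)
        rej = abc_reject(obs, table, n_keep=40)
        for method in ("loclinear", "nonlinear"):
            post = regression_adjust(obs, table, rej, method=method)
            p = post.params
            assert ((p["theta_w"] >= 1e-3) & (p["theta_w"] <= 1.0)).all()
            assert (p["theta_d0"] <= np.minimum(p["theta_d1"], p["theta_w"])
                    * (1 + 1e-9)).all()
            assert ((p["t_years"] >= 3000) & (p["t_years"] <= 12000)).all()
            assert ((p["mig_wd"] >= 0) & (p["mig_wd"] <= 100)).all()

    def test_too_few_accepted_rows_rejected(self, rng):
        table = synthetic_table(rng, n_rows=30)
        obs = summary_of(rng.normal(size=6))
        rej = abc_reject(obs, table, n_keep=10)
        with pytest.raises(ValueError):
            regression_adjust(obs, table, rej, method="loclinear")


class TestPosteriorSummaries:
    def test_equal_weights_median_and_hpd(self):
        values = np.arange(1.0, 101.0)
        weights = np.ones(100)
        assert weighted_median(values, weights) == pytest.approx(50.5)
        lo, hi = weighted_hpd(values, weights, 0.95)
        blo, bhi = hpd_brute(values, weights, 0.95)
        assert (lo, hi) == (blo, bhi)
        assert hi - lo == pytest.approx(94.0)

    def test_hpd_matches_brute_force_on_random_samples(self, rng):
        for _ in range(25):
            v = rng.normal(size=60) ** 3  # skewed
            w = rng.uniform(0.1, 1.0, size=60)
            assert weighted_hpd(v, w) == pytest.approx(hpd_brute(v, w))

    def test_point_mass_degenerate_interval(self):
        v = np.full(10, 3.14)
        lo, hi = weighted_hpd(v, np.ones(10))
        assert lo == hi == 3.14

    def test_hpd_no_wider_than_equal_tailed(self, rng):
        for _ in range(10):
            v = np.sort(rng.gamma(2.0, size=80))
            w = np.ones(80)
            lo, hi = weighted_hpd(v, w)
            # central window holding exactly 95% of the empirical mass
            assert (hi - lo) <= (v[77] - v[2]) + 1e-9

    def test_summary_ordering_invariant(self, rng):
        table = synthetic_table(rng, n_rows=60)
        post = PosteriorSample(
            params=table.params, weights=np.ones(60),
            distances=np.zeros(60), method="rejection",
        )
        for est in posterior_summary(post):
            assert est.hpd_low <= est.median <= est.hpd_high


class TestDerivedQuantities:
    def test_published_medians_give_published_time(self):
        from milletabc.studydata import POSTERIOR_MEDIANS

        d = derived_quantities(POSTERIOR_MEDIANS)
        assert d.t_years == pytest.approx(8881.2, rel=1e-3)
        assert d.bottleneck_ratio == pytest.approx(1.19e-2, rel=0.01)
        assert d.expansion_ratio > 0

    def test_unit_consistency(self):
        med = {"theta_w": 6.5e-8 * 4e4, "theta_d0": 1e-3, "theta_d1": 1e-2,
               "T": 1.0, "mu": 6.5e-8}
        assert derived_quantities(med).t_years == pytest.approx(4e4)

    def test_per_draw_ratios_positive(self, rng):
        table = synthetic_table(rng, n_rows=40)
        post = PosteriorSample(
            params=table.params, weights=np.ones(40),
            distances=np.zeros(40), method="rejection",
        )
        d = derived_quantities(post)
        assert (d.per_draw > 0).all().all()
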