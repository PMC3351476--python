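"""Prior sampling, event schedule and coalescent simulator behavior."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import kstest

from milletabc.popgen import harmonic_numbers, tajimas_d_from_counts
from milletabc.simulate import (
    WITHOUT_MIGRATION,
    DemographicParams,
    LocusSpec,
    PriorConfig,
    SimulatedLocus,
    _sim_ancestry,
    event_schedule,
    fixed_s_focal_counts,
    read_ms,
    sample_prior,
    simulate_dataset,
    simulate_locus,
    write_ms,
)

from _oracles import fixed_s_counts_oracle


def constant_params(theta=0.005, mu=1e-8, mig=0.0):
    """Degenerate model: domestic identical to wild (constant total size)."""
    return DemographicParams(
        theta_w=theta, theta_d0=theta, theta_d1=theta, rho=0.0,
        mig_wd=mig, mig_dw=mig, mu=mu, t_years=1.0,
    )


class TestPriors:
    def test_marginal_supports_and_bottleneck_ordering(self, rng):
        prior = PriorConfig()
        for _ in range(2000):
            p = sample_prior(prior, rng)
            assert 1e-3 <= p.theta_w <= 1.0
            assert 1e-8 <= p.theta_d1 <= 1.0
            assert p.theta_d0 <= min(p.theta_d1, p.theta_w)
            assert p.theta_d0 >= 1e-5 * min(p.theta_d1, p.theta_w) * (1 - 1e-9)
            assert 0.0 <= p.mig_wd <= 100.0 and 0.0 <= p.mig_dw <= 100.0
            assert 3000.0 <= p.t_years <= 12000.0
            assert p.T == pytest.approx(p.t_years * p.mu / p.theta_w)

    def test_mu_median_matches_lognormal_closed_form(self, rng):
        draws = [sample_prior(PriorConfig(), rng).mu for _ in range(20000)]
        # median of exp(N(-17.7, 1)) = e^-17.7 = 2.04e-8
        assert np.median(draws) == pytest.approx(np.exp(-17.7), rel=0.05)

    def test_log_theta_w_uniform(self, rng):
        draws = np.log([sample_prior(PriorConfig(), rng).theta_w
                        for _ in range(5000)])
        lo, hi = np.log(1e-3), 0.0
        assert kstest((draws - lo) / (hi - lo), "uniform").pvalue > 0.01

    def test_without_migration_scenario_zeroes_rates(self, rng):
        p = sample_prior(PriorConfig(scenario=WITHOUT_MIGRATION), rng)
        assert p.mig_wd == 0.0 and p.mig_dw == 0.0


class TestEventSchedule:
    def test_equal_sizes_give_zero_growth(self):
        s = event_schedule(constant_params())
        assert s.growth_rate == 0.0 and s.growth_rate_scaled == 0.0

    def test_unit_growth_case(self):
        # theta_d1 / theta_d0 = e and T = 1 -> scaled growth rate 1
        theta_w = 0.01
        mu = 1e-8
        t = theta_w / mu  # makes T = 1
        p = DemographicParams(
            theta_w=theta_w, theta_d0=0.001, theta_d1=0.001 * np.e,
            rho=0, mig_wd=0, mig_dw=0, mu=mu, t_years=t,
        )
        assert event_schedule(p).growth_rate_scaled == pytest.approx(1.0)

    def test_trajectory_hits_founder_size_at_domestication(self, rng):
        for _ in range(20):
            p = sample_prior(PriorConfig(), rng)
            s = event_schedule(p)
            rel = s.domestic_relative_size(s.T)
            assert rel == pytest.approx(p.theta_d0 / p.theta_w, rel=1e-9)

    def test_ordering_invariant_violation_raises(self):
        with pytest.raises(ValueError):
            DemographicParams(
                theta_w=0.01, theta_d0=0.5, theta_d1=0.1, rho=0,
                mig_wd=0, mig_dw=0, mu=1e-8, t_years=5000,
            )


class TestSimulateLocus:
    SPEC = LocusSpec("locus", n_wild=5, n_dom=8, L=400)

    def test_fixed_s_zero(self):
        locus = simulate_locus(constant_params(), self.SPEC, seed=1, fixed_s=0)
        assert locus.S == 0

    def test_fixed_s_exact_and_polymorphic_in_focal(self):
        for seed in range(5):
            locus = simulate_locus(
                constant_params(), self.SPEC, seed=seed, fixed_s=7, focal="dom"
            )
            assert locus.S == 7
            dom = locus.haplotypes[5:]
            counts = dom.sum(axis=0)
            assert ((counts > 0) & (counts < 8)).all()

    def test_same_seed_bitwise_identical(self):
        a = simulate_locus(constant_params(), self.SPEC, seed=3)
        b = simulate_locus(constant_params(), self.SPEC, seed=3)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            LocusSpec("bad", n_wild=1, n_dom=0, L=100)

    def test_single_population_diversity_calibration(self):
        # constant size, n_dom only: E(pi_total) = theta_locus = 4
        theta, L, reps = 0.01, 400, 500
        p = constant_params(theta=theta)
        sched = event_schedule(p)
        rng = np.random.default_rng(11)
        pis = []
        from milletabc.simulate import _poisson_mutations

        for ts in _sim_ancestry(sched, 0, 20, L, rng, num_replicates=reps):
            G, _ = _poisson_mutations(ts, p.mu, rng)
            k = G.sum(axis=0)
            pis.append(np.sum(k * (20 - k)) / (20 * 19 / 2))
        expect = theta * L
        se = np.std(pis) / np.sqrt(reps)
        assert abs(np.mean(pis) - expect) < 3 * se


class TestFixedSPlacement:
    def test_matches_independent_edge_table_oracle(self):
        """Distribution of derived counts agrees with a reimplementation."""
        p = constant_params(theta=0.01)
        sched = event_schedule(p)
        rng = np.random.default_rng(5)
        focal = np.arange(10)
        mine, oracle = [], []
        reps = _sim_ancestry(sched, 0, 10, 300, rng, num_replicates=400)
        for ts in reps:
            mine.extend(fixed_s_focal_counts(ts, focal, 3, rng))
            oracle.extend(fixed_s_counts_oracle(ts, focal, 3, rng))
        mine, oracle = np.asarray(mine), np.asarray(oracle)
        se = np.sqrt(np.var(mine) / len(mine) + np.var(oracle) / len(oracle))
        assert abs(mine.mean() - oracle.mean()) < 4 * se
        # frequency-class distribution agrees
        f1 = np.bincount(mine, minlength=10)[1:] / len(mine)
        f2 = np.bincount(oracle, minlength=10)[1:] / len(oracle)
        assert np.abs(f1 - f2).max() < 0.05


class TestSimulateDataset:
    SPECS = [
        LocusSpec("a", 4, 6, 300),
        LocusSpec("b", 5, 8, 500),
        LocusSpec("c", 3, 7, 200),
    ]

    def test_smoke_and_schema(self):
        from milletabc.studydata import fitted_params, sts_locus_specs

        loci, summary = simulate_dataset(
            fitted_params(), sts_locus_specs(), seed=2
        )
        assert len(loci) == 8
        assert len(summary.values) == 48

    def test_deterministic(self):
        l1, s1 = simulate_dataset(constant_params(), self.SPECS, seed=9)
        l2, s2 = simulate_dataset(constant_params(), self.SPECS, seed=9)
        for a, b in zip(l1, l2):
            assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.allclose(s1.values, s2.values, equal_nan=True)

    def test_batched_and_per_locus_engines_agree_in_distribution(self):
        p = constant_params(theta=0.01)
        mean_s = {}
        for batch in (True, False):
            ss = []
            rng = np.random.default_rng(17)
            for _ in range(150):
                loci, _ = simulate_dataset(
                    p, self.SPECS, rng=rng, batch=batch, summarize=False
                )
                ss.append(sum(l.S for l in loci))
            mean_s[batch] = (np.mean(ss), np.std(ss) / np.sqrt(len(ss)))
        diff = abs(mean_s[True][0] - mean_s[False][0])
        se = np.hypot(mean_s[True][1], mean_s[False][1])
        assert diff < 4 * se

    def test_divergence_grows_with_time(self):
        """Without gene flow, fixed differences accumulate with T."""
        means = []
        for t_years in (2e3, 2e5):
            p = DemographicParams(
                theta_w=0.01, theta_d0=0.005, theta_d1=0.01, rho=0,
                mig_wd=0, mig_dw=0, mu=1e-8, t_years=t_years,
            )
            rng = np.random.default_rng(23)
            fixed = []
            for _ in range(150):
                loci, _ = simulate_dataset(
                    p, [LocusSpec("x", 6, 6, 400)], rng=rng, summarize=False
                )
                locus = loci[0]
                kw = locus.haplotypes[:6].sum(axis=0)
                kd = locus.haplotypes[6:].sum(axis=0)
                fixed.append(
                    int((((kw == 6) & (kd == 0)) | ((kw == 0) & (kd == 6))).sum())
                )
            means.append(np.mean(fixed))
        assert means[1] > means[0]

    def test_gene_flow_lowers_divergence(self):
        """Higher wild->domestic migration lowers between-population Fst."""
        fsts = {}
        for mig in (0.0, 20.0):
            p = DemographicParams(
                theta_w=0.01, theta_d0=0.002, theta_d1=0.01, rho=0,
                mig_wd=mig, mig_dw=0.0, mu=1e-8,
                t_years=0.3 * 0.01 / 1e-8,  # T = 0.3
            )
            rng = np.random.default_rng(31)
            vals = []
            for _ in range(150):
                loci, _ = simulate_dataset(
                    p, [LocusSpec("x", 8, 8, 400)], rng=rng, summarize=False
                )
                locus = loci[0]
                from milletabc.twopop import summarize_locus

                two = summarize_locus("x", *locus.site_pair()).two
                if two.Fst is not None:
                    vals.append(two.Fst)
            fsts[mig] = np.mean(vals)
        assert fsts[20.0] < fsts[0.0]


class TestMsInterchange:
    def test_roundtrip(self, tmp_path, rng):
        specs = [LocusSpec("a", 3, 4, 100), LocusSpec("b", 2, 5, 150)]
        loci, _ = simulate_dataset(
            constant_params(theta=0.02), specs, seed=13, summarize=False
        )
        path = tmp_path / "out.ms"
        write_ms(loci, path)
        back = read_ms(path, specs)
        for a, b in zip(loci, back):
            assert np.array_equal(a.haplotypes, b.haplotypes)
            assert np.allclose(a.positions, b.positions, atol=a.L * 1e-5)
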