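"""Distribution fitting, simulation correctness and convergence checking."""

import numpy as np
import pytest
from scipy import stats

from pahrisk import monte_carlo as mc, registry, risk

from pahrisk.monte_carlo import (
    DistributionSpec,
    convergence_check,
    fit_lognormal,
    lognormal_from_mean_cv,
    run_simulation,
)


def point_specs(survey_means):
    total_bapeq = float(risk.compute_bapeq(survey_means).sum())
    return {
        "bw": DistributionSpec("bw", "point", (60.0,)),
        "ir": DistributionSpec("ir", "point", (49.3,)),
        "ed": DistributionSpec("ed", "point", (70.0,)),
        "bapeq": DistributionSpec("bapeq", "point", (total_bapeq,)),
        "concentration": DistributionSpec("concentration", "point",
                                          (float(survey_means.sum()),)),
    }


class TestFitLognormal:
    def test_analytic_symmetric_sample(self):
        mu, sigma, p = fit_lognormal(np.exp([-1.0, 0.0, 1.0]))
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, abs=1e-12)  # sample (ddof=1) SD
        assert 0 <= p <= 1

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        draws = rng.lognormal(1.0, 0.4, 5000)
        mu, sigma, p = fit_lognormal(draws)
        assert mu == pytest.approx(1.0, abs=0.02)
        assert sigma == pytest.approx(0.4, abs=0.02)
        assert p > 0.01  # log-draws are exactly normal

    @pytest.mark.parametrize("bad", [
        [1.0, 2.0],                 # too few
        [1.0, -1.0, 2.0],           # non-positive
        [3.0, 3.0, 3.0, 3.0],       # constant: degenerate for Shapiro-Wilk
    ])
    def test_invalid_input(self, bad):
        with pytest.raises(ValueError):
            fit_lognormal(bad)


class TestDistributionSpec:
    def test_family_validation(self):
        with pytest.raises(ValueError):
            DistributionSpec("bw", "gamma", (1.0, 2.0))
        with pytest.raises(ValueError):
            DistributionSpec("bw", "uniform", (5.0, 1.0))
        with pytest.raises(ValueError):
            DistributionSpec("bw", "normal", (60.0, -1.0))
        with pytest.raises(ValueError):
            DistributionSpec("bw", "point", (1.0, 2.0))
        with pytest.raises(ValueError):
            DistributionSpec("bw", "triangular", (3.0, 1.0, 2.0))

    def test_lognormal_moment_match(self):
        mu, sigma = lognormal_from_mean_cv(49.3, 0.3)
        assert np.exp(mu + sigma ** 2 / 2) == pytest.approx(49.3, rel=1e-12)

    def test_truncated_normal_stays_positive(self):
        spec = DistributionSpec("bw", "normal", (0.5, 2.0))
        draws = spec.sample(np.random.default_rng(0), 2000)
        assert np.all(draws > 0)


class TestRunSimulation:
    def test_point_masses_reproduce_deterministic_risk(self, survey_means,
                                                       carc_params):
        res = run_simulation(point_specs(survey_means), carc_params,
                             n_iterations=50, seed=0,
                             hq_composition=survey_means)
        total_bapeq = risk.compute_bapeq(survey_means).sum()
        _, det_tilcr = risk.compute_ilcr(np.array([total_bapeq]), carc_params)
        assert np.all(res.tilcr_draws == det_tilcr)  # exact, not approximate
        _, det_hi = risk.compute_hq(survey_means, carc_params)
        np.testing.assert_allclose(res.hi_draws, det_hi, rtol=1e-12)

    def test_seed_contract(self, survey_means, carc_params):
        specs = point_specs(survey_means)
        specs["bapeq"] = DistributionSpec("bapeq", "lognormal", (1.0, 0.5))
        r1 = run_simulation(specs, carc_params, n_iterations=500, seed=1)
        r2 = run_simulation(specs, carc_params, n_iterations=500, seed=1)
        r3 = run_simulation(specs, carc_params, n_iterations=500, seed=2)
        np.testing.assert_array_equal(r1.tilcr_draws, r2.tilcr_draws)
        assert not np.array_equal(r1.tilcr_draws, r3.tilcr_draws)

    def test_lognormal_tail_matches_closed_form(self, survey_means, carc_params):
        mu, sigma = 1.0, 0.8
        specs = point_specs(survey_means)
        specs["bapeq"] = DistributionSpec("bapeq", "lognormal", (mu, sigma))
        n = 10_000
        res = run_simulation(specs, carc_params, n_iterations=n, seed=3)
        # TILCR = bapeq x scale, so P(TILCR > t) has a log-normal closed form
        scale = risk.compute_ilcr(np.array([1.0]), carc_params)[1]
        for t in (1e-5, 2e-5, 5e-5):
            p_true = 1 - stats.norm.cdf((np.log(t / scale) - mu) / sigma)
            se = np.sqrt(p_true * (1 - p_true) / n)
            p_emp = np.mean(res.tilcr_draws > t)
            assert abs(p_emp - p_true) <= 3 * se

    def test_mean_tilcr_obeys_law_of_large_numbers(self, carc_params):
        # independent product: E[TILCR] = scale x E[bapeq] E[ir] E[ed] / bw
        specs = {
            "bw": DistributionSpec("bw", "point", (60.0,)),
            "ir": DistributionSpec("ir", "lognormal", lognormal_from_mean_cv(49.3, 0.3)),
            "ed": DistributionSpec("ed", "uniform", (30.0, 70.0)),
            "bapeq": DistributionSpec("bapeq", "lognormal", (1.0, 0.6)),
        }
        res = run_simulation(specs, carc_params, n_iterations=100_000, seed=8)
        e_bapeq = np.exp(1.0 + 0.6 ** 2 / 2)
        analytic = (1e-3 * carc_params.csf * (49.3e-3) * 365.0 * 50.0
                    / (60.0 * carc_params.at_days)) * e_bapeq
        assert res.tilcr_draws.mean() == pytest.approx(analytic, rel=0.01)

    def test_percentiles_monotone_and_exceedance_bounded(self, survey_means,
                                                         carc_params):
        specs = point_specs(survey_means)
        specs["bapeq"] = DistributionSpec("bapeq", "lognormal", (0.5, 1.0))
        res = run_simulation(specs, carc_params, n_iterations=2000, seed=4)
        assert np.all(np.diff(res.percentiles["tilcr"].to_numpy()) >= 0)
        assert all(0 <= v <= 1 for v in res.exceedance.values())

    def test_missing_spec_rejected(self, carc_params):
        with pytest.raises(ValueError, match="bapeq"):
            run_simulation({"bw": DistributionSpec("bw", "point", (60.0,)),
                            "ir": DistributionSpec("ir", "point", (49.3,)),
                            "ed": DistributionSpec("ed", "point", (70.0,))},
                           carc_params)


class TestConvergence:
    def test_point_config_is_trivially_stable(self, survey_means, carc_params):
        stable, table = convergence_check(point_specs(survey_means), carc_params,
                                          iteration_counts=(1000, 2000), seed=0)
        assert stable
        assert table["tilcr_p95"].nunique() == 1

    def test_sweep_shows_shrinking_monte_carlo_error(self, survey_means,
                                                     carc_params):
        specs = point_specs(survey_means)
        specs["bapeq"] = DistributionSpec("bapeq", "lognormal", (1.0, 0.9))
        stable, table = convergence_check(specs, carc_params, seed=11)
        assert len(table) == 4
        se = table["tilcr_se"].to_numpy()
        n = table["n_iterations"].to_numpy()
        assert np.all(np.diff(se) < 0)
        # SE ~ 1/sqrt(n) within 50% slack
        expected = se[0] * np.sqrt(n[0] / n)
        assert np.all(np.abs(se - expected) / expected < 0.5)

    def test_count_validation(self, survey_means, carc_params):
        with pytest.raises(ValueError):
            convergence_check(point_specs(survey_means), carc_params,
                              iteration_counts=(4000,))
        with pytest.raises(ValueError):
            convergence_check(point_specs(survey_means), carc_params,
                              iteration_counts=(7000, 4000))


def test_default_specs_cover_all_variables(survey_means):
    from pahrisk import synthetic
    conc = synthetic.generate_from_survey(200, seed=1)
    specs = mc.default_specs(conc)
    assert {"bw", "ir", "ed", "ef", "bapeq", "concentration"} <= set(specs)
    assert specs["bapeq"].family == "lognormal"
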