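"""Source- and ring-resolved risk attribution: closure, ground truth, toys."""

import numpy as np
import pytest

from pahrisk import pmf, registry, synthetic
from pahrisk.pmf import FactorModel, fit_pmf
from pahrisk.source_risk import (
    apportion_concentrations,
    attribute_risk,
    ring_class_risk_shares,
)

from conftest import match_factors

ABBRS = registry.abbreviations()
IDX = {a: j for j, a in enumerate(ABBRS)}


def make_model(contributions, profiles, labels=None):
    contributions = np.asarray(contributions, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    k = profiles.shape[0]
    return FactorModel(
        contributions=contributions, profiles=profiles, q=0.0,
        q_expected=1.0, n_starts=1, best_start=0, n_iterations=0,
        converged=True, congener_r2=np.ones(16),
        standardized_residuals=np.zeros_like(contributions @ profiles),
        labels=labels,
    )


def profile_row(**mass):
    row = np.zeros(16)
    for abbr, v in mass.items():
        row[IDX[abbr]] = v
    return row / row.sum()


class TestApportionment:
    def test_single_factor_equals_reconstruction(self):
        model = make_model([[2.0], [3.0]], profile_row(Nap=1.0)[None, :])
        parts = apportion_concentrations(model)
        np.testing.assert_array_equal(parts[0], model.reconstruction())

    def test_parts_sum_to_reconstruction(self, recovery_model):
        parts = apportion_concentrations(recovery_model)
        np.testing.assert_allclose(parts.sum(axis=0),
                                   recovery_model.reconstruction(), rtol=1e-12)

    def test_noiseless_ground_truth_decomposition(self):
        # with disjoint-support profiles and pure samples the factorization is
        # essentially unique, so the fitted g·f terms match the generator's
        rng = np.random.default_rng(11)
        profiles = np.zeros((4, 16))
        for h in range(4):
            profiles[h, 4 * h:4 * h + 4] = [0.4, 0.3, 0.2, 0.1]
        g = rng.lognormal(1.0, 1.0, (30, 4))
        g[:4] = np.diag([8.0, 6.0, 4.0, 2.0])  # pure samples pin the solution
        x = g @ profiles
        u = 0.1 * x + 0.05
        model = fit_pmf(x, u, 4, n_starts=4, seed=11, max_iter=60000, tol=1e-12)
        perm, sims = match_factors(model.profiles, profiles)
        assert min(sims) > 0.9999
        parts = apportion_concentrations(model)
        col_scale = x.max(axis=0)
        for h in range(4):
            true_part = np.outer(g[:, perm[h]], profiles[perm[h]])
            dev = np.abs(parts[h] - true_part) / col_scale
            assert dev.max() < 1e-4


class TestAttributeRisk:
    def test_single_factor_gets_all_risk(self):
        model = make_model([[2.0], [3.0]], profile_row(Nap=0.7, BaP=0.3)[None, :])
        att = attribute_risk(model)
        assert att.hi_share[0] == pytest.approx(100.0)
        assert att.tilcr_share[0] == pytest.approx(100.0)

    def test_shares_close_to_100(self, recovery_model, carc_params):
        for mode in ("pooled", "mean_share"):
            att = attribute_risk(recovery_model, carc_params, mode=mode)
            assert att.hi_share.sum() == pytest.approx(100.0, abs=1e-6)
            assert att.tilcr_share.sum() == pytest.approx(100.0, abs=1e-6)
            assert np.all(att.hi_share >= 0) and np.all(att.tilcr_share >= 0)

    def test_toy_shares_match_hand_computation(self, carc_params):
        # factor A carries the potent carcinogens, factor B the bulk mass
        fa = profile_row(DahA=0.5, BaP=0.5)
        fb = profile_row(Nap=0.8, Phe=0.2)
        g = np.array([[1.0, 2.0], [3.0, 4.0]])
        model = make_model(g, np.vstack([fa, fb]), labels=["carc", "bulk"])
        att = attribute_risk(model, carc_params)

        # independent hand computation from TEF/RfD weights
        tef = registry.tef_vector()
        rfd = registry.rfd_vector()
        mass_a = g[:, 0].sum() * fa
        mass_b = g[:, 1].sum() * fb
        hi_a, hi_b = (mass_a / rfd).sum(), (mass_b / rfd).sum()
        ti_a, ti_b = (mass_a * tef).sum(), (mass_b * tef).sum()
        assert att.hi_share[0] == pytest.approx(100 * hi_a / (hi_a + hi_b), rel=1e-9)
        assert att.tilcr_share[0] == pytest.approx(100 * ti_a / (ti_a + ti_b), rel=1e-9)
        # TEF weighting concentrates carcinogenic risk in factor A
        assert att.tilcr_share[0] > att.hi_share[0]

    def test_scale_invariance(self, carc_params):
        fa = profile_row(DahA=0.5, BaP=0.5)
        fb = profile_row(Nap=0.8, Phe=0.2)
        g = np.array([[1.0, 2.0], [3.0, 4.0]])
        m1 = make_model(g, np.vstack([fa, fb]))
        m2 = make_model(g * 10.0, np.vstack([fa, fb]))
        a1, a2 = attribute_risk(m1, carc_params), attribute_risk(m2, carc_params)
        np.testing.assert_allclose(a1.hi_share, a2.hi_share, rtol=1e-12)
        np.testing.assert_allclose(a1.tilcr_share, a2.tilcr_share, rtol=1e-12)

    def test_zero_risk_rejected(self, carc_params):
        model = make_model(np.zeros((2, 2)), np.vstack([
            profile_row(Nap=1.0), profile_row(Phe=1.0)]))
        with pytest.raises(ValueError, match="zero total risk"):
            attribute_risk(model, carc_params)


class TestRingShares:
    def test_survey_means_ring_dominances(self, survey_means, carc_params):
        table = ring_class_risk_shares(survey_means, carc_params)
        assert table["hi_share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert table["tilcr_share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        by_ring = table.set_index("ring_class")
        # low-ring mass drives the hazard index ...
        assert by_ring["hi_share_pct"].idxmax() == 2
        # ... while the potent five-ring congeners dominate carcinogenic risk
        assert by_ring["tilcr_share_pct"].idxmax() == 5
        assert by_ring.loc[5, "tilcr_share_pct"] > 50.0

    def test_single_congener_input(self, carc_params):
        vec = np.zeros(16)
        vec[IDX["BaP"]] = 3.0
        table = ring_class_risk_shares(vec, carc_params).set_index("ring_class")
        assert table.loc[5, "hi_share_pct"] == pytest.approx(100.0)
        assert table.loc[5, "tilcr_share_pct"] == pytest.approx(100.0)

    def test_matrix_input_pools_samples(self, carc_params):
        conc = synthetic.generate_from_survey(50, seed=2)
        table = ring_class_risk_shares(conc, carc_params)
        assert table["hi_share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
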