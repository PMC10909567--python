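import warnings

import numpy as np
import pytest

from coralipm import vital_rates
from coralipm.data_io import ColonyObservation, RecruitSurvey, FecundityRecord
from coralipm.synthetic import GenerativeParams, simulate_survey
from coralipm.vital_rates import (SeparationWarning, estimate_settlement,
                                  fit_growth, fit_recruit_sizes, fit_survival,
                                  fit_fragmentation, fit_fecundity,
                                  rates_from_params)


def _mk_obs(sizes, survived=None, sizes_t1=None):
    out = []
    for i, s in enumerate(sizes):
        sv = True if survived is None else survived[i]
        s1 = None
        if sv:
            s1 = s if sizes_t1 is None else sizes_t1[i]
        out.append(ColonyObservation(f"C{i}", "AT", "S1", "G", "weedy", 2016,
                                     float(s), sv, s1))
    return out


class TestSurvival:
    def test_all_survived_raises_separation_flag(self):
        obs = _mk_obs(np.linspace(2, 50, 40))
        with pytest.warns(SeparationWarning):
            model = fit_survival(obs)
        assert model.separation

    def test_predictions_bounded(self, fitted_rates):
        z = np.linspace(-5, 15, 200)
        p = fitted_rates.survival.prob(z)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_irls_matches_statsmodels(self, assemblage):
        _, obs, _, _ = assemblage
        a = fit_survival(obs, engine="statsmodels")
        b = fit_survival(obs, engine="irls")
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-7)
        np.testing.assert_allclose(a.cov, b.cov, rtol=1e-5)


class TestGrowth:
    def test_identity_growth_recovered_exactly(self):
        sizes = np.linspace(2, 80, 60)
        model = fit_growth(_mk_obs(sizes))
        np.testing.assert_allclose(model.coef, [0.0, 1.0, 0.0], atol=1e-8)
        assert model.sd(3.0)[0] < 1e-8

    def test_quadratic_term_recovered(self):
        rng = np.random.default_rng(0)
        p = GenerativeParams(b0=0.4, b1=0.9, b2=-0.02, growth_sd=0.3,
                             a0=20.0, a1=0.0, c0=-30.0,
                             n_colonies=5000, n_years=2, seed=17)
        obs, _ = simulate_survey(p)
        model = fit_growth(obs)
        se = np.sqrt(np.diag(model.cov))
        for est, s, true in zip(model.coef, se, (0.4, 0.9, -0.02)):
            assert abs(est - true) <= 2.6 * s

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_growth(_mk_obs([2.0, 3.0, 4.0]))

    def test_loglinear_sd_option(self, assemblage):
        _, obs, _, _ = assemblage
        m = fit_growth(obs, sd_model="loglinear")
        assert np.all(m.sd(np.linspace(0, 8, 20)) > 0)

    def test_site_random_intercept_small_shift(self, assemblage):
        # balanced synthetic data: marginal predictions barely move
        _, obs, _, _ = assemblage
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixed = fit_growth(obs)
            mixed = fit_growth(obs, site_random_intercept=True)
        z = np.linspace(1, 7, 30)
        rel = np.abs(mixed.mean(z) - fixed.mean(z)) / np.abs(fixed.mean(z))
        assert np.max(rel) < 0.10


class TestFragmentation:
    def test_no_events_gives_zero_probability(self):
        obs = _mk_obs(np.linspace(2, 50, 30))
        with pytest.warns(UserWarning, match="no fragmentation"):
            kappa, kb, kz0 = fit_fragmentation(obs)
        assert kb is None and kz0 is None
        assert np.all(kappa.prob(np.linspace(0, 8, 50)) == 0)

    def test_mean_remnant_count_at_least_one(self, fitted_rates):
        z = np.linspace(0, 9, 100)
        assert np.all(fitted_rates.remnant_count.mean_count(z) >= 1.0)


class TestFecundity:
    def test_noiseless_table_exact(self):
        z = np.linspace(0.5, 6, 40)
        recs = [FecundityRecord("weedy", float(np.exp(zi)),
                                float(np.exp(1.0 + 0.8 * zi - 0.03 * zi ** 2)))
                for zi in z]
        model = fit_fecundity(recs)
        np.testing.assert_allclose(model.coef, [1.0, 0.8, -0.03], atol=1e-6)

    def test_monotone_when_linear_positive(self):
        z = np.linspace(0.5, 6, 40)
        recs = [FecundityRecord("weedy", float(np.exp(zi)),
                                float(np.exp(0.5 + 1.2 * zi)))
                for zi in z]
        model = fit_fecundity(recs)
        pred = model.expected(np.linspace(0.5, 6, 100))
        assert np.all(np.diff(pred) > 0)

    def test_all_zero_outputs_degenerate(self):
        recs = [FecundityRecord("weedy", 10.0, 0.0) for _ in range(20)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_fecundity(recs)


class TestSettlement:
    def _fec_model(self):
        # phi_f(z) = exp(log 100) = 100 larvae per colony, flat in size
        return vital_rates.FecundityModel(np.array([np.log(100.0), 0.0, 0.0]))

    def test_simple_ratio(self):
        obs = _mk_obs([10.0])  # one colony, 100 predicted larvae
        surveys = [RecruitSurvey("AT", "S1", 2016, 10, tuple([1.0] * 10))]
        st = estimate_settlement(surveys, self._fec_model(), obs)
        assert st.pooled == pytest.approx(0.1)

    def test_zero_recruits_warns_phi_zero(self):
        obs = _mk_obs([10.0])
        surveys = [RecruitSurvey("AT", "S1", 2016, 0, ())]
        with pytest.warns(UserWarning, match="zero recruits"):
            st = estimate_settlement(surveys, self._fec_model(), obs)
        assert st.pooled == 0.0

    def test_poisson_ratio_estimator_recovers_truth(self):
        p = GenerativeParams(phi_true=0.02, f0=0.5, f1=0.5,
                             n_colonies=3000, n_years=4, seed=23)
        obs, recruits = simulate_survey(p)
        model = vital_rates.FecundityModel(np.array([p.f0, p.f1, p.f2]))
        st = estimate_settlement(recruits, model, obs)
        assert abs(st.pooled - 0.02) <= 0.005


class TestRecruitSizes:
    def test_sd_floor_applied(self):
        surveys = [RecruitSurvey("AT", "S1", 2016, 6, tuple([2.0] * 6))]
        c0 = fit_recruit_sizes(surveys)
        assert c0.sd == vital_rates.RECRUIT_SD_FLOOR

    def test_recovery(self):
        rng = np.random.default_rng(2)
        sizes = tuple(np.exp(rng.normal(1.0, 0.4, 2000)))
        c0 = fit_recruit_sizes([RecruitSurvey("AT", "S1", 2016, 2000, sizes)])
        assert abs(c0.mu - 1.0) < 0.03
        assert abs(c0.sd - 0.4) < 0.03

    def test_too_few_sizes_instructs_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            fit_recruit_sizes([RecruitSurvey("AT", "S1", 2016, 2,
                                             (1.0, 2.0))])


class TestSerialization:
    def test_json_round_trip(self, fitted_rates, tmp_path):
        path = tmp_path / "rates.json"
        fitted_rates.to_json(path)
        back = vital_rates.VitalRateSet.from_json(path)
        np.testing.assert_allclose(back.survival.coef,
                                   fitted_rates.survival.coef)
        np.testing.assert_allclose(back.growth.sd_coef,
                                   fitted_rates.growth.sd_coef)
        assert back.settlement.yearly == fitted_rates.settlement.yearly
        assert back.size_range == fitted_rates.size_range

    def test_true_rates_from_params(self):
        p = GenerativeParams()
        rates = rates_from_params(p, (2.0, 500.0))
        z = np.linspace(1, 6, 10)
        np.testing.assert_allclose(
            rates.survival.logit(z), p.a0 + p.a1 * z)
        assert rates.settlement.pooled == p.phi_true
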