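"""Friberg-Karlsson dynamics, measurement densities, and population terms."""

import numpy as np
import pytest
from scipy import integrate as sci_integrate
from scipy import stats

from pmxbayes.models import (
    EPS,
    FKParams,
    allometric_params,
    fk_rhs,
    ktr_to_mtt,
    lognormal_loglik,
    mtt_to_ktr,
    population_logprior,
    predicted_concentration,
)
from pmxbayes.odes import OdeSettings, integrate
from pmxbayes.solvers import OneCptParams, TwoCptParams

from conftest import FK_TRUTH, TRUTH


class TestTransitRate:
    def test_reference_values(self):
        assert mtt_to_ktr(125.0) == pytest.approx(0.032)
        assert mtt_to_ktr(4.0) == pytest.approx(1.0)

    def test_roundtrip(self):
        assert ktr_to_mtt(mtt_to_ktr(87.3)) == pytest.approx(87.3, rel=1e-12)

    def test_nonpositive_mtt_rejected(self):
        with pytest.raises(ValueError):
            mtt_to_ktr(0.0)


class TestFkRhs:
    def test_baseline_is_drug_free_equilibrium(self):
        dy = fk_rhs(0.0, np.zeros(5), np.zeros(3), FK_TRUTH, TRUTH.Vcent)
        assert dy == pytest.approx(np.zeros(5), abs=1e-15)

    def test_saturated_drug_effect_shuts_down_proliferation(self):
        # chat >= 1/alpha: Edrug caps at 1 and the proliferation term vanishes
        chat = 2.0 / FK_TRUTH.alpha
        y_pk = np.array([0.0, chat * TRUTH.Vcent, 0.0])
        y_pd = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        dy = fk_rhs(0.0, y_pd, y_pk, FK_TRUTH, TRUTH.Vcent)
        expected = -FK_TRUTH.ktr * (y_pd[0] + FK_TRUTH.circ0)
        assert dy[0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_circulating_count_is_floored(self):
        y_pd = np.array([0.0, 0.0, 0.0, 0.0, -2 * FK_TRUTH.circ0])
        dy = fk_rhs(0.0, y_pd, np.zeros(3), FK_TRUTH, TRUTH.Vcent)
        assert np.all(np.isfinite(dy))
        # the feedback saw circ = EPS, not a negative count
        feedback = (FK_TRUTH.circ0 / EPS) ** FK_TRUTH.gamma
        assert dy[0] == pytest.approx(
            FK_TRUTH.ktr * FK_TRUTH.circ0 * (feedback - 1.0), rel=1e-10
        )

    def test_edrug_stays_in_unit_interval(self):
        for chat in (0.0, 0.5 / FK_TRUTH.alpha, 10.0 / FK_TRUTH.alpha):
            y_pk = np.array([0.0, chat * TRUTH.Vcent, 0.0])
            dy = fk_rhs(0.0, np.zeros(5), y_pk, FK_TRUTH, TRUTH.Vcent)
            # at baseline the proliferation derivative is -ktr*circ0*Edrug
            edrug = -dy[0] / (FK_TRUTH.ktr * FK_TRUTH.circ0)
            assert -1e-12 <= edrug <= 1.0 + 1e-12

    def test_perturbed_system_returns_to_baseline_without_drug(self):
        # the weak feedback (gamma 0.17) relaxes slowly: ~40 mean transit
        # times are needed before the residual drops below 1e-6 of baseline
        fk = FKParams(mtt=20.0, circ0=5.0, alpha=0.0, gamma=0.17)
        y0 = np.array([2.0, -1.0, 0.5, 1.0, -0.5])
        horizon = 40.0 * fk.mtt
        y = integrate(
            lambda t, y: fk_rhs(t, y, np.zeros(3), fk, TRUTH.Vcent),
            y0, 0.0, horizon, OdeSettings(rtol=1e-10, atol=1e-12),
        )
        assert np.max(np.abs(y)) < 1e-6 * fk.circ0


class TestMeasurementModel:
    def test_exact_prediction_leaves_only_normalizing_terms(self):
        y = 3.7
        sigma = 0.25
        got = lognormal_loglik(y, y, sigma)
        want = -np.log(y) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        assert got == pytest.approx(want, rel=1e-12)

    def test_additivity_over_observations(self, rng):
        y = rng.lognormal(1.0, 0.3, size=7)
        yhat = rng.lognormal(1.0, 0.3, size=7)
        total = lognormal_loglik(y, yhat, 0.2)
        parts = sum(lognormal_loglik(yi, yh, 0.2) for yi, yh in zip(y, yhat))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_matches_scipy_lognorm(self, rng):
        y = rng.lognormal(0.5, 0.4, size=11)
        yhat = rng.lognormal(0.5, 0.4, size=11)
        sigma = 0.3
        want = stats.lognorm.logpdf(y, s=sigma, scale=yhat).sum()
        assert lognormal_loglik(y, yhat, sigma) == pytest.approx(want, rel=1e-12)

    def test_density_integrates_to_one(self):
        yhat, sigma = 4.0, 0.35
        val, _ = sci_integrate.quad(
            lambda y: np.exp(lognormal_loglik(y, yhat, sigma)), 1e-9, 200.0, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_sigma_mle_is_root_mean_squared_log_residual(self, rng):
        y = rng.lognormal(1.0, 0.5, size=40)
        yhat = np.full(40, np.exp(1.0))
        mle = np.sqrt(np.mean((np.log(y) - np.log(yhat)) ** 2))
        grid = np.linspace(0.5 * mle, 2.0 * mle, 401)
        lls = [lognormal_loglik(y, yhat, s) for s in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(mle, rel=1e-2)

    @pytest.mark.parametrize(
        "y, yhat, match",
        [(-1.0, 2.0, "observations"), (2.0, 0.0, "predictions")],
    )
    def test_nonpositive_inputs_get_distinct_messages(self, y, yhat, match):
        with pytest.raises(ValueError, match=match):
            lognormal_loglik(y, yhat, 0.2)


class TestPredictedConcentration:
    def test_amount_over_volume(self):
        amounts = np.array([[0.0, 0.0], [400.0, 200.0], [0.0, 0.0]])
        got = predicted_concentration(amounts, 40.0, np.array([0, 1]))
        assert got == pytest.approx([10.0, 5.0])

    def test_empty_view_gives_empty_vector(self):
        amounts = np.zeros((3, 4))
        assert predicted_concentration(amounts, 40.0, np.array([], dtype=int)).size == 0

    def test_linearity_in_inverse_volume(self):
        amounts = np.random.default_rng(0).uniform(1, 100, size=(3, 6))
        obs = np.arange(6)
        c1 = predicted_concentration(amounts, 20.0, obs)
        c2 = predicted_concentration(amounts, 40.0, obs)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)


class TestAllometry:
    def test_reference_weight_is_identity(self):
        scaled = allometric_params(TRUTH, 70.0)
        assert scaled == TRUTH

    def test_doubled_weight_power_laws(self):
        scaled = allometric_params(TRUTH, 140.0)
        assert scaled.CL == pytest.approx(TRUTH.CL * 2**0.75, rel=1e-12)
        assert scaled.Q == pytest.approx(TRUTH.Q * 2**0.75, rel=1e-12)
        assert scaled.Vcent == pytest.approx(TRUTH.Vcent * 2.0, rel=1e-12)
        assert scaled.Vperi == pytest.approx(TRUTH.Vperi * 2.0, rel=1e-12)

    def test_absorption_rate_is_never_scaled(self):
        for w in (40.0, 70.0, 120.0):
            assert allometric_params(TRUTH, w).ka == TRUTH.ka

    def test_one_compartment_variant(self):
        p = OneCptParams(CL=8.0, Vcent=30.0, ka=1.5)
        scaled = allometric_params(p, 35.0)
        assert scaled.CL == pytest.approx(8.0 * 0.5**0.75, rel=1e-12)
        assert scaled.Vcent == pytest.approx(15.0, rel=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            allometric_params(TRUTH, 0.0)


class TestPopulationLogPrior:
    def test_typical_subject_hits_the_mode_offset(self):
        theta_pop = np.array([10.0, 15.0, 35.0])
        omega = np.array([0.2, 0.3, 0.25])
        got = population_logprior(theta_pop[None, :], theta_pop, omega)
        want = np.sum(-np.log(theta_pop) - np.log(omega) - 0.5 * np.log(2 * np.pi))
        assert got == pytest.approx(want, rel=1e-12)

    def test_matches_scipy_lognorm_sum(self, rng):
        theta_pop = np.array([10.0, 15.0, 35.0, 105.0, 2.0])
        omega = np.array([0.25, 0.4, 0.25, 0.4, 0.5])
        theta = rng.lognormal(np.log(theta_pop), omega, size=(6, 5))
        want = stats.lognorm.logpdf(theta, s=omega, scale=theta_pop).sum()
        got = population_logprior(theta, theta_pop, omega)
        assert got == pytest.approx(want, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            population_logprior(np.ones((2, 3)), np.ones(4), np.ones(4))
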