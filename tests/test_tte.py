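"""Log-logistic TTE model: hazard identities, covariate scale, censored ML."""

import numpy as np
import pandas as pd
import pytest
from lifelines import LogLogisticFitter
from scipy.integrate import quad

from tgitte.synthetic import generate_events
from tgitte.tte import (
    FAMILIES,
    CovariateSet,
    ParametricTTEEstimator,
    TTEParameters,
    fit_tte,
    hazard,
    individual_scale,
    loglik_tte,
    simulate_events,
    survival,
)


def make_covset(n=6, lambda0=0.0063, lambda1=5.93, cavg=None):
    cavg = cavg if cavg is not None else np.zeros(n)
    return CovariateSet(
        data=pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(n)],
                "lambda0": np.full(n, lambda0),
                "lambda1": np.full(n, lambda1),
                "cavg": cavg,
            }
        )
    )


class TestHazardSurvival:
    def test_loglogistic_values(self):
        te = 703.17
        assert hazard(0.0, te, 4.0) == 0.0
        assert hazard(te, te, 4.0) == pytest.approx(2.0 / te, rel=1e-12)
        assert hazard(0.0, te, 1.0) == pytest.approx(1.0 / te, rel=1e-12)

    def test_survival_median_identity(self):
        """S(Te) = 1/2 exactly: the scale is the median event time."""
        for s in (0.5, 1.0, 4.0, 9.0):
            assert survival(0.0, 703.17, s) == 1.0
            assert survival(703.17, 703.17, s) == pytest.approx(0.5, rel=1e-14)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_hazard_integrates_to_log_survival(self, family):
        """Quadrature of h(t) must reproduce -log S(t) to 1e-8."""
        te, s = 500.0, 4.0 if family != "gompertz" else 1.5
        for t in (50.0, 250.0, 500.0, 1800.0):
            cum, _ = quad(lambda u: hazard(u, te, s, family), 0.0, t, limit=400)
            assert -np.log(survival(t, te, s, family)) == pytest.approx(cum, abs=1e-8)

    def test_survival_strictly_decreasing(self):
        t = np.linspace(0.0, 3000.0, 100)
        sv = survival(t, 700.0, 4.0)
        assert np.all(np.diff(sv) < 0)


class TestIndividualScale:
    def test_neutral_covariates_return_te_pop(self):
        p = TTEParameters(te_pop=703.17, beta_lambda0=-0.75, beta_lambda1=-0.46, beta_cavg=0.63)
        cov = make_covset(3)
        te = individual_scale(p, cov)
        np.testing.assert_allclose(te, 703.17, rtol=1e-12)

    def test_doubled_growth_rate_multiplier(self):
        """lambda0 at twice its median with beta = -0.75 scales Te by exp(-0.75)."""
        p = TTEParameters(te_pop=703.17, beta_lambda0=-0.75)
        cov = make_covset(3)
        cov.data.loc[0, "lambda0"] = 2 * cov.medians["lambda0"]
        te = individual_scale(p, cov)
        assert te[0] == pytest.approx(703.17 * np.exp(-0.75), rel=1e-10)
        assert te[1] == pytest.approx(703.17, rel=1e-10)

    def test_cavg_term_not_centered(self):
        """The exposure term is ratio-scaled without the -1 offset, so
        Cavg at its median multiplies Te by exp(beta) ~ 1.878."""
        p = TTEParameters(te_pop=100.0, beta_cavg=0.63)
        cov = make_covset(4, cavg=np.array([0.0, 300.0, 300.0, 600.0]))
        te = individual_scale(p, cov)
        assert cov.medians["cavg"] == 300.0
        assert te[1] == pytest.approx(100.0 * np.exp(0.63), rel=1e-10)
        assert np.exp(0.63) == pytest.approx(1.878, abs=1e-3)
        assert te[0] == pytest.approx(100.0, rel=1e-10)  # vehicle multiplier 1

    def test_missing_subject_covariates_error(self):
        p = TTEParameters(te_pop=100.0)
        cov = make_covset(2)
        with pytest.raises(KeyError):
            cov.aligned(["S0", "S9"])


class TestLoglik:
    def test_single_censored_subject(self):
        p = TTEParameters(te_pop=500.0, shape_s=4.0)
        events = pd.DataFrame({"subject": ["S0"], "time": [800.0], "status": [0]})
        expected = -np.log(1 + (800.0 / 500.0) ** 4)
        assert loglik_tte(p, events) == pytest.approx(expected, rel=1e-12)

    def test_single_event_at_scale(self):
        """At t = Te: log h + log S = log(2/Te) + log(1/2)."""
        te = 500.0
        p = TTEParameters(te_pop=te, shape_s=4.0)
        events = pd.DataFrame({"subject": ["S0"], "time": [te], "status": [1]})
        assert loglik_tte(p, events) == pytest.approx(np.log(2.0 / te) + np.log(0.5), rel=1e-12)

    def test_censored_likelihood_increases_with_te(self):
        events = pd.DataFrame({"subject": ["S0"], "time": [800.0], "status": [0]})
        lls = [
            loglik_tte(TTEParameters(te_pop=te), events) for te in (300.0, 800.0, 3000.0)
        ]
        assert lls[0] < lls[1] < lls[2]

    def test_frailty_marginal_matches_zero_omega_limit(self):
        events = pd.DataFrame(
            {"subject": ["S0", "S1"], "time": [300.0, 700.0], "status": [1, 0]}
        )
        base = loglik_tte(TTEParameters(te_pop=500.0), events)
        tiny = loglik_tte(TTEParameters(te_pop=500.0, omega_te=1e-5), events)
        assert tiny == pytest.approx(base, abs=1e-6)


class TestSimulation:
    def test_median_u_gives_scale(self):
        """Inverse CDF at u = 1/2 is exactly Te."""
        te = 703.17
        assert te * (1.0 / 0.5 - 1.0) ** (1.0 / 4.0) == pytest.approx(te)

    def test_empirical_median_near_scale(self):
        p = TTEParameters(te_pop=700.0, shape_s=4.0)
        cov = make_covset(4000)
        events = simulate_events(p, cov, censor_time=1e7, seed=7)
        assert events["status"].eq(1).all()
        assert np.median(events["time"]) == pytest.approx(700.0, rel=0.05)

    def test_tiny_censor_time_censors_everyone(self):
        p = TTEParameters(te_pop=700.0)
        cov = make_covset(50)
        events = simulate_events(p, cov, censor_time=1e-6, seed=1)
        assert events["status"].eq(0).all()

    def test_seed_determinism(self):
        p = TTEParameters(te_pop=700.0, omega_te=0.2)
        cov = make_covset(30)
        a = simulate_events(p, cov, censor_time=2400.0, seed=5)
        b = simulate_events(p, cov, censor_time=2400.0, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestFitting:
    def test_no_covariate_recovery_and_lifelines_crosscheck(self):
        """ML scale estimate vs an independent log-logistic fitter."""
        p = TTEParameters(te_pop=700.0, shape_s=4.0)
        cov = make_covset(500)
        events = simulate_events(p, cov, censor_time=2400.0, seed=11)
        est = ParametricTTEEstimator(
            with_covariates=False, frailty="none", estimate_shape=True
        ).fit(events)
        assert est.params_.te_pop == pytest.approx(700.0, rel=0.1)
        llf = LogLogisticFitter().fit(events["time"], events["status"])
        # lifelines alpha_ is the scale, beta_ the shape
        assert est.params_.te_pop == pytest.approx(llf.alpha_, rel=1e-3)
        assert est.params_.shape_s == pytest.approx(llf.beta_, rel=1e-3)

    def test_covariate_signs_recovered(self):
        """Negative growth-rate and positive exposure coefficients, as in
        the fitted covariate model."""
        truth = TTEParameters(
            te_pop=703.17,
            beta_lambda0=-0.75,
            beta_lambda1=-0.46,
            beta_cavg=0.63,
            omega_te=0.043,
        )
        events, cov = generate_events(truth, n=300, censor_time=2400.0, seed=3)
        fit = fit_tte(events, cov=cov, frailty="none")
        assert fit.estimates["beta_lambda0"] < 0
        assert fit.estimates["beta_lambda1"] < 0
        assert fit.estimates["beta_cavg"] > 0
        assert fit.estimates["te_pop"] == pytest.approx(703.17, rel=0.15)

    def test_family_screen_prefers_generating_family(self):
        """Exponential fits of log-logistic data lose the AIC comparison."""
        p = TTEParameters(te_pop=700.0, shape_s=4.0)
        cov = make_covset(300)
        events = simulate_events(p, cov, censor_time=5000.0, seed=23)
        fits = [
            fit_tte(events, family=f, with_covariates=False, frailty="none", estimate_shape=True)
            for f in ("loglogistic", "exponential")
        ]
        assert fits[0].aic < fits[1].aic

    def test_loglik_scale_invariance(self):
        """Scaling all times and Te by c shifts the loglik by -n_events*log(c)
        (the Jacobian of the time rescaling), leaving the maximizer scaled."""
        rng = np.random.default_rng(0)
        times = rng.uniform(100.0, 900.0, 40)
        status = rng.integers(0, 2, 40)
        ev = pd.DataFrame({"subject": [f"S{i}" for i in range(40)], "time": times, "status": status})
        ev2 = ev.assign(time=ev["time"] * 10.0)
        ll1 = loglik_tte(TTEParameters(te_pop=500.0), ev)
        ll2 = loglik_tte(TTEParameters(te_pop=5000.0), ev2)
        assert ll2 == pytest.approx(ll1 - status.sum() * np.log(10.0), rel=1e-10)

    def test_needs_at_least_one_event(self):
        ev = pd.DataFrame({"subject": ["a", "b"], "time": [10.0, 20.0], "status": [0, 0]})
        with pytest.raises(ValueError, match="at least one event"):
            ParametricTTEEstimator(with_covariates=False).fit(ev)

    def test_sklearn_get_set_params(self):
        est = ParametricTTEEstimator(family="weibull")
        params = est.get_params()
        assert params["family"] == "weibull"
        est.set_params(family="loglogistic", shape=4.0)
        assert est.family == "loglogistic"
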