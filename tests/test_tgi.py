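"""Simeoni TGI model: growth-rate limits, ODE simulation, event detection."""

import numpy as np
import pytest
from scipy.integrate import quad

from tgitte.pk import PKParameters, make_regimen
from tgitte.tgi import (
    TGIParameters,
    Trajectory,
    growth_rate,
    natural_growth_rate,
    simulate_trajectory,
    time_to_threshold,
)

PK = PKParameters(clearance=100.0, volume_dist=150.0)
# published typical values of the fitted model
L0, L1, K = 0.0063, 5.93, 2.4e-5


class TestGrowthRate:
    def test_exponential_limit_below_switch(self):
        """Far below the switch volume the rate is lambda0 * TV.

        At TV = 0.01 * lambda1/lambda0 the correction is (0.01)^20."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=1.0)
        tv = 0.01 * p.switch_volume
        assert growth_rate(tv, 0.0, p) == pytest.approx(L0 * tv, rel=1e-12)

    def test_rate_at_switch_volume(self):
        """At TV = lambda1/lambda0 the bracket is (1+1)^(1/20)."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=1.0)
        tv = p.switch_volume
        assert growth_rate(tv, 0.0, p) == pytest.approx(L0 * tv / 2 ** (1 / 20), rel=1e-12)

    def test_linear_limit_above_switch(self):
        """With the published rates the switch is near 941 mm3 and the
        unperturbed rate plateaus at lambda1 = 5.93 mm3/h."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=1.0)
        assert p.switch_volume == pytest.approx(941.27, abs=0.01)
        assert growth_rate(50000.0, 0.0, p) == pytest.approx(L1, rel=1e-3)

    def test_kill_term_linear_in_concentration(self):
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=K, tv0=1.0)
        tv, cp = 500.0, 300.0
        base = growth_rate(tv, 0.0, p)
        assert growth_rate(tv, cp, p) == pytest.approx(base - K * cp * tv, rel=1e-12)

    def test_michaelis_menten_effect_saturates(self):
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=0.01, tv0=1.0, kc50=100.0)
        tv = 500.0
        r_low = growth_rate(tv, 0.0, p) - growth_rate(tv, 1e6, p)
        # at Cp >> KC50 the effect approaches kill * TV
        assert r_low == pytest.approx(0.01 * tv, rel=1e-3)

    def test_nonpositive_volume_rejected(self):
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=1.0)
        with pytest.raises(ValueError):
            growth_rate(0.0, 0.0, p)


class TestNaturalGrowth:
    def test_exponential_direct_product(self):
        assert natural_growth_rate(100.0, 0.0, {"lambda0": 0.0063}, "exponential") == pytest.approx(0.63)

    def test_koch_limits(self):
        """Koch growth is ~2*lambda0*TV at small TV and plateaus at lambda1."""
        params = {"lambda0": 0.005, "lambda1": 6.0}
        tiny = 1e-4
        assert natural_growth_rate(tiny, 0.0, params, "koch") == pytest.approx(
            2 * 0.005 * tiny, rel=1e-6
        )
        assert natural_growth_rate(1e9, 0.0, params, "koch") == pytest.approx(6.0, rel=1e-5)

    def test_simeoni_consistent_with_growth_rate(self):
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=0.0, tv0=1.0)
        for tv in (10.0, 500.0, 941.0, 3000.0):
            assert natural_growth_rate(
                tv, 0.0, {"lambda0": L0, "lambda1": L1}, "simeoni"
            ) == pytest.approx(growth_rate(tv, 0.0, p), rel=1e-12)

    def test_quadratic_is_polynomial_in_time(self):
        # TV(t) = TV0 + l0 t + l1 t^2 -> dTV/dt = l0 + 2 l1 t
        params = {"lambda0": 2.0, "lambda1": 0.05}
        assert natural_growth_rate(100.0, 10.0, params, "quadratic") == pytest.approx(3.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown growth model"):
            natural_growth_rate(1.0, 0.0, {"lambda0": 1.0}, "gompertzian")


class TestSimulation:
    def test_exponential_phase_closed_form(self):
        """Below the switch volume growth is exponential within 0.5%."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=50.0)
        times = np.linspace(0.0, 300.0, 11)
        traj = simulate_trajectory(p, None, None, times)
        expected = 50.0 * np.exp(L0 * times)
        np.testing.assert_allclose(traj.volumes, expected, rtol=5e-3)

    def test_linear_phase_closed_form(self):
        """Far above the switch, TV grows as tv0 + lambda1 * t within 0.5%."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=20000.0)
        times = np.linspace(0.0, 500.0, 11)
        traj = simulate_trajectory(p, None, None, times)
        expected = 20000.0 + L1 * times
        np.testing.assert_allclose(traj.volumes, expected, rtol=5e-3)

    def test_separable_quadrature_oracle(self):
        """For kill = 0 the ODE is separable: t(TV) = integral dv/(v g(v)).

        High-resolution quadrature of the inverse problem must agree
        with the forward solver to < 0.1%."""
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=200.0)

        def inv_rate(v):
            x = (L0 / L1) * v
            return (1 + x**20) ** (1 / 20) / (L0 * v)

        for target in (500.0, 941.0, 1500.0, 3000.0):
            t_expected, _ = quad(inv_rate, 200.0, target, limit=200)
            traj = simulate_trajectory(p, None, None, np.array([0.0, t_expected]))
            assert traj.volumes[-1] == pytest.approx(target, rel=1e-3)

    def test_backends_agree(self):
        reg = make_regimen("d", 2.4, "Q3dx6")
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=K, tv0=150.0)
        times = np.linspace(0.0, 1200.0, 26)
        a = simulate_trajectory(p, PK, reg, times, backend="numba")
        b = simulate_trajectory(p, PK, reg, times, backend="scipy")
        np.testing.assert_allclose(a.volumes, b.volumes, rtol=1e-5)

    def test_tolerance_halving_changes_little(self):
        reg = make_regimen("d", 0.9, "Q1dx5")
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=K, tv0=150.0)
        times = np.linspace(0.0, 2000.0, 21)
        a = simulate_trajectory(p, PK, reg, times, rtol=1e-8, atol=1e-10)
        b = simulate_trajectory(p, PK, reg, times, rtol=5e-9, atol=5e-11)
        np.testing.assert_allclose(a.volumes, b.volumes, rtol=1e-3)

    def test_positive_everywhere_and_strong_kill_shrinks(self):
        """When kill dominates growth the tumor regresses but stays positive."""
        reg = make_regimen("d", 0.9, "Q1dx5")
        p = TGIParameters(lambda0=L0, lambda1=L1, kill=2e-4, tv0=150.0)
        times = np.arange(0.0, 121.0, 24.0)
        traj = simulate_trajectory(p, PK, reg, times)
        assert np.all(traj.volumes > 0)
        assert np.all(np.diff(traj.volumes) < 0)  # shrinks at every dosing day

    def test_monotone_in_kill_and_dose(self):
        """Pointwise ordering: more kill or more dose never grows more."""
        times = np.linspace(0.0, 800.0, 17)
        reg = make_regimen("d", 0.9, "Q1dx5")
        lo = simulate_trajectory(
            TGIParameters(lambda0=L0, lambda1=L1, kill=1e-5, tv0=150.0), PK, reg, times
        )
        hi = simulate_trajectory(
            TGIParameters(lambda0=L0, lambda1=L1, kill=5e-5, tv0=150.0), PK, reg, times
        )
        assert np.all(hi.volumes <= lo.volumes + 1e-9)

        p = TGIParameters(lambda0=L0, lambda1=L1, kill=K, tv0=150.0)
        d_lo = simulate_trajectory(p, PK, make_regimen("a", 0.3, "Q1dx5"), times)
        d_hi = simulate_trajectory(p, PK, make_regimen("b", 0.9, "Q1dx5"), times)
        assert np.all(d_hi.volumes <= d_lo.volumes + 1e-9)

    def test_times_must_start_at_zero(self):
        p = TGIParameters(lambda0=L0, lambda1=L1, tv0=100.0)
        with pytest.raises(ValueError):
            simulate_trajectory(p, None, None, np.array([24.0, 48.0]))


class TestTimeToThreshold:
    def test_discrete_rule_returns_first_grid_crossing(self):
        traj = Trajectory(times=np.array([0.0, 24.0, 48.0, 72.0]),
                          volumes=np.array([500.0, 1200.0, 1600.0, 2000.0]))
        assert time_to_threshold(traj, 1500.0) == 48.0

    def test_never_reaching_returns_none(self):
        traj = Trajectory(times=np.array([0.0, 24.0]), volumes=np.array([100.0, 200.0]))
        assert time_to_threshold(traj, 1500.0) is None

    def test_exponential_crossing_continuous_vs_closed_form(self):
        """Pure exponential from 100 mm3 at 0.0063/h crosses 1500 mm3 at
        ln(15)/0.0063 ~ 429.9 h; the discrete rule returns the next
        scheduled measurement."""
        # switch far above threshold so growth stays exponential
        p = TGIParameters(lambda0=0.0063, lambda1=5e4, tv0=100.0)
        times = np.arange(0.0, 600.0, 24.0)
        traj = simulate_trajectory(p, None, None, times)
        t_exact = np.log(15.0) / 0.0063
        assert t_exact == pytest.approx(429.9, abs=0.1)
        cont = time_to_threshold(traj, 1500.0, rule="continuous")
        assert cont == pytest.approx(t_exact, rel=1e-3)
        disc = time_to_threshold(traj, 1500.0)
        assert disc == times[np.searchsorted(times, t_exact)]

    def test_invalid_inputs(self):
        traj = Trajectory(times=np.array([0.0]), volumes=np.array([100.0]))
        with pytest.raises(ValueError):
            time_to_threshold(traj, -5.0)
        with pytest.raises(ValueError):
            Trajectory(times=np.array([]), volumes=np.array([]))
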