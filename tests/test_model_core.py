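import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fraximm.model_core import (
    DEFAULT_PARAMS,
    ModelParams,
    Trajectory,
    TreatmentSchedule,
    TumorState,
    daily_update,
    gompertz_step,
    lq_survival,
    simulate,
)


def gompertz_numeric(C, a, K, dt):
    """Fine-step numerical integration of dC/dt = a*C*ln(K/C)."""
    sol = solve_ivp(
        lambda _, y: a * y * np.log(K / y),
        (0.0, dt),
        [C],
        rtol=1e-10,
        atol=1e-14,
        dense_output=True,
    )
    return float(sol.y[0, -1])


class TestGompertzStep:
    @pytest.mark.parametrize(
        "C,a,K,dt,expected",
        [
            (50.0, 0.2, 50.0, 1.0, 50.0),  # fixed point at carrying capacity
            (7.3, 0.0, 100.0, 5.0, 7.3),  # zero growth rate
            (1.0, 0.1, 100.0, 1.0, 100.0 * (1 / 100.0) ** math.exp(-0.1)),
        ],
    )
    def test_known_values(self, C, a, K, dt, expected):
        assert gompertz_step(C, a, K, dt) == pytest.approx(expected, rel=1e-12)

    def test_one_day_growth_from_unit_size(self):
        # frozen value from the closed form, cross-checked by integration
        assert gompertz_step(1.0, 0.1, 100.0, 1.0) == pytest.approx(1.550, abs=5e-4)
        assert gompertz_step(1.0, 0.1, 100.0, 1.0) == pytest.approx(
            gompertz_numeric(1.0, 0.1, 100.0, 1.0), rel=1e-8
        )

    @pytest.mark.parametrize("C,K", [(0.0, 10.0), (-1.0, 10.0), (1.0, 0.0)])
    def test_domain_errors(self, C, K):
        with pytest.raises(ValueError):
            gompertz_step(C, 0.1, K)

    @given(
        C=st.floats(0.001, 500.0),
        a=st.floats(0.0, 1.0),
        K=st.floats(1.0, 500.0),
        dt=st.floats(0.0, 10.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_numerical_integration(self, C, a, K, dt):
        expected = gompertz_numeric(C, a, K, dt)
        assert gompertz_step(C, a, K, dt) == pytest.approx(expected, rel=1e-6)

    @given(C=st.floats(0.01, 99.0))
    @settings(max_examples=30, derandomize=True)
    def test_stays_in_unit_interval_below_capacity(self, C):
        out = gompertz_step(C, 0.3, 100.0, 1.0)
        assert C < out <= 100.0


class TestLQSurvival:
    def test_zero_dose_full_survival(self):
        assert lq_survival(0.0, 0.2, 0.02) == 1.0

    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(0.2, 0.02, math.exp(-2.88)), (0.3, 0.03, math.exp(-4.32))],
    )
    def test_eight_gray(self, alpha, beta, expected):
        assert lq_survival(8.0, alpha, beta) == pytest.approx(expected, rel=1e-12)
        assert 0 < lq_survival(8.0, alpha, beta) < 1

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_survival(-1.0, 0.2, 0.02)

    def test_strictly_decreasing_in_dose(self):
        doses = np.linspace(0, 20, 11)
        surv = [lq_survival(d, 0.2, 0.02) for d in doses]
        assert all(s1 > s2 for s1, s2 in zip(surv, surv[1:]))


class TestDailyUpdate:
    def test_quiescent_state_unchanged(self):
        p = ModelParams(a=0.0, K=100, C0=1, alpha=0.2, beta=0.02, gamma=0.5, mu=0.05, sigma=1)
        out = daily_update(TumorState(0, 10.0, 0.0), p)
        assert out.C == pytest.approx(10.0)
        assert out.I == 0.0
        assert out.day == 1

    def test_immune_decay_and_potentiated_kill(self):
        p = ModelParams(a=0.0, K=100, C0=1, alpha=0.2, beta=0.02, gamma=0.5, mu=0.05, sigma=1)
        out = daily_update(TumorState(0, 10.0, 2.0), p, dose=0.0, mt_active=True)
        assert out.I == pytest.approx(1.0)
        assert out.C == pytest.approx(10.0 * math.exp(-0.1), rel=1e-12)

    def test_radiation_kill_recruits_immune_stimulation(self):
        p = ModelParams(a=0.0, K=100, C0=1, alpha=0.2, beta=0.02, gamma=0.5, mu=0.01, sigma=0)
        out = daily_update(TumorState(0, 10.0, 0.0), p, dose=8.0)
        S = lq_survival(8.0, 0.2, 0.02)
        assert out.I == pytest.approx(10.0 * (1 - S), rel=1e-12)
        assert out.C == pytest.approx(10.0 * S * math.exp(-0.01 * out.I), rel=1e-12)
        # 0.5105 when computed with 4-digit rounded intermediates
        assert out.C == pytest.approx(0.5105, abs=1e-3)


class TestSimulate:
    def test_zero_horizon_single_state(self, params):
        traj = simulate(params, TreatmentSchedule(), 0)
        assert len(traj) == 1
        assert traj[0] == TumorState(0, params.C0, 0.0)

    def test_untreated_growth_matches_closed_form(self):
        p = ModelParams(a=0.1, K=200, C0=0.01, alpha=0.2, beta=0.02, gamma=0.5, mu=0.0, sigma=0)
        traj = simulate(p, TreatmentSchedule(), 18)
        expected = 200 * (0.01 / 200) ** math.exp(-0.1 * 18)
        assert traj.final.C == pytest.approx(expected, rel=1e-12)
        assert traj.final.C == pytest.approx(38.90, abs=2e-2)

    @pytest.mark.parametrize("days", [(1, 2), (3, 10), (2, 17)])
    def test_commuting_kill_without_growth_or_immunity(self, days):
        p = ModelParams(a=0.0, K=200, C0=10, alpha=0.2, beta=0.02, gamma=0.5, mu=0.0, sigma=0)
        S = lq_survival(8.0, 0.2, 0.02)
        sched = TreatmentSchedule([(days[0], 8.0), (days[1], 8.0)])
        traj = simulate(p, sched, 18)
        assert traj.final.C == pytest.approx(10 * S**2, rel=1e-12)
        assert traj.final.C == pytest.approx(0.0315, abs=5e-5)

    def test_no_radiation_keeps_immune_state_zero(self, params):
        traj = simulate(params, TreatmentSchedule([], range(7, 17)), 30)
        assert np.all(traj.immune == 0.0)
        pure = [params.C0]
        for _ in range(30):
            pure.append(gompertz_step(pure[-1], params.a, params.K, 1.0))
        np.testing.assert_allclose(traj.areas, pure, rtol=1e-12)

    def test_event_beyond_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            simulate(params, TreatmentSchedule([(20, 8.0)]), 18)

    @given(sigma2=st.floats(0.0, 20.0), bump=st.floats(0.1, 30.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_final_size_never_increases_with_potentiation(self, sigma2, bump):
        sched = TreatmentSchedule([(7, 8.0), (14, 8.0)], range(7, 17))
        low = simulate(DEFAULT_PARAMS.with_values(sigma=sigma2), sched, 25).final.C
        high = simulate(DEFAULT_PARAMS.with_values(sigma=sigma2 + bump), sched, 25).final.C
        assert high <= low * (1 + 1e-12)

    @given(
        a=st.floats(0.0, 0.5),
        gamma=st.floats(0.0, 0.98),
        mu=st.floats(0.0, 1.0),
        sigma=st.floats(0.0, 20.0),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_states_nonnegative_and_finite_over_100_days(self, a, gamma, mu, sigma):
        p = ModelParams(a=a, K=200, C0=0.01, alpha=0.2, beta=0.02, gamma=gamma, mu=mu, sigma=sigma)
        traj = simulate(p, TreatmentSchedule([(7, 8.0), (14, 8.0)], range(7, 17)), 100)
        assert np.all(traj.areas >= 0) and np.all(np.isfinite(traj.areas))
        assert np.all(traj.immune >= 0) and np.all(np.isfinite(traj.immune))


class TestTypes:
    def test_parameter_bounds_enforced(self):
        good = dict(a=0.1, K=200, C0=0.01, alpha=0.2, beta=0.02, gamma=0.6, mu=0.03, sigma=5)
        ModelParams(**good)
        for bad in (
            {"a": -0.1},
            {"K": 0.0},
            {"C0": 0.0},
            {"C0": 300.0},
            {"gamma": 1.0},
            {"gamma": -0.1},
            {"mu": -1.0},
            {"sigma": -1.0},
        ):
            with pytest.raises(ValueError):
                ModelParams(**{**good, **bad})

    def test_schedule_rejects_duplicate_or_invalid_events(self):
        with pytest.raises(ValueError):
            TreatmentSchedule([(7, 8.0), (7, 8.0)])
        with pytest.raises(ValueError):
            TreatmentSchedule([(-1, 8.0)])
        with pytest.raises(ValueError):
            TreatmentSchedule([(7, 0.0)])

    def test_trajectory_requires_consecutive_days(self):
        with pytest.raises(ValueError):
            Trajectory([TumorState(0, 1.0, 0.0), TumorState(2, 1.0, 0.0)])
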