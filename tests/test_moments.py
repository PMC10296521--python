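"""Closed-form moment kernel: spot values, independent oracles, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import dblquad, quad, solve_ivp

from axondrift import (
    GrowthParams,
    ValidationError,
    asymptotic_msl,
    characteristic_time,
    diffusion_coefficient,
    linear_regime_check,
    mean_position,
    mean_squared_displacement_full,
    mean_squared_length,
    mean_squared_length_diffusion_form,
    mean_squared_velocity,
    mean_velocity,
    velocity_correlation,
)

GRID = np.arange(5.0, 45.0, 5.0)

params_st = st.builds(
    GrowthParams,
    a0=st.floats(0.0, 5.0),
    gamma1=st.floats(0.01, 1.0),
    sigma2=st.floats(0.0, 1.0),
    v0_mean=st.floats(0.0, 5.0),
)


# ---------------------------------------------------------------------------
# mean velocity


def test_mean_velocity_initial_and_terminal(ref_params):
    assert mean_velocity(ref_params, 0.0) == pytest.approx(0.9)
    # by gamma1*t = 20 the transient is gone
    vd = ref_params.a0 / ref_params.gamma1
    assert mean_velocity(ref_params, 1000.0) == pytest.approx(vd, rel=1e-8)
    assert vd == pytest.approx(28.18, abs=0.01)


def test_mean_velocity_matches_ode_solution(ref_params):
    """<V(t)> solves dV/dt = a0 - gamma1 V from V0 (deterministic part)."""
    t_end = characteristic_time(ref_params)
    sol = solve_ivp(
        lambda t, v: ref_params.a0 - ref_params.gamma1 * v,
        (0.0, t_end),
        [ref_params.v0_mean],
        rtol=1e-12,
        atol=1e-12,
        dense_output=True,
    )
    expected = sol.y[0, -1]
    assert expected == pytest.approx(18.145, abs=2e-3)
    assert mean_velocity(ref_params, t_end) == pytest.approx(expected, rel=1e-9)


def test_mean_velocity_rejects_bad_time(ref_params):
    with pytest.raises(ValidationError):
        mean_velocity(ref_params, -1.0)
    with pytest.raises(ValidationError):
        mean_velocity(ref_params, math.nan)


# ---------------------------------------------------------------------------
# correlation / mean squared velocity


def test_correlation_equals_msv_at_equal_times(ref_params):
    t = np.linspace(0.0, 50.0, 100)
    np.testing.assert_allclose(
        velocity_correlation(ref_params, t, t),
        mean_squared_velocity(ref_params, t),
        rtol=1e-12,
    )


def test_noiseless_correlation_factorizes():
    p = GrowthParams(a0=2.0, gamma1=0.3, sigma2=0.0, v0_mean=1.5)
    for t1, t2 in [(0.0, 3.0), (2.0, 7.0), (10.0, 10.0)]:
        assert velocity_correlation(p, t1, t2) == pytest.approx(
            mean_velocity(p, t1) * mean_velocity(p, t2), rel=1e-12
        )


def test_msv_at_zero_is_v0_squared(ref_params):
    assert mean_squared_velocity(ref_params, 0.0) == pytest.approx(0.81)


def _ou_exact_draw(params, t, v_prev, t_prev, rng):
    """Exact-OU sampler (independent oracle): V(t) | V(t_prev) = v_prev."""
    g = params.gamma1
    vd = params.a0 / g
    E = np.exp(-g * (t - t_prev))
    var = params.sigma2 * (1.0 - E**2) / (2.0 * g)
    return vd + (v_prev - vd) * E + np.sqrt(var) * rng.standard_normal(np.shape(v_prev))


def test_stationary_correlation_monte_carlo(ref_params):
    """<V(200)^2> vs an exact-OU ensemble of 2e5 sample paths."""
    rng = np.random.default_rng(7)
    n = 200_000
    v0 = np.full(n, ref_params.v0_mean)
    v200 = _ou_exact_draw(ref_params, 200.0, v0, 0.0, rng)
    est = np.mean(v200**2)
    se = np.std(v200**2, ddof=1) / math.sqrt(n)
    closed = velocity_correlation(ref_params, 200.0, 200.0)
    assert closed == pytest.approx(796.58, abs=0.01)
    assert abs(est - closed) < 3.0 * se


def test_two_time_correlation_monte_carlo(ref_params):
    """<V(40) V(35)> vs chained exact-OU transitions."""
    rng = np.random.default_rng(11)
    n = 200_000
    v35 = _ou_exact_draw(ref_params, 35.0, np.full(n, ref_params.v0_mean), 0.0, rng)
    v40 = _ou_exact_draw(ref_params, 40.0, v35, 35.0, rng)
    prod = v35 * v40
    se = np.std(prod, ddof=1) / math.sqrt(n)
    assert abs(np.mean(prod) - velocity_correlation(ref_params, 40.0, 35.0)) < 3.0 * se


# ---------------------------------------------------------------------------
# mean position


def test_mean_position_examples(ref_params):
    assert mean_position(ref_params, 0.0) == 0.0
    # pure exponential decay integrates to V0/gamma1
    p = GrowthParams(a0=0.0, gamma1=1.0, sigma2=0.0, v0_mean=1.0)
    assert mean_position(p, 50.0) == pytest.approx(1.0, rel=1e-12)


def test_mean_position_is_integral_of_mean_velocity(ref_params):
    val, err = quad(lambda q: mean_velocity(ref_params, q), 0.0, 40.0, epsabs=1e-10, epsrel=1e-10)
    assert mean_position(ref_params, 40.0) == pytest.approx(val, rel=1e-9)


# ---------------------------------------------------------------------------
# mean squared length / displacement, against 2D quadrature of the
# two-time velocity correlation


def _centered_corr(params, t1, t2):
    """Correlation of velocity fluctuations about the terminal drift:
    full two-time correlation minus drift^2 and drift-cross terms."""
    g = params.gamma1
    vd = params.a0 / g
    dv = params.v0_mean - vd
    return (
        dv**2 * np.exp(-g * (t1 + t2))
        + params.sigma2 / (2.0 * g) * (np.exp(-g * abs(t1 - t2)) - np.exp(-g * (t1 + t2)))
    )


@pytest.mark.parametrize("t", [5.0, 20.0, 40.0])
def test_msl_matches_double_quadrature(ref_params, t):
    val, err = dblquad(
        lambda q2, q1: _centered_corr(ref_params, q1, q2),
        0.0, t, 0.0, t, epsabs=1e-9, epsrel=1e-9,
    )
    assert mean_squared_length(ref_params, t) == pytest.approx(val, rel=1e-6)


@pytest.mark.parametrize("t", [5.0, 20.0, 40.0])
def test_msd_full_matches_double_quadrature(ref_params, t):
    val, err = dblquad(
        lambda q2, q1: velocity_correlation(ref_params, q1, q2),
        0.0, t, 0.0, t, epsabs=1e-9, epsrel=1e-9,
    )
    assert mean_squared_displacement_full(ref_params, t) == pytest.approx(val, rel=1e-6)


def test_msl_zero_at_origin(ref_params):
    assert mean_squared_length(ref_params, 0.0) == 0.0
    assert mean_squared_displacement_full(ref_params, 0.0) == 0.0


def test_msd_full_reduces_when_transient_vanishes():
    # V0 = a0/gamma1: the transient term vanishes, leaving (V0 t)^2
    p = GrowthParams(a0=0.6, gamma1=0.3, sigma2=0.4, v0_mean=2.0)
    for t in GRID:
        assert mean_squared_displacement_full(p, t) == pytest.approx(
            mean_squared_length(p, t) + (2.0 * t) ** 2, rel=1e-10
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(params=params_st)
def test_msl_printed_and_diffusion_forms_agree(params):
    t = np.arange(1.0, 41.0)
    a = np.asarray(mean_squared_length(params, t))
    b = np.asarray(mean_squared_length_diffusion_form(params, t))
    np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-300)


def test_msl_monotone_on_grid(ref_params):
    t = np.linspace(0.0, 40.0, 401)
    vals = np.asarray(mean_squared_length(ref_params, t))
    assert np.all(vals >= 0)
    assert np.all(np.diff(vals) >= 0)


def test_msl_small_time_is_cubic_in_noise(ref_params):
    """For g*t -> 0 the variance part grows as sigma2 t^3 / 3."""
    p = GrowthParams(a0=0.0, gamma1=0.11, sigma2=0.52, v0_mean=0.0)
    for t in (1e-6, 1e-4, 1e-3):
        assert mean_squared_length(p, t) == pytest.approx(p.sigma2 * t**3 / 3.0, rel=1e-3)


# ---------------------------------------------------------------------------
# asymptote, diffusion coefficient, characteristic time


def test_asymptote_matches_msl_at_large_time(ref_params):
    """The printed linear asymptote drops the constant -3 sigma2/(2 g^3);
    at g*t = 20 the remaining difference is exactly that constant."""
    g, s2 = ref_params.gamma1, ref_params.sigma2
    t = 20.0 / g
    dropped = 1.5 * s2 / g**3
    assert asymptotic_msl(ref_params, t) - mean_squared_length(ref_params, t) == pytest.approx(
        dropped, rel=1e-6
    )
    # and the asymptote is within 1% of the full expression by then
    assert asymptotic_msl(ref_params, t) == pytest.approx(
        mean_squared_length(ref_params, t), rel=1e-2
    )


def test_asymptote_constant_when_noise_free():
    p = GrowthParams(a0=1.0, gamma1=0.5, sigma2=0.0, v0_mean=3.0)
    const = (p.v0_mean - p.a0 / p.gamma1) ** 2 / p.gamma1**2
    for t in (0.0, 10.0, 100.0):
        assert asymptotic_msl(p, t) == pytest.approx(const, rel=1e-12)


def test_asymptote_slope_is_twice_diffusion(ref_params):
    slope = asymptotic_msl(ref_params, 11.0) - asymptotic_msl(ref_params, 10.0)
    assert slope == pytest.approx(2.0 * diffusion_coefficient(ref_params), rel=1e-12)


def test_diffusion_coefficient_values(ref_params):
    assert diffusion_coefficient(ref_params) == pytest.approx(21.5, abs=0.05)
    assert diffusion_coefficient(GrowthParams(a0=1.0, gamma1=0.2, sigma2=0.0)) == 0.0


def test_diffusion_equals_half_large_time_msl_slope(ref_params):
    t0 = 25.0 / ref_params.gamma1
    dt = 0.1
    slope = (
        mean_squared_length(ref_params, t0 + dt) - mean_squared_length(ref_params, t0 - dt)
    ) / (2.0 * dt)
    assert diffusion_coefficient(ref_params) == pytest.approx(slope / 2.0, rel=1e-6)


@pytest.mark.parametrize("gamma1, tau", [(0.11, 9.0909), (1.0, 1.0), (0.5, 2.0)])
def test_characteristic_time(gamma1, tau):
    assert characteristic_time(GrowthParams(a0=1.0, gamma1=gamma1, sigma2=0.1)) == pytest.approx(
        tau, abs=1e-4
    )


# ---------------------------------------------------------------------------
# linear-regime check


def test_linear_regime_reference_values():
    res = linear_regime_check(v=10.0, gamma1=0.1, gamma2=1e-3)
    assert res.ratio == pytest.approx(100.0)
    assert res.satisfied
    assert not linear_regime_check(v=100.0, gamma1=0.1, gamma2=1e-3).satisfied
    unbounded = linear_regime_check(v=1e6, gamma1=0.1, gamma2=0.0)
    assert math.isinf(unbounded.ratio) and unbounded.satisfied


# ---------------------------------------------------------------------------
# structural invariants (property-based)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(params=params_st, t=st.floats(0.0, 50.0))
def test_jensen_inequality(params, t):
    assert mean_squared_velocity(params, t) >= mean_velocity(params, t) ** 2 - 1e-9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(params=params_st, t1=st.floats(0.0, 50.0), t2=st.floats(0.0, 50.0))
def test_correlation_symmetric(params, t1, t2):
    assert velocity_correlation(params, t1, t2) == pytest.approx(
        velocity_correlation(params, t2, t1), rel=1e-12, abs=1e-12
    )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(params=params_st, t=st.floats(0.1, 50.0))
def test_mean_position_derivative_is_mean_velocity(params, t):
    h = 1e-5 * max(1.0, t)
    deriv = (mean_position(params, t + h) - mean_position(params, t - h)) / (2.0 * h)
    assert deriv == pytest.approx(mean_velocity(params, t), rel=1e-7, abs=1e-9)


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        GrowthParams(a0=1.0, gamma1=0.0, sigma2=0.1)
    with pytest.raises(ValidationError):
        GrowthParams(a0=1.0, gamma1=0.1, sigma2=-0.1)
    with pytest.raises(ValidationError):
        GrowthParams(a0=math.inf, gamma1=0.1, sigma2=0.1)
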