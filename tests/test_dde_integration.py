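"""DDE integrators against method-of-steps closed forms."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ddehm import (
    DivergenceError,
    GenericDDE,
    TFAParams,
    configure_tfa,
    integrate_adaptive,
    integrate_fixed,
    integrate_with_sensitivities,
)
from ddehm.lagged_inputs import LagSeries, LagSpec
from ddehm.neural_kinetics import init_weights
from ddehm.simulators import tfa_steady_state


def _delay_decay():
    """dx/dt = -x(t-1) with history x = 1 for t <= 0."""
    return GenericDDE(rhs=lambda t, c, xl: -xl(1.0), delays=(1.0,), names=("x",))


def _delay_decay_exact(t):
    """Method-of-steps closed form: sum_k (-1)^k (t-k+1)^k / k!."""
    total = 0.0
    for k in range(int(math.floor(t)) + 2):
        arg = t - k + 1
        if arg >= 0:
            total += (-1) ** k * arg**k / math.factorial(k)
    return total


def test_fixed_step_matches_delay_decay_closed_form():
    tg = np.linspace(0.0, 3.0, 31)
    traj = integrate_fixed(_delay_decay(), tg, 0.005, c0=[1.0])
    exact = np.array([_delay_decay_exact(t) for t in tg])
    assert abs(traj.states[10, 0] - 0.0) < 1e-6  # x(1) = 0
    assert abs(traj.states[-1, 0] - (-1.0 / 6.0)) < 5e-6  # x(3) = -1/6
    assert np.max(np.abs(traj.states[:, 0] - exact)) < 1e-5


def test_fixed_step_is_second_order_on_the_delay_decay_oracle():
    tg = np.array([0.0, 3.0])
    errs = []
    for h in (0.05, 0.025, 0.0125):
        traj = integrate_fixed(_delay_decay(), tg, h, c0=[1.0])
        errs.append(abs(traj.states[-1, 0] - (-1.0 / 6.0)))
    r1, r2 = errs[0] / errs[1], errs[1] / errs[2]
    assert 2.8 < r1 < 5.5 and 2.8 < r2 < 5.5  # ~4x per halving


def test_fixed_step_pure_ode_exponential_decay():
    ode = GenericDDE(rhs=lambda t, c, xl: -c, delays=(), names=("x",))
    traj = integrate_fixed(ode, np.array([0.0, 1.0]), 0.01, c0=[1.0])
    assert traj.states[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-4)


def test_zero_rates_keep_trajectory_exactly_constant():
    spec = configure_tfa("1B", hidden=2)
    p = spec.init_params(0)
    for arr in (p.w1, p.b1, p.w2, p.b2):
        arr[...] = 0.0
    traj = integrate_fixed(spec, np.arange(0.0, 200.0, 10.0), 1.0, params=p, c0=[1.23])
    assert np.all(traj.states == 1.23)


def test_fixed_step_larger_than_delay_is_rejected():
    with pytest.raises(ValueError, match="smallest delay"):
        integrate_fixed(_delay_decay(), np.array([0.0, 3.0]), 1.5, c0=[1.0])


def test_divergence_raises_with_offending_time():
    blow = GenericDDE(rhs=lambda t, c, xl: c**2, delays=(), names=("x",))
    with np.errstate(over="ignore"), pytest.raises(DivergenceError):
        integrate_fixed(blow, np.array([0.0, 5.0]), 0.01, c0=[1.0])


def test_adaptive_matches_closed_forms_within_tolerance():
    tg = np.linspace(0.0, 3.0, 31)
    rtol, atol = 1e-7, 1e-10
    traj = integrate_adaptive(_delay_decay(), tg, rtol, atol, c0=[1.0])
    exact = np.array([_delay_decay_exact(t) for t in tg])
    assert np.all(np.abs(traj.states[:, 0] - exact) <= 100 * (rtol * np.abs(exact) + atol))

    ode = GenericDDE(rhs=lambda t, c, xl: -c, delays=(), names=("x",))
    a = integrate_adaptive(ode, np.array([0.0, 1.0]), 1e-8, 1e-12, c0=[1.0])
    assert a.states[-1, 0] == pytest.approx(math.exp(-1.0), rel=1e-6)


def test_adaptive_tolerance_halving_convergence_contract():
    tg = np.array([0.0, 3.0])
    loose = integrate_adaptive(_delay_decay(), tg, 1e-5, 1e-8, c0=[1.0])
    tight = integrate_adaptive(_delay_decay(), tg, 5e-6, 5e-9, c0=[1.0])
    prev_err = abs(loose.states[-1, 0] - (-1.0 / 6.0))
    assert abs(tight.states[-1, 0] - loose.states[-1, 0]) <= max(prev_err, 1e-7)


def test_adaptive_places_mesh_points_at_propagated_discontinuities():
    tau = 0.7
    prob = GenericDDE(rhs=lambda t, c, xl: -xl(tau) + 0.3 * c, delays=(tau,), names=("x",))
    _, mesh = integrate_adaptive(prob, np.array([0.0, 3.0]), 1e-6, 1e-9, c0=[1.0], return_mesh=True)
    for k in (1, 2):
        assert np.min(np.abs(mesh - k * tau)) < 1e-9


def test_adaptive_agrees_with_fixed_step_on_the_tfa_model():
    p = TFAParams()
    x0 = tfa_steady_state(p.kf_lo, p)

    def f(t, c, xlag):
        xl = xlag(p.tau)[0]
        xd = xlag(p.tau_deg)[0]
        kf = p.kf_hi if t >= p.t_step else p.kf_lo
        return np.array(
            [kf * xl**2 / (xl**2 + p.K_d)
             - p.k_deg * ((1 - p.phi_deg) * c[0] + p.phi_deg * xd) + p.R_bas]
        )

    prob = GenericDDE(rhs=f, delays=(p.tau, p.tau_deg), breakpoints=(p.t_step,), names=("x",))
    tg = np.arange(0.0, 500.0 + 1e-9, 10.0)
    ada = integrate_adaptive(prob, tg, 1e-8, 1e-11, c0=[x0])
    fix = integrate_fixed(prob, tg, 1.0, c0=[x0])
    rel = np.max(np.abs(ada.states - fix.states) / np.maximum(np.abs(fix.states), 1e-3))
    assert rel <= 1e-3


def test_no_delay_hybrid_equals_reference_ode_solver():
    # LagSpec with all counts zero reduces to a standard non-delayed model
    spec = configure_tfa("1C", hidden=4, n_lags=0)
    params = spec.init_params(3)
    tg = np.arange(0.0, 300.0 + 1e-9, 10.0)
    traj = integrate_adaptive(spec, tg, 1e-9, 1e-12, params=params, c0=[0.5])

    from ddehm.neural_kinetics import forward

    def ref_rhs(t, y):
        X = np.array([y[0], t / spec.time_input.scale])  # forward applies the time tanh
        rho = forward(X, params)[0] * spec.output_scale[0]
        return [rho - 0.05 * y[0] + 0.005]

    sol = solve_ivp(ref_rhs, (0.0, 300.0), [0.5], t_eval=tg, rtol=1e-10, atol=1e-13)
    assert np.max(np.abs(traj.states[:, 0] - sol.y[0])) <= 1e-6


def test_buffer_never_extrapolates_forward():
    seen = []

    def f(t, c, xlag):
        v = xlag(0.5)  # raises inside evaluate() if beyond the buffer
        seen.append(t)
        return -v

    prob = GenericDDE(rhs=f, delays=(0.5,), names=("x",))
    integrate_fixed(prob, np.array([0.0, 2.0]), 0.1, c0=[1.0])
    integrate_adaptive(prob, np.array([0.0, 2.0]), 1e-6, 1e-9, c0=[1.0])
    assert seen  # all delayed queries served without contract violations


def test_sensitivities_zero_at_t0_and_linear_parameter_closed_form():
    # rate = psi(x) * b2 with psi = x -> dx/dt = b2 * x; d x / d b2 = t e^(b2 t)
    from ddehm.hybrid_balance import HybridModelSpec

    spec = HybridModelSpec(
        states=("x",), K=[[1.0]], lags=LagSpec(states={"x": LagSeries(n_lags=0)}),
        hidden=1, psi=("x",),
    )
    p = spec.init_params(0)
    p.w1[...] = 0.0
    p.b1[...] = 0.0
    p.w2[...] = 0.0
    p.b2[...] = -1.0
    tg = np.linspace(0.0, 1.0, 11)
    for backend in ("generic", "fast"):
        traj, sens = integrate_with_sensitivities(
            spec, p, tg, 0.001, c0=[1.0], backend=backend
        )
        assert np.all(sens.sens[0] == 0.0)
        # b2 is the last parameter in the flat order
        got = sens.sens[-1, 0, -1]
        assert got == pytest.approx(1.0 * math.exp(-1.0), abs=1e-5)


def test_hybrid_sensitivities_match_finite_differences_of_the_solve():
    spec = configure_tfa("1C", hidden=3)
    p = spec.init_params(11)
    tg = np.arange(0.0, 400.0 + 1e-9, 20.0)
    traj, sens = integrate_with_sensitivities(spec, p, tg, 1.0, c0=[0.2])
    w = p.flatten()
    eps = 1e-5
    rng = np.random.default_rng(0)
    for i in rng.choice(p.n_w, size=6, replace=False):
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        sp = integrate_fixed(spec, tg, 1.0, params=p.with_flat(wp), c0=[0.2])
        sm = integrate_fixed(spec, tg, 1.0, params=p.with_flat(wm), c0=[0.2])
        fd = (sp.states[:, 0] - sm.states[:, 0]) / (2 * eps)
        scale = max(1.0, np.max(np.abs(sens.sens[:, 0, i])))
        assert np.max(np.abs(fd - sens.sens[:, 0, i])) / scale <= 1e-4
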