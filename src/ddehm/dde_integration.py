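"""Forward integration of hybrid delay differential equations.

Two schemes are provided:

* a fixed-step predictor-corrector (Heun) scheme with storage of the
  trajectory for delayed lookups.  The predictor rate at t_k and the
  corrector rate at t_k + h are averaged, which removes most of the
  error of a plain linear (Euler) approximation;
* an adaptive embedded Runge-Kutta 2(3) pair (Bogacki-Shampine) with a
  cubic-Hermite continuous extension from which delayed values are
  evaluated; derivative discontinuities propagating from t0 at
  multiples of each delay are handled by forcing mesh points there.

Both schemes clamp delayed lookups before the initial time to the
initial state.  The sensitivity-augmented integrator propagates
d(state)/d(weight) alongside the states with the same stepping scheme;
sensitivities are clamped to zero before t0 (initial states do not
depend on the network weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .hybrid_balance import HybridModelSpec, rhs as hybrid_rhs, kinetic_rates
from .lagged_inputs import HistoryBuffer
from .neural_kinetics import MLPParams, forward, jacobian_inputs, jacobian_weights
from .sensitivities import SensitivityTrajectory, sensitivity_rhs

__all__ = [
    "Trajectory",
    "GenericDDE",
    "DivergenceError",
    "StiffnessError",
    "integrate_fixed",
    "integrate_adaptive",
    "integrate_with_sensitivities",
]


class DivergenceError(RuntimeError):
    """The state became non-finite during integration."""

    def __init__(self, t):
        super().__init__(f"integration diverged (non-finite state) at t={t}")
        self.t = t


class StiffnessError(RuntimeError):
    """Adaptive step size underflowed."""


@dataclass
class Trajectory:
    """Time grid, state matrix and optional kinetic-rate diagnostics."""

    times: np.ndarray
    states: np.ndarray
    names: tuple[str, ...] = ()
    rates: np.ndarray | None = None
    inputs: np.ndarray | None = None
    exog: dict | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise DivergenceError(self.times[np.argmax(~np.isfinite(self.states).all(axis=1))])
        if not self.names:
            self.names = tuple(f"c{i}" for i in range(self.states.shape[1]))

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]


@dataclass(frozen=True)
class GenericDDE:
    """A delay differential equation in functional form.

    ``rhs(t, c, xlag)`` where ``xlag(offset)`` returns the state vector
    at ``t - offset`` (clamped to c(t0) before t0).  ``delays`` lists the
    positive lag offsets the right-hand side uses; ``breakpoints`` lists
    known discontinuity times of the right-hand side (e.g. an induction
    step), which the adaptive scheme will not step across.
    """

    rhs: Callable
    delays: tuple[float, ...] = ()
    breakpoints: tuple[float, ...] = ()
    names: tuple[str, ...] = ()
    rate_fn: Callable | None = None


def _exog_buffer(spec: HybridModelSpec, exog, t0: float, t_end: float) -> HistoryBuffer | None:
    """Pack exogenous records into a history buffer covering [t0, t_end]."""
    names = spec.exog_names
    if not names:
        return None
    if exog is None:
        raise ValueError(f"model needs exogenous records {names} but none were given")
    series = {}
    for nm in names:
        t_ex, v_ex = exog[nm]
        series[nm] = (np.asarray(t_ex, float), np.asarray(v_ex, float))
    t_all = np.unique(np.concatenate([t for t, _ in series.values()]))
    if t_all[0] > t0 or t_all[-1] < t_end - 1e-9:
        raise ValueError("exogenous records must cover the integration interval")
    vals = np.column_stack([np.interp(t_all, t, v) for t, v in series.values()])
    buf = HistoryBuffer(tuple(names), t_all[0], vals[0], capacity=len(t_all) + 1)
    for t, v in zip(t_all[1:], vals[1:]):
        buf.append(t, v)
    return buf


def _internal_grid(t_grid: np.ndarray, step: float) -> tuple[float, float, int, float]:
    t_grid = np.asarray(t_grid, float)
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    if step <= 0:
        raise ValueError("step must be positive")
    if t_end - t0 <= 0:
        return t0, t_end, 0, 0.0  # degenerate single-point grid
    n = max(1, int(round((t_end - t0) / step)))
    h = (t_end - t0) / n
    return t0, t_end, n, h

def _sample(t_grid, t_int, values):
    """Linear interpolation of internal-grid values onto the output grid."""
    t_grid = np.asarray(t_grid, float)
    idx = np.clip(np.searchsorted(t_int, t_grid, side="right") - 1, 0, len(t_int) - 2)
    w = (t_grid - t_int[idx]) / (t_int[idx + 1] - t_int[idx])
    w = np.clip(w, 0.0, 1.0)
    return (1 - w[:, None]) * values[idx] + w[:, None] * values[idx + 1]


def _as_problem(model, params, exog, t0, t_end):
    """Normalize a HybridModelSpec or GenericDDE to (rhs, delays, breakpoints, names, rate_fn)."""
    if isinstance(model, GenericDDE):
        return model, None

    if not isinstance(model, HybridModelSpec):
        raise TypeError("model must be a HybridModelSpec or GenericDDE")
    if params is None:
        raise ValueError("hybrid model integration requires MLP parameters")
    exbuf = _exog_buffer(model, exog, t0, t_end)

    def f(t, c, history):
        return hybrid_rhs(t, c, history, model, params, exbuf)

    def rate_fn(t, c, history):
        return kinetic_rates(t, history, model, params, exbuf, c=c)

    delays = tuple(float(o) for o in model.lags.all_offsets)
    prob = GenericDDE(rhs=f, delays=delays, names=model.states, rate_fn=rate_fn)
    return prob, exbuf


def _check_step(h: float, delays: Sequence[float]) -> None:
    pos = [d for d in delays if d > 0]
    if pos and h > min(pos) + 1e-12:
        raise ValueError(
            f"fixed step {h} exceeds the smallest delay {min(pos)}; "
            "delayed lookups would leave the stored buffer"
        )


def integrate_fixed(
    model,
    t_grid: np.ndarray,
    step: float,
    *,
    params: MLPParams | None = None,
    c0: np.ndarray | None = None,
    exog: Mapping | None = None,
    record_rates: bool = False,
) -> Trajectory:
    """Fixed-step Heun integration with stored delayed values.

    The kinetic rates of each step are averaged between the step start
    and the predicted step end.  Delayed queries are served from the
    stored trajectory with linear interpolation and clamp to c(t0)
    before t0.  ``step`` must not exceed the smallest positive delay.
    """
    t_grid = np.asarray(t_grid, float)
    t0, t_end, n, h = _internal_grid(t_grid, step)
    c0 = np.atleast_1d(np.asarray(c0, float))
    prob, _ = _as_problem(model, params, exog, t0, t_end)
    if n == 0:
        names = prob.names or tuple(f"c{i}" for i in range(c0.shape[0]))
        return Trajectory(t_grid, np.tile(c0, (len(t_grid), 1)), names)
    _check_step(h, prob.delays)

    m = c0.shape[0]
    names = prob.names or tuple(f"c{i}" for i in range(m))
    buf = HistoryBuffer(names, t0, c0, capacity=n + 2)
    breaks = np.asarray(sorted(prob.breakpoints), float)

    def call(f, t, c, t_eval=None):
        te = t if t_eval is None else t_eval
        if isinstance(model, HybridModelSpec):
            return np.atleast_1d(f(te, c, buf))
        xlag = lambda off: c.copy() if off == 0 else buf.evaluate(t - off)
        return np.atleast_1d(f(te, c, xlag))

    c = c0.copy()
    for k in range(n):
        t = t0 + k * h
        f1 = call(prob.rhs, t, c)
        pred = c + h * f1
        if not np.all(np.isfinite(pred)):
            raise DivergenceError(t + h)
        buf.append(t + h, pred)
        # corrector stage: if the step ends exactly on a declared rhs
        # breakpoint, average with the left-limit rate so the
        # discontinuity takes effect only from the next step on
        t2 = t + h
        t2_eval = t2
        if breaks.size and np.any(np.abs(breaks - t2) <= 1e-9 * max(1.0, abs(t2))):
            t2_eval = t2 - 1e-9 * h
        f2 = call(prob.rhs, t2, pred, t_eval=t2_eval)
        c = c + 0.5 * h * (f1 + f2)
        if not np.all(np.isfinite(c)):
            raise DivergenceError(t + h)
        buf.replace_last(t + h, c)

    t_int = buf.times
    states = _sample(t_grid, t_int, buf.values)
    rates = None
    if record_rates and prob.rate_fn is not None:
        rows = []
        for t in t_grid:
            c_t = buf.evaluate(t)
            if isinstance(model, HybridModelSpec):
                rows.append(np.atleast_1d(prob.rate_fn(t, c_t, buf)))
            else:
                xlag = lambda off, _t=t: buf.evaluate(_t - off)
                rows.append(np.atleast_1d(prob.rate_fn(t, c_t, xlag)))
        rates = np.array(rows)
    return Trajectory(t_grid, states, names, rates=rates)


# ----------------------------------------------------------------------
# Adaptive Bogacki-Shampine 2(3) with cubic Hermite continuous extension
# ----------------------------------------------------------------------

class _DenseHistory:
    """Accepted mesh plus cubic-Hermite evaluation; clamps before t0."""

    def __init__(self, names, t0, c0, f0):
        self.names = tuple(names)
        self.ts = [t0]
        self.ys = [np.asarray(c0, float)]
        self.fs = [np.asarray(f0, float)]
        self.stage: tuple[float, np.ndarray] | None = None

    @property
    def t0(self):
        return self.ts[0]

    def push(self, t, y, f):
        self.ts.append(t)
        self.ys.append(y)
        self.fs.append(f)

    def index(self, name):
        return self.names.index(name)

    def evaluate(self, t):
        if t <= self.ts[0]:
            return self.ys[0].copy()
        if self.stage is not None and abs(t - self.stage[0]) <= 1e-12 * max(1.0, abs(t)):
            return self.stage[1].copy()
        if t > self.ts[-1] + 1e-12 * max(1.0, abs(t)):
            raise ValueError(f"delayed query at t={t} beyond computed mesh")
        i = int(np.searchsorted(self.ts, t, side="right")) - 1
        i = min(i, len(self.ts) - 2)
        t_lo, t_hi = self.ts[i], self.ts[i + 1]
        hseg = t_hi - t_lo
        s = (t - t_lo) / hseg
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s**2 * (3 - 2 * s)
        h11 = s**2 * (s - 1)
        return (
            h00 * self.ys[i]
            + h10 * hseg * self.fs[i]
            + h01 * self.ys[i + 1]
            + h11 * hseg * self.fs[i + 1]
        )


def integrate_adaptive(
    model,
    t_grid: np.ndarray,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
    *,
    params: MLPParams | None = None,
    c0: np.ndarray | None = None,
    exog: Mapping | None = None,
    max_step: float | None = None,
    return_mesh: bool = False,
):
    """Adaptive embedded RK2(3) integration with continuous extension.

    Delayed values are evaluated on the cubic Hermite interpolant of the
    accepted mesh.  The step never exceeds the smallest positive delay,
    and mesh points are forced at the propagated discontinuities
    t0 + k*tau (k = 1, 2) of every delay tau and at declared
    breakpoints of the right-hand side.
    """
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be positive")
    t_grid = np.asarray(t_grid, float)
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    c0 = np.atleast_1d(np.asarray(c0, float))
    prob, _ = _as_problem(model, params, exog, t0, t_end)

    names = prob.names or tuple(f"c{i}" for i in range(c0.shape[0]))
    pos_delays = [d for d in prob.delays if d > 0]
    hmax = t_end - t0
    if pos_delays:
        hmax = min(hmax, min(pos_delays))
    if max_step is not None:
        hmax = min(hmax, max_step)

    # derivative discontinuities propagate from t0 and every declared
    # breakpoint at multiples of each delay
    roots = {t0} | {float(b) for b in prob.breakpoints}
    breaks = sorted(
        {r + k * d for r in roots for d in pos_delays for k in (0, 1, 2)} | roots
    )
    breaks = [b for b in breaks if t0 < b < t_end]

    hist = _DenseHistory(names, t0, c0, np.zeros_like(c0))

    def call(t, y):
        if isinstance(model, HybridModelSpec):
            hist.stage = (t, y)
            out = np.atleast_1d(prob.rhs(t, y, hist))
            hist.stage = None
            return out
        xlag = lambda off: y.copy() if off == 0 else hist.evaluate(t - off)
        return np.atleast_1d(prob.rhs(t, y, xlag))

    f0 = call(t0, c0)
    hist.fs[0] = f0

    t, y, f = t0, c0.copy(), f0
    h = min(hmax, (t_end - t0) / 100.0)
    bi = 0
    hmin = 1e-12 * max(1.0, abs(t_end - t0))
    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        h = min(h, hmax, t_end - t)
        while bi < len(breaks) and breaks[bi] <= t + 1e-12 * max(1.0, abs(t)):
            bi += 1
        if bi < len(breaks) and t + h > breaks[bi]:
            h = breaks[bi] - t
        if h < hmin:
            raise StiffnessError(f"step size underflow at t={t}")
        end_is_break = bi < len(breaks) and abs(t + h - breaks[bi]) <= 1e-9 * max(1.0, abs(t + h))
        k1 = f
        k2 = call(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = call(t + 0.75 * h, y + 0.75 * h * k2)
        y_new = y + h * (2 * k1 + 3 * k2 + 4 * k3) / 9.0
        # left-limit evaluation when the step ends on a rhs breakpoint:
        # the segment's dense slope must belong to the pre-break regime
        k4 = call(t + h - (1e-9 * h if end_is_break else 0.0), y_new)
        err_vec = h * (-5 * k1 + 6 * k2 + 8 * k3 - 9 * k4) / 72.0
        scale_ = abs_tol + rel_tol * np.maximum(np.abs(y), np.abs(y_new))
        err = float(np.sqrt(np.mean((err_vec / scale_) ** 2)))
        if not np.isfinite(err):
            raise DivergenceError(t + h)
        if err <= 1.0:
            t = t + h
            y = y_new
            hist.push(t, y, k4)
            # first-same-as-last: restart the slope on the right limit
            f = call(t, y) if end_is_break else k4
        fac = 0.9 * (1.0 / max(err, 1e-10)) ** (1.0 / 3.0)
        h = h * min(5.0, max(0.2, fac))

    t_mesh = np.asarray(hist.ts)
    states = np.array([hist.evaluate(tq) for tq in t_grid])
    traj = Trajectory(t_grid, states, names)
    if return_mesh:
        return traj, t_mesh
    return traj


# ----------------------------------------------------------------------
# Sensitivity-augmented integration (generic path + compiled fast path)
# ----------------------------------------------------------------------

def _input_map(spec: HybridModelSpec):
    """ANN input columns as (kind, index, offset) in assembly order."""
    entries = []
    for name, series in spec.lags.states.items():
        i = spec.state_index(name)
        for off in series.lag_offsets:
            entries.append(("state", i, float(off)))
    exog_names = spec.exog_names
    for name, series in spec.lags.exog.items():
        j = exog_names.index(name)
        for off in series.lag_offsets:
            entries.append(("exog", j, float(off)))
    if spec.time_input is not None:
        entries.append(("time", -1, 0.0))
    return entries


def _generic_sens(spec, p, t_grid, step, c0, exog):
    """Reference NumPy implementation of states + sensitivities."""
    t_grid = np.asarray(t_grid, float)
    t0, t_end, n, h = _internal_grid(t_grid, step)
    c0 = np.atleast_1d(np.asarray(c0, float))
    m, q, nw = spec.n_states, spec.n_rates, spec.init_params(0).n_w
    if n == 0:
        return (
            Trajectory(t_grid, np.tile(c0, (len(t_grid), 1)), spec.states),
            SensitivityTrajectory(t_grid, np.zeros((len(t_grid), m, nw))),
        )
    _check_step(h, list(spec.lags.all_offsets))
    exbuf = _exog_buffer(spec, exog, t0, t_end)
    buf = HistoryBuffer(spec.states, t0, c0, capacity=n + 2)
    imap = _input_map(spec)

    S_hist = np.zeros((n + 1, m, nw))
    t_int = t0 + h * np.arange(n + 1)

    def sens_lookup(tq, S_stage, t_stage):
        """Delayed sensitivity; zero before t0, linear interp inside."""
        if tq <= t0:
            return np.zeros((m, nw))
        if abs(tq - t_stage) < 1e-12 * max(1.0, abs(t_stage)):
            return S_stage
        x = (tq - t0) / h
        i = min(int(np.floor(x)), n - 1)
        wgt = x - i
        return (1 - wgt) * S_hist[i] + wgt * S_hist[i + 1]

    def full_rhs(t, c, S, t_stage):
        X = spec.assemble_X(buf, exbuf, t)
        rho = forward(X, p)
        psi = spec.psi_values(t, c)
        r = spec.output_scale * psi * rho
        dc = spec.K @ r
        D = 0.0
        if spec.growth_output is None:
            if isinstance(spec.dilution, str):
                D = float(exbuf.evaluate(t)[exbuf.index(spec.dilution)])
            elif spec.dilution is not None:
                D = float(spec.dilution)
            if D != 0.0:
                dc = dc - D * np.where(spec.dilution_mask, c, 0.0)
        else:
            mu = r[spec.growth_output]
            dc = dc - mu * c
            if spec.b is not None:
                dc = dc + spec.b
        if spec.A is not None:
            dc = dc + spec.A @ c
        if spec.u0 is not None:
            dc = dc + spec.u0
        for state, ex, coef in spec.feed_terms:
            dc[spec.state_index(state)] += coef * float(exbuf.evaluate(t)[exbuf.index(ex)])

        # sensitivity pieces
        JX = jacobian_inputs(X, p)  # (q, L)
        Jw = jacobian_weights(X, p)  # (q, nw)
        offsets = sorted({off for kind, _, off in imap if kind == "state"})
        jac_by_lag, sens_by_lag = [], []
        for off in offsets:
            Jc = np.zeros((q, m))
            for col, (kind, idx, o) in enumerate(imap):
                if kind == "state" and o == off:
                    Jc[:, idx] += JX[:, col]
            jac_by_lag.append(Jc)
            sens_by_lag.append(sens_lookup(t - off, S, t_stage))
        dpsi_dc = None
        if spec.psi is not None and any(term is not None for term in spec.psi):
            dpsi_dc = np.zeros((q, m))
            for j, term in enumerate(spec.psi):
                if term is None:
                    continue
                if isinstance(term, str):
                    dpsi_dc[j, spec.state_index(term)] = 1.0
                else:
                    dpsi_dc[j] = np.asarray(term[1](t, c), float)
        dS = sensitivity_rhs(
            K=spec.K,
            psi=psi,
            rho=rho,
            scale=spec.output_scale,
            jac_inputs_by_lag=jac_by_lag,
            delayed_sens=sens_by_lag,
            jac_weights=Jw,
            dpsi_dc=dpsi_dc,
            sens=S,
            D=D,
            dil_mask=spec.dilution_mask,
            A=spec.A,
            growth_output=spec.growth_output,
            c=c,
        )
        return dc, dS

    c = c0.copy()
    S = np.zeros((m, nw))
    for k in range(n):
        t = t0 + k * h
        f1, g1 = full_rhs(t, c, S, t)
        pred_c, pred_S = c + h * f1, S + h * g1
        if not np.all(np.isfinite(pred_c)):
            raise DivergenceError(t + h)
        buf.append(t + h, pred_c)
        S_hist[k + 1] = pred_S
        f2, g2 = full_rhs(t + h, pred_c, pred_S, t + h)
        c = c + 0.5 * h * (f1 + f2)
        S = S + 0.5 * h * (g1 + g2)
        if not np.all(np.isfinite(c)):
            raise DivergenceError(t + h)
        buf.replace_last(t + h, c)
        S_hist[k + 1] = S

    states = _sample(t_grid, t_int, buf.values)
    sens = _sample(t_grid, t_int, S_hist.reshape(n + 1, m * nw)).reshape(len(t_grid), m, nw)
    return Trajectory(t_grid, states, spec.states), SensitivityTrajectory(t_grid, sens)



def integrate_with_sensitivities(
    spec: HybridModelSpec,
    params: MLPParams,
    t_grid: np.ndarray,
    step: float,
    *,
    c0: np.ndarray,
    exog: Mapping | None = None,
    backend: str = "auto",
):
    """States and forward sensitivities d c / d w on ``t_grid``.

    The sensitivity system is stepped with the same fixed-step averaged-
    rate scheme as the states; delayed sensitivities are clamped to zero
    before t0.  ``backend='fast'`` selects the compiled kernel (requires
    lag offsets commensurate with the step and declarative psi terms);
    ``'generic'`` forces the NumPy reference path; ``'auto'`` tries the
    fast path and falls back.
    """
    if backend not in ("auto", "fast", "generic"):
        raise ValueError("backend must be 'auto', 'fast' or 'generic'")
    if backend in ("auto", "fast"):
        from . import _fastpath

        try:
            plan = _fastpath.build_plan(
                spec, np.asarray(t_grid, float), step,
                np.atleast_2d(np.asarray(c0, float)),
                [exog] if exog is not None else None,
            )
        except _fastpath.FastPathUnavailable:
            if backend == "fast":
                raise
        else:
            states, sens = _fastpath.run(plan, params, with_sens=True)
            traj = Trajectory(np.asarray(t_grid, float), states[0], spec.states)
            return traj, SensitivityTrajectory(np.asarray(t_grid, float), sens[0])
    return _generic_sens(spec, params, t_grid, step, np.asarray(c0, float), exog)
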