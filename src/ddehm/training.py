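"""Parameter identification and model performance criteria.

The network weights w minimize the weighted least-squares objective

    E = 1/(P*n) * sum_l sum_i (c_m,l,i - c_l,i(t, w))^2 / c_sigma,i

over all P samples and n state variables of the training runs, with
per-variable standard-deviation weights (division by the standard
deviation as stated; variance weighting is available as a switch).
Gradients come from the forward sensitivity equations — the optimizer
(scipy's trust-region-reflective least squares) always receives the
analytic residual Jacobian, never finite differences.

Identification is an iterative process stopped by generalization: the
validation criterion is evaluated at every accepted iterate and the
returned parameters are those of the best validation value, not the
last iterate.  Several random restarts guard against local minima.

Performance criteria:

    MSE = 1/(P*n) * SSE                     (unweighted residuals)
    BIC = -(n*P/2) * ln(SSE) - (n_w/2) * ln(n*P/(2*pi))

Larger BIC is better; model selection maximizes the validation BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._rng import derive_seed
from .dde_integration import DivergenceError, integrate_fixed, integrate_with_sensitivities
from .hybrid_balance import HybridModelSpec
from .neural_kinetics import MLPParams

__all__ = [
    "Run",
    "TimeSeriesDataset",
    "split_roles",
    "TrainOptions",
    "FitResult",
    "objective",
    "mse",
    "bic",
    "criteria",
    "fit_once",
    "fit_multistart",
]


@dataclass
class Run:
    """One measured time-series run.

    ``y`` is the (T, n_states) matrix of measured concentrations at
    ``times``; ``sigma`` the per-variable standard deviations used for
    weighting; ``exog`` maps exogenous record names (feed rate, dilution
    rate, ...) to (times, values) pairs; ``c0`` the initial state used
    to start simulations (defaults to the first measurement row).
    """

    name: str
    times: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]
    sigma: np.ndarray
    role: str = "train"
    c0: np.ndarray | None = None
    exog: dict | None = None
    config: dict | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.y = np.asarray(self.y, float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        self.sigma = np.atleast_1d(np.asarray(self.sigma, float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"run {self.name!r}: times must be strictly increasing")
        if self.y.shape != (len(self.times), len(self.names)):
            raise ValueError(f"run {self.name!r}: measurement matrix shape mismatch")
        if self.sigma.shape != (len(self.names),) or np.any(self.sigma <= 0):
            raise ValueError(f"run {self.name!r}: sigma must be positive per variable")
        if self.role not in ("train", "valid", "test"):
            raise ValueError(f"run {self.name!r}: unknown split role {self.role!r}")
        if self.c0 is None:
            self.c0 = self.y[0].copy()
        else:
            self.c0 = np.atleast_1d(np.asarray(self.c0, float))

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class TimeSeriesDataset:
    """A collection of runs sharing the same measured variables."""

    runs: list

    def __post_init__(self):
        if not self.runs:
            raise ValueError("dataset must contain at least one run")
        names = self.runs[0].names
        for r in self.runs:
            if r.names != names:
                raise ValueError("all runs must share the same variable names")

    @property
    def names(self) -> tuple[str, ...]:
        return self.runs[0].names

    @property
    def P(self) -> int:
        """Total sample count over all runs."""
        return sum(r.n_samples for r in self.runs)

    @property
    def n(self) -> int:
        """Number of measured state variables."""
        return len(self.names)

    def subset(self, role: str) -> "TimeSeriesDataset":
        return TimeSeriesDataset([r for r in self.runs if r.role == role])


def split_roles(runs: Sequence[Run], train_frac: float = 2.0 / 3.0) -> TimeSeriesDataset:
    """Assign split roles run-by-run: training first until it holds about
    ``train_frac`` of all data points (the customary two-thirds), the
    remainder alternating validation and test.  Assignment is by whole
    runs in the given order (runs are the natural blocking unit)."""
    total = sum(r.n_samples for r in runs)
    out, acc = [], 0
    next_other = "valid"
    for r in runs:
        if acc + r.n_samples / 2 < train_frac * total:
            role = "train"
            acc += r.n_samples
        else:
            role = next_other
            next_other = "test" if next_other == "valid" else "valid"
        r.role = role
        out.append(r)
    if not any(r.role == "valid" for r in out):
        out[-1].role = "valid"
    return TimeSeriesDataset(out)


@dataclass
class TrainOptions:
    """Numerical settings of one identification run.

    ``step``: integration step of the fixed-step sensitivity scheme
    (default: a tenth of the smallest measurement spacing, capped by the
    smallest delay).  ``weight_mode``: 'sd' divides squared residuals by
    c_sigma as in the printed objective, 'var' by c_sigma^2.
    ``val_criterion``: early-stopping criterion on the validation split
    ('bic', maximized, or 'mse'/'e', minimized).
    """

    step: float | None = None
    max_iter: int = 300
    ftol: float = 1e-8
    xtol: float = 1e-10
    gtol: float = 1e-10
    weight_mode: str = "sd"
    val_criterion: str = "bic"
    backend: str = "auto"

    def resolve_step(self, spec: HybridModelSpec, dataset: "TimeSeriesDataset") -> float:
        if self.step is not None:
            return self.step
        spacings = [
            float(np.min(np.diff(r.times))) for r in dataset.runs if r.n_samples > 1
        ]
        if not spacings:
            return 1.0  # all runs degenerate (single sample); value unused
        h = min(spacings) / 10.0
        delays = spec.lags.all_offsets
        if delays.size:
            h = min(h, float(delays.min()))
        return h


@dataclass
class FitResult:
    """Outcome of one identification (or the best of several restarts)."""

    params: MLPParams
    seed: int
    n_w: int
    criteria: dict
    best_iter: int = 0
    n_iter: int = 0
    success: bool = True
    message: str = ""
    log: list = field(default_factory=list)
    restarts: list | None = None


# ----------------------------------------------------------------------
# Prediction machinery
# ----------------------------------------------------------------------

class _Predictor:
    """Batched simulation of every run of a dataset for given weights."""

    def __init__(self, spec: HybridModelSpec, dataset: TimeSeriesDataset, step: float, backend: str):
        self.spec = spec
        self.dataset = dataset
        self.step = step
        self.backend = backend
        self.groups = []  # (run indices, fast plan or None)
        by_grid: dict = {}
        for i, r in enumerate(dataset.runs):
            by_grid.setdefault(r.times.tobytes(), []).append(i)
        for idx in by_grid.values():
            plan = None
            if backend in ("auto", "fast"):
                from . import _fastpath

                runs = [dataset.runs[i] for i in idx]
                try:
                    plan = _fastpath.build_plan(
                        spec,
                        runs[0].times,
                        step,
                        np.array([r.c0 for r in runs]),
                        [r.exog for r in runs],
                    )
                except _fastpath.FastPathUnavailable:
                    if backend == "fast":
                        raise
            self.groups.append((idx, plan))

    def _run_generic(self, run, params, with_sens):
        if with_sens:
            traj, sens = integrate_with_sensitivities(
                self.spec, params, run.times, self.step,
                c0=run.c0, exog=run.exog, backend="generic",
            )
            return traj.states, sens.sens
        traj = integrate_fixed(
            self.spec, run.times, self.step, params=params, c0=run.c0, exog=run.exog
        )
        return traj.states, None

    def predict(self, params: MLPParams, with_sens: bool = False):
        """Per-run state matrices (and sensitivities) in dataset order."""
        from . import _fastpath

        states = [None] * len(self.dataset.runs)
        sens = [None] * len(self.dataset.runs)
        for idx, plan in self.groups:
            if plan is not None:
                st, se = _fastpath.run(plan, params, with_sens=with_sens)
                for pos, i in enumerate(idx):
                    states[i] = st[pos]
                    if with_sens:
                        sens[i] = se[pos]
            else:
                for i in idx:
                    states[i], sens[i] = self._run_generic(
                        self.dataset.runs[i], params, with_sens
                    )
        return states, (sens if with_sens else None)


def _residual_scale(dataset: TimeSeriesDataset, weight_mode: str) -> list:
    P, n = dataset.P, dataset.n
    scales = []
    for r in dataset.runs:
        w = r.sigma if weight_mode == "sd" else r.sigma**2
        scales.append(np.sqrt(w * P * n))
    return scales


def _criteria_from_states(dataset, states, n_w, weight_mode):
    P, n = dataset.P, dataset.n
    sse = 0.0
    e = 0.0
    for run, st in zip(dataset.runs, states):
        res = run.y - st
        sse += float(np.sum(res**2))
        w = run.sigma if weight_mode == "sd" else run.sigma**2
        e += float(np.sum(res**2 / w))
    e /= P * n
    mse_val = sse / (P * n)
    if sse == 0.0:
        bic_val = math.inf  # perfect fit: log-likelihood term diverges
    else:
        bic_val = -(n * P / 2.0) * math.log(sse) - (n_w / 2.0) * math.log(n * P / (2.0 * math.pi))
    return {"E": e, "MSE": mse_val, "BIC": bic_val, "SSE": sse, "P": P, "n": n}


def criteria(
    spec: HybridModelSpec,
    params: MLPParams,
    dataset: TimeSeriesDataset,
    opts: TrainOptions | None = None,
    n_w: int | None = None,
) -> dict:
    """E, MSE, BIC and SSE of a model on a dataset (one integration)."""
    opts = opts or TrainOptions()
    step = opts.resolve_step(spec, dataset)
    pred = _Predictor(spec, dataset, step, opts.backend)
    states, _ = pred.predict(params)
    return _criteria_from_states(dataset, states, n_w or params.n_w, opts.weight_mode)


def objective(spec, params, dataset, opts=None) -> float:
    """Weighted least-squares objective E (infinite on divergence)."""
    try:
        return criteria(spec, params, dataset, opts)["E"]
    except DivergenceError:
        return math.inf


def mse(spec, params, dataset, opts=None) -> float:
    """Unweighted mean squared residual over the dataset."""
    try:
        return criteria(spec, params, dataset, opts)["MSE"]
    except DivergenceError:
        return math.inf


def bic(spec, params, dataset, n_w: int | None = None, opts=None) -> float:
    """Bayesian information criterion (larger is better)."""
    try:
        return criteria(spec, params, dataset, opts, n_w=n_w)["BIC"]
    except DivergenceError:
        return -math.inf


def _crit_value(crit_dict, criterion):
    key = {"bic": "BIC", "mse": "MSE", "e": "E"}[criterion]
    v = crit_dict[key]
    return -v if key == "BIC" else v  # normalized: smaller is better


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def fit_once(
    spec: HybridModelSpec,
    train: TimeSeriesDataset,
    valid: TimeSeriesDataset,
    seed: int,
    opts: TrainOptions | None = None,
) -> FitResult:
    """One gradient-based identification from a random initialization.

    Minimizes E on the training runs with the analytic sensitivity
    Jacobian; the validation criterion is evaluated at every accepted
    iterate and the parameters with the best validation value are
    returned.  Failed integrations during the search yield an infinite
    objective (the step is rejected), not a fatal error.
    """
    opts = opts or TrainOptions()
    step = opts.resolve_step(spec, train)
    p0 = spec.init_params(seed)
    pred_train = _Predictor(spec, train, step, opts.backend)
    pred_valid = _Predictor(spec, valid, step, opts.backend)
    scales = _residual_scale(train, opts.weight_mode)
    n_res = sum(r.y.size for r in train.runs)
    penalty = 1e3

    state = {
        "best": None,  # (normalized criterion, iter, flat params)
        "iter": 0,
        "log": [],
        "last_jac": None,  # (w bytes, residuals)
        "any_finite": False,
    }

    def residuals_from(states):
        parts = [
            ((run.y - st) / sc).ravel()
            for run, st, sc in zip(train.runs, states, scales)
        ]
        return np.concatenate(parts)

    def fun(w):
        if state["last_jac"] is not None and state["last_jac"][0] == w.tobytes():
            return state["last_jac"][1]
        p = p0.with_flat(w)
        try:
            states, _ = pred_train.predict(p)
        except DivergenceError:
            return np.full(n_res, penalty)
        r = residuals_from(states)
        if not np.all(np.isfinite(r)):
            return np.full(n_res, penalty)
        state["any_finite"] = True
        return r

    def jac(w):
        p = p0.with_flat(w)
        try:
            states, sens = pred_train.predict(p, with_sens=True)
        except DivergenceError:
            return np.zeros((n_res, p0.n_w))
        r = residuals_from(states)
        state["last_jac"] = (w.tobytes(), r)
        J = np.vstack(
            [
                (-se / sc[None, :, None]).reshape(-1, p0.n_w)
                for se, sc in zip(sens, scales)
            ]
        )
        # validation early stopping: score this accepted iterate
        it = state["iter"]
        state["iter"] = it + 1
        try:
            v_states, _ = pred_valid.predict(p)
            v_crit = _criteria_from_states(valid, v_states, p0.n_w, opts.weight_mode)
            score = _crit_value(v_crit, opts.val_criterion)
        except DivergenceError:
            score = math.inf
        train_e = float(np.sum(r**2)) if np.all(np.isfinite(r)) else math.inf
        state["log"].append((it, train_e, score))
        if state["best"] is None or score < state["best"][0]:
            state["best"] = (score, it, w.copy())
        return J

    w0 = p0.flatten()
    try:
        res = least_squares(
            fun, w0, jac=jac, method="trf",
            max_nfev=opts.max_iter, ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol,
        )
        message, success = res.message, True
    except Exception as exc:  # numerical failure inside the solver
        message, success = str(exc), False

    if state["best"] is None or not state["any_finite"]:
        return FitResult(
            params=p0, seed=seed, n_w=p0.n_w,
            criteria={}, success=False,
            message=f"no finite objective found: {message}",
            log=state["log"],
        )

    _, best_iter, w_best = state["best"]
    p_best = p0.with_flat(w_best)
    out_criteria = {}
    for split_name, ds, pr in (("train", train, pred_train), ("valid", valid, pred_valid)):
        try:
            st, _ = pr.predict(p_best)
            out_criteria[split_name] = _criteria_from_states(ds, st, p0.n_w, opts.weight_mode)
        except DivergenceError:
            out_criteria[split_name] = {
                "E": math.inf, "MSE": math.inf, "BIC": -math.inf,
                "SSE": math.inf, "P": ds.P, "n": ds.n,
            }
    return FitResult(
        params=p_best,
        seed=seed,
        n_w=p0.n_w,
        criteria=out_criteria,
        best_iter=best_iter,
        n_iter=state["iter"],
        success=success,
        message=message,
        log=state["log"],
    )


def fit_multistart(
    spec: HybridModelSpec,
    train: TimeSeriesDataset,
    valid: TimeSeriesDataset,
    n_restarts: int,
    base_seed: int,
    opts: TrainOptions | None = None,
) -> FitResult:
    """Best of ``n_restarts`` random initializations by validation BIC.

    Restart seeds derive deterministically from ``base_seed``, so the
    outcome is independent of execution order; ties break to the lower
    restart index.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    results = []
    for i in range(n_restarts):
        results.append(fit_once(spec, train, valid, derive_seed(base_seed, "restart", i), opts))
    ok = [r for r in results if r.success and r.criteria]
    if not ok:
        raise RuntimeError(
            "all restarts failed: " + "; ".join(r.message for r in results)
        )
    best = max(ok, key=lambda r: r.criteria["valid"]["BIC"])
    best.restarts = [
        {
            "seed": r.seed,
            "success": r.success,
            "valid_bic": r.criteria.get("valid", {}).get("BIC", -math.inf),
            "valid_mse": r.criteria.get("valid", {}).get("MSE", math.inf),
        }
        for r in results
    ]
    return best
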