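"""Synthetic-data generators for the two case studies.

Case I — transcription factor autoregulation with a translocation
delay.  A single positive-feedback DDE for the nuclear concentration x:

    dx/dt = kf(t) * x(t-tau)^2 / (x(t-tau)^2 + Kd)
            - k_deg * [(1-phi) * x(t) + phi * x(t-tau_deg)] + R_bas

kf steps from a low (monostable-low) to a bistability-inducing value at
t_step, forcing a jump to the upper state.  The synthesis delay tau
produces the characteristic staircase transition; the partially delayed
dissociation term (lag tau_deg, fraction phi) produces the damped
overshoot/decline within the stairs seen in the reference trajectories.
With tau_deg = 0 (or phi = 0) the loss term is the plain instantaneous
first-order dissociation; in that case the transition is provably
monotone.  The constants are not physical ground truth but a versioned
configuration chosen to reproduce the qualitative phenotype at O(1)
nM concentrations.

Case II — fed-batch *Pichia pastoris* on methanol with a quadratic
(Erlang-2) distributed delay between substrate uptake and growth /
product formation, realized by the linear chain W, Z:

    dX/dt = mu(W) X - D X           dS/dt = -rS(S) X - D (S - S_F)
    dP/dt = rP(W) X - D P           dV/dt = F
    dW/dt = (Z - W)/beta            dZ/dt = (S - Z)/beta
    F = V/(S_F - S) * (rS X + (S_set - S)/tau_set),   D = F/V
    mu = K_B1 W/(K_s + W) - K_B2 m_ATP
    rP = K_rho1 mu + K_rho2         rS = rS_max S/(K_s + S)

The chain is equivalent to W(t) = Int S(t-tau) tau/beta^2 e^(-tau/beta)
dtau; :func:`distributed_delay_oracle` evaluates that convolution by
quadrature as an independent cross-check.  The substrate setpoint
follows a per-run schedule (the excitation needed for identification);
the feed is clamped at zero when the controller demands removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ._rng import derive_seed
from .dde_integration import GenericDDE, Trajectory, integrate_fixed
from .training import Run, TimeSeriesDataset

__all__ = [
    "TFAParams",
    "PichiaParams",
    "ModelValidityError",
    "tfa_steady_state",
    "simulate_tfa",
    "simulate_pichia",
    "distributed_delay_oracle",
    "add_noise",
    "make_case_study",
]


class ModelValidityError(RuntimeError):
    """The simulation left its physically meaningful domain."""


# ----------------------------------------------------------------------
# Case I: TF-A
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TFAParams:
    """Constants of the TF-A generator (time unit: minutes).

    ``kf_lo``/``kf_hi``: synthesis rate before/after the induction step
    at ``t_step``; ``K_d``: Hill half-saturation (on x^2); ``k_deg``:
    first-order loss constant; ``phi_deg``: fraction of the loss carried
    by the delayed term; ``R_bas``: basal synthesis; ``tau``:
    translocation delay; ``tau_deg``: loss delay; ``x0``/``history``
    default to the pre-step low steady state.
    """

    kf_lo: float = 0.025
    kf_hi: float = 0.15
    t_step: float = 200.0
    K_d: float = 0.3
    k_deg: float = 0.05
    R_bas: float = 0.005
    tau: float = 120.0
    tau_deg: float = 20.0
    phi_deg: float = 0.5
    x0: float | None = None
    t_end: float = 720.0

    def __post_init__(self):
        for name in ("kf_lo", "kf_hi", "K_d", "k_deg", "R_bas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau < 0 or self.tau_deg < 0:
            raise ValueError("delays must be non-negative")


def tfa_steady_state(kf: float, params: TFAParams, upper: float = 1.0) -> float:
    """Root of the no-delay vector field in (0, upper] (low branch by default)."""
    f = lambda x: kf * x**2 / (x**2 + params.K_d) - params.k_deg * x + params.R_bas
    return brentq(f, 1e-12, upper)


def simulate_tfa(
    params: TFAParams | None = None,
    t_grid: np.ndarray | None = None,
    step: float = 0.25,
) -> Trajectory:
    """Clean TF-A trajectory (and the synthesis-rate diagnostic).

    With tau > 0 the induced transition is a staircase with damped
    overshoots (non-monotone); with tau = tau_deg = 0 it is a smooth
    monotone transition.
    """
    p = params or TFAParams()
    if t_grid is None:
        t_grid = np.arange(0.0, p.t_end + 1e-9, 10.0)
    t_grid = np.asarray(t_grid, float)
    if p.kf_lo != p.kf_hi and not (t_grid[0] < p.t_step < t_grid[-1]):
        warnings.warn("time grid does not bracket the kf step time", stacklevel=2)
    x0 = p.x0 if p.x0 is not None else tfa_steady_state(p.kf_lo, p)

    def synth(t, xl):
        kf = p.kf_hi if t >= p.t_step else p.kf_lo
        return kf * xl**2 / (xl**2 + p.K_d)

    def f(t, c, xlag):
        xl = xlag(p.tau)[0]
        xd = xlag(p.tau_deg)[0]
        loss = p.k_deg * ((1.0 - p.phi_deg) * c[0] + p.phi_deg * xd)
        return np.array([synth(t, xl) - loss + p.R_bas])

    def rate_fn(t, c, xlag):
        return np.array([synth(t, xlag(p.tau)[0])])

    delays = tuple(d for d in (p.tau, p.tau_deg) if d > 0)
    prob = GenericDDE(rhs=f, delays=delays, breakpoints=(p.t_step,), names=("x",), rate_fn=rate_fn)
    return integrate_fixed(prob, t_grid, step, c0=np.array([x0]), record_rates=True)


# ----------------------------------------------------------------------
# Case II: Pichia pastoris fed-batch
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PichiaParams:
    """Constants of the fed-batch generator (time unit: hours, g/L).

    The Erlang-2 kernel scale ``beta`` is set so the kernel's mean delay
    2*beta equals 5 h.  Controller: substrate setpoint ``S_set`` (may be
    overridden by a per-run schedule), feed concentration ``S_F``,
    controller time constant ``tau_set``.
    """

    K_B1: float = 0.04
    K_B2: float = 0.2
    K_s: float = 0.1
    m_ATP: float = 0.05
    K_rho1: float = 0.08
    K_rho2: float = 0.0003
    r_S_max: float = 0.09
    beta: float = 2.5
    S_F: float = 100.0
    S_set: float = 0.5
    tau_set: float = 2.0
    X0: float = 2.0
    S0: float = 3.0
    P0: float = 0.0
    V0: float = 1.0

    def __post_init__(self):
        if self.S_F <= self.S_set:
            raise ValueError("feed concentration S_F must exceed the setpoint")
        for name in ("K_B1", "K_s", "r_S_max", "beta", "tau_set", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


PICHIA_STATES = ("X", "S", "P", "V", "W", "Z")


def _pichia_kinetics(p: PichiaParams, S, W):
    mu = p.K_B1 * W / (p.K_s + W) - p.K_B2 * p.m_ATP
    rP = p.K_rho1 * mu + p.K_rho2
    rS = p.r_S_max * S / (p.K_s + S)
    return rS, mu, rP


def simulate_pichia(
    params: PichiaParams | None = None,
    t_end: float = 100.0,
    step: float = 0.05,
    *,
    setpoint_schedule=None,
    obs_dt: float = 1.0,
) -> Trajectory:
    """Clean fed-batch trajectory with rates and feed records.

    ``setpoint_schedule`` is a list of (time, S_set) pairs (piecewise-
    constant, first entry at t=0); the feed rate F and dilution D = F/V
    are recorded as exogenous series for later use by hybrid models.
    """
    p = params or PichiaParams()
    sched = setpoint_schedule or [(0.0, p.S_set)]
    s_times = np.array([s[0] for s in sched])
    s_vals = np.array([s[1] for s in sched])
    if s_times[0] > 0:
        raise ValueError("setpoint schedule must start at t=0")

    def setpoint(t):
        return s_vals[np.searchsorted(s_times, t, side="right") - 1]

    def feed(t, c):
        X, S, P, V, W, Z = c
        rS, _, _ = _pichia_kinetics(p, S, W)
        F = (V / (p.S_F - S)) * (rS * X + (setpoint(t) - S) / p.tau_set)
        return max(F, 0.0)

    def f(t, c, xlag):
        X, S, P, V, W, Z = c
        if V <= 0:
            raise ModelValidityError(f"culture volume became non-positive at t={t}")
        rS, mu, rP = _pichia_kinetics(p, S, W)
        F = feed(t, c)
        D = F / V
        return np.array(
            [
                mu * X - D * X,
                -rS * X - D * (S - p.S_F),
                rP * X - D * P,
                F,
                (Z - W) / p.beta,
                (S - Z) / p.beta,
            ]
        )

    def rate_fn(t, c, xlag):
        rS, mu, rP = _pichia_kinetics(p, c[1], c[4])
        return np.array([rS, mu, rP])

    t_grid = np.arange(0.0, t_end + 1e-9, obs_dt)
    c0 = np.array([p.X0, p.S0, p.P0, p.V0, p.S0, p.S0])
    prob = GenericDDE(
        rhs=f, delays=(), breakpoints=tuple(s_times[1:]), names=PICHIA_STATES, rate_fn=rate_fn
    )
    traj = integrate_fixed(prob, t_grid, step, c0=c0, record_rates=True)
    if traj.states[:, [0, 1, 2, 3]].min() < -1e-9:
        raise ModelValidityError("negative concentration in the fed-batch simulation")
    F_series = np.array([feed(t, traj.states[i]) for i, t in enumerate(t_grid)])
    traj.exog = {"F": F_series, "D": F_series / traj.states[:, 3]}
    return traj


def distributed_delay_oracle(S_times, S_values, beta: float, t, n_quad: int = 4000):
    """W(t) = Int_0^inf S(t - tau) tau/beta^2 e^(-tau/beta) dtau by quadrature.

    Used only as an independent cross-check of the W, Z linear chain.
    The kernel is truncated at 10*beta (captures all but ~5e-4 of its
    mass); if the available history is shorter, the head of the kernel
    clamps to the earliest stored value and a truncation warning with
    the missing-mass bound is issued.
    """
    S_times = np.asarray(S_times, float)
    S_values = np.asarray(S_values, float)
    ts = np.atleast_1d(np.asarray(t, float))
    horizon = 10.0 * beta
    out = np.empty(len(ts))
    for i, tq in enumerate(ts):
        if tq - horizon < S_times[0] - 1e-9:
            miss = tq - S_times[0]
            bound = (1.0 + miss / beta) * np.exp(-miss / beta) if miss > 0 else 1.0
            warnings.warn(
                f"history shorter than 10*beta before t={tq}; "
                f"kernel mass up to {bound:.3g} clamped to the earliest value",
                stacklevel=2,
            )
        tau = np.linspace(0.0, horizon, n_quad)
        kern = tau / beta**2 * np.exp(-tau / beta)
        Sv = np.interp(tq - tau, S_times, S_values)
        out[i] = np.trapezoid(kern * Sv, tau)
    return out if out.shape[0] > 1 else float(out[0])


# ----------------------------------------------------------------------
# Noise corruption and case-study packaging
# ----------------------------------------------------------------------

def add_noise(
    traj: Trajectory,
    relative_sd: float,
    seed: int,
    *,
    role: str = "train",
    name: str = "run",
    columns: tuple[str, ...] | None = None,
    c0: np.ndarray | None = None,
) -> TimeSeriesDataset:
    """White-noise corruption of a clean trajectory into a dataset.

    Gaussian noise with standard deviation ``relative_sd * |clean|`` is
    added independently per sample; the recorded per-variable sigma is
    ``relative_sd * mean(|clean|)`` (unit weights when relative_sd=0).
    Exogenous records are copied uncorrupted.  Reproducible by seed.
    """
    if relative_sd < 0:
        raise ValueError("relative_sd must be non-negative")
    cols = columns or traj.names
    idx = [traj.names.index(c) for c in cols]
    clean = traj.states[:, idx]
    rng = np.random.default_rng(seed)
    noisy = clean + relative_sd * np.abs(clean) * rng.standard_normal(clean.shape)
    if relative_sd > 0:
        sigma = relative_sd * np.mean(np.abs(clean), axis=0)
        sigma = np.maximum(sigma, 1e-12)
    else:
        sigma = np.ones(len(idx))
    exog = None
    if traj.exog:
        exog = {k: (traj.times.copy(), np.asarray(v, float).copy()) for k, v in traj.exog.items()}
    run = Run(
        name=name,
        times=traj.times.copy(),
        y=noisy,
        names=tuple(cols),
        sigma=sigma,
        role=role,
        c0=np.asarray(c0, float) if c0 is not None else clean[0].copy(),
        exog=exog,
    )
    return TimeSeriesDataset([run])


_TFA_DEFAULT = {
    "relative_sd": 0.05,
    "obs_dt": 10.0,
    "step": 0.25,
    "x0_factors": (0.5, 1.0, 2.0),
    # (clean run index, role) for each of the six corrupted sets
    "assignment": (
        (0, "train"), (1, "train"), (0, "valid"), (2, "valid"), (1, "test"), (2, "test"),
    ),
}

_PICHIA_DEFAULT = {
    "relative_sd": 0.05,
    "obs_dt": 1.0,
    "step": 0.05,
    "t_end": 100.0,
    "runs": (
        {"X0": 2.0, "S0": 3.0, "schedule": ((0.0, 1.5), (30.0, 0.3), (60.0, 1.0)), "role": "train"},
        {"X0": 1.5, "S0": 0.5, "schedule": ((0.0, 0.5), (25.0, 1.8), (55.0, 0.4), (80.0, 1.2)), "role": "train"},
        {"X0": 2.5, "S0": 2.0, "schedule": ((0.0, 1.0), (40.0, 0.25), (70.0, 1.5)), "role": "valid"},
        {"X0": 2.0, "S0": 1.0, "schedule": ((0.0, 0.4), (20.0, 1.2), (50.0, 2.0), (75.0, 0.5)), "role": "test"},
    ),
}


def _split(runs_by_role):
    return {
        role: TimeSeriesDataset(runs) for role, runs in runs_by_role.items() if runs
    }


def make_case_study(case: str, config: dict | None = None, master_seed: int = 0):
    """Generate the train/valid/test datasets of a case study.

    TF-A: three clean trajectories with distinct initial concentrations,
    each corrupted twice with independent white noise -> six noisy sets,
    two per split role.  Pichia: four fed-batch runs with varied initial
    states and setpoint schedules (2 train / 1 valid / 1 test).  Every
    run carries its generating configuration; regeneration from the same
    config and master seed is bit-identical.
    """
    if case == "tfa":
        cfg = {**_TFA_DEFAULT, **(config or {})}
        params = cfg.get("params") or TFAParams()
        t_grid = np.arange(0.0, params.t_end + 1e-9, cfg["obs_dt"])
        base = tfa_steady_state(params.kf_lo, params)
        cleans = [
            simulate_tfa(replace(params, x0=base * f), t_grid, cfg["step"])
            for f in cfg["x0_factors"]
        ]
        runs_by_role: dict[str, list] = {"train": [], "valid": [], "test": []}
        for j, (ci, role) in enumerate(cfg["assignment"]):
            ds = add_noise(
                cleans[ci],
                cfg["relative_sd"],
                derive_seed(master_seed, "tfa", "noise", j, ci, role),
                role=role,
                name=f"tfa-{role}-{j}",
            )
            run = ds.runs[0]
            run.config = {"case": "tfa", "clean_run": ci, "x0_factor": cfg["x0_factors"][ci]}
            runs_by_role[role].append(run)
        return _split(runs_by_role)

    if case == "pichia":
        cfg = {**_PICHIA_DEFAULT, **(config or {})}
        params = cfg.get("params") or PichiaParams()
        runs_by_role = {"train": [], "valid": [], "test": []}
        for j, rcfg in enumerate(cfg["runs"]):
            p_run = replace(params, X0=rcfg["X0"], S0=rcfg["S0"])
            traj = simulate_pichia(
                p_run,
                t_end=cfg["t_end"],
                step=cfg["step"],
                setpoint_schedule=list(rcfg["schedule"]),
                obs_dt=cfg["obs_dt"],
            )
            ds = add_noise(
                traj,
                cfg["relative_sd"],
                derive_seed(master_seed, "pichia", "noise", j),
                role=rcfg["role"],
                name=f"pichia-{rcfg['role']}-{j}",
                columns=("X", "S", "P", "V"),
            )
            run = ds.runs[0]
            run.config = {"case": "pichia", "run": j, **{k: rcfg[k] for k in ("X0", "S0")}}
            runs_by_role[rcfg["role"]].append(run)
        return _split(runs_by_role)

    raise ValueError(f"unknown case study {case!r} (use 'tfa' or 'pichia')")
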