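"""Forward sensitivity equations of the hybrid DDE.

Differentiating the balance dc/dt = K.(psi*rho) - D.c + u with respect
to the network weights w, and accounting for every lagged appearance of
the states, gives

    d/dt (dc/dw) = sum_k  d(K.psi.rho)/dc(t-k*tau) . dc(t-k*tau)/dw
                   + d(K.psi.rho)/dw  -  D . dc/dw

with the chain-rule expansion

    d(K.psi.rho)/dc_k = K.[rho * dpsi/dc_k + psi * drho/dc_k]
    d(K.psi.rho)/dw   = K.[rho * dpsi/dw  + psi * drho/dw]

where drho/dc_k are the network input Jacobians restricted to the input
columns fed by lag k.  Delayed sensitivities are zero before t0: the
initial states do not depend on w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SensitivityTrajectory", "sensitivity_rhs", "objective_gradient"]


@dataclass
class SensitivityTrajectory:
    """d(state)/d(weight) along a trajectory: (T, n_states, n_w)."""

    times: np.ndarray
    sens: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.sens = np.asarray(self.sens, float)
        if self.sens.ndim != 3:
            raise ValueError("sensitivity array must be (time, state, parameter)")


def sensitivity_rhs(
    *,
    K: np.ndarray,
    psi: np.ndarray,
    rho: np.ndarray,
    scale: np.ndarray,
    jac_inputs_by_lag: Sequence[np.ndarray],
    delayed_sens: Sequence[np.ndarray],
    jac_weights: np.ndarray,
    sens: np.ndarray,
    dpsi_dc: np.ndarray | None = None,
    dpsi_dw: np.ndarray | None = None,
    D: float = 0.0,
    dil_mask: np.ndarray | None = None,
    A: np.ndarray | None = None,
    growth_output: int | None = None,
    c: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side of the sensitivity system, shape (m, n_w).

    ``jac_inputs_by_lag[k]`` is drho/dc(t - off_k), shape (q, m), already
    mapped from ANN input columns to state indices; ``delayed_sens[k]``
    the matching dc(t - off_k)/dw, shape (m, n_w) (zero-clamped before
    t0 by the caller).  ``dpsi_dc`` is evaluated at the instantaneous
    state (parametric factors take no lagged arguments here) and pairs
    with the current ``sens``.  With no trainable constants in psi,
    ``dpsi_dw`` is zero and the direct term reduces to K.psi.drho/dw.
    """
    K = np.atleast_2d(np.asarray(K, float))
    q = K.shape[1]
    psi = np.asarray(psi, float).reshape(q)
    rho = np.asarray(rho, float).reshape(q)
    scale = np.asarray(scale, float).reshape(q)

    drho_tot = np.asarray(jac_weights, float).copy()
    for Jc, Sd in zip(jac_inputs_by_lag, delayed_sens):
        drho_tot += Jc @ Sd
    dr = scale[:, None] * psi[:, None] * drho_tot
    if dpsi_dc is not None:
        dr += scale[:, None] * rho[:, None] * (dpsi_dc @ sens)
    if dpsi_dw is not None:
        dr += scale[:, None] * rho[:, None] * dpsi_dw

    out = K @ dr
    if growth_output is not None:
        if c is None:
            raise ValueError("growth mode requires the current state c")
        mu = scale[growth_output] * psi[growth_output] * rho[growth_output]
        out = out - np.outer(c, dr[growth_output]) - mu * sens
    elif D != 0.0:
        mask = np.ones(K.shape[0]) if dil_mask is None else np.asarray(dil_mask, float)
        out = out - D * mask[:, None] * sens
    if A is not None:
        out = out + np.asarray(A, float) @ sens
    return out


def objective_gradient(traj, sens_traj, dataset, weight_mode: str = "sd"):
    """Residual Jacobian and objective gradient from solved sensitivities.

    Residuals are r_{l,i} = (c_m - c) / sqrt(w_i * P * n) with w_i the
    per-variable standard deviation (default, as in the weighted
    least-squares objective) or variance (``weight_mode='var'``), so
    that E = sum r^2.  The Jacobian row for each residual is
    -dc/dw scaled identically, and grad E = 2 J^T r.

    ``traj``/``sens_traj`` may be single objects or lists aligned with
    ``dataset.runs``; trajectories must be sampled at the measurement
    times of each run.
    """
    from .training import TimeSeriesDataset  # local import to avoid a cycle

    if not isinstance(dataset, TimeSeriesDataset):
        dataset = TimeSeriesDataset([dataset])
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    senss = sens_traj if isinstance(sens_traj, (list, tuple)) else [sens_traj]
    if len(trajs) != len(dataset.runs) or len(senss) != len(dataset.runs):
        raise ValueError("one trajectory and sensitivity per run required")

    P, n = dataset.P, dataset.n
    res_parts, jac_parts = [], []
    for run, tr, se in zip(dataset.runs, trajs, senss):
        if len(tr.times) != len(run.times) or not np.allclose(tr.times, run.times):
            raise ValueError("trajectory not sampled at the run's measurement times")
        w = run.sigma if weight_mode == "sd" else run.sigma**2
        denom = np.sqrt(w * P * n)  # (m,)
        r = (run.y - tr.states) / denom  # (T, m)
        J = -se.sens / denom[None, :, None]  # (T, m, nw)
        res_parts.append(r.ravel())
        jac_parts.append(J.reshape(-1, J.shape[-1]))
    residuals = np.concatenate(res_parts)
    jacobian = np.vstack(jac_parts)
    grad = 2.0 * jacobian.T @ residuals
    return grad, jacobian, residuals
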