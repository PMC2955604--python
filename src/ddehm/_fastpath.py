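"""Compiled fixed-step integration kernel for training.

Parameter identification evaluates the hybrid DDE (and its sensitivity
system, n_states x n_w extra equations) thousands of times.  This module
lowers the declarative :class:`~ddehm.hybrid_balance.HybridModelSpec`
into flat arrays on a uniform step grid and runs the same predictor-
corrector averaged-rate scheme as the generic integrator inside a
numba-compiled loop, batched over runs that share a time grid.

Supported structures: MLP kinetics with optional per-output state
multipliers (psi), constant or exogenous dilution, linear parametric
terms A.c + u0, exogenous additive feed terms, and lag offsets that are
integer multiples of the step.  Anything else (callable psi factors,
growth-dilution mode, incommensurate lags) raises
:class:`FastPathUnavailable` and is served by the generic path, against
which this kernel is cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .hybrid_balance import HybridModelSpec
from .neural_kinetics import MLPParams

__all__ = ["FastPathUnavailable", "FastPlan", "build_plan", "run"]


class FastPathUnavailable(RuntimeError):
    """The model structure is outside what the compiled kernel supports."""


@dataclass
class FastPlan:
    spec: HybridModelSpec
    c0: np.ndarray          # (B, m)
    src: np.ndarray         # (L,) int64: state idx, -1 time, -(2+e) exog e
    off: np.ndarray         # (L,) int64 lag offsets in steps
    itanh: np.ndarray       # (L,) bool
    K: np.ndarray
    A: np.ndarray
    u0: np.ndarray
    psi_idx: np.ndarray     # (q,) int64, -1 for unity factor
    scale: np.ndarray
    dmask: np.ndarray       # (m,) float
    D: np.ndarray           # (B, n+1)
    useries: np.ndarray     # (B, n+1, m)
    exseries: np.ndarray    # (B, n_ex, n+1)
    t0: float
    h: float
    tscale: float
    obs_idx: np.ndarray     # (T,) int64
    obs_w: np.ndarray       # (T,)
    t_grid: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.D.shape[1] - 1


def build_plan(
    spec: HybridModelSpec,
    t_grid: np.ndarray,
    step: float,
    c0_batch: np.ndarray,
    exog_list=None,
) -> FastPlan:
    """Lower a hybrid model + batch of runs onto the kernel's arrays."""
    from .dde_integration import _input_map, _internal_grid  # shared conventions

    if spec.growth_output is not None:
        raise FastPathUnavailable("growth-dilution mode is generic-path only")
    if spec.psi is not None and any(
        term is not None and not isinstance(term, str) for term in spec.psi
    ):
        raise FastPathUnavailable("callable psi factors are generic-path only")

    t_grid = np.asarray(t_grid, float)
    t0, t_end, n, h = _internal_grid(t_grid, step)
    if n == 0:
        raise FastPathUnavailable("degenerate single-point time grid")
    c0_batch = np.atleast_2d(np.asarray(c0_batch, float))
    B, m = c0_batch.shape
    if m != spec.n_states:
        raise ValueError("initial-condition width does not match the model states")

    imap = _input_map(spec)
    L = len(imap)
    src = np.empty(L, np.int64)
    off = np.empty(L, np.int64)
    ann_exog = list(spec.lags.exog)
    for l, (kind, idx, offset) in enumerate(imap):
        steps = offset / h
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise FastPathUnavailable(
                f"lag offset {offset} is not an integer multiple of the step {h}"
            )
        off[l] = int(round(steps))
        if kind == "state":
            src[l] = idx
        elif kind == "time":
            src[l] = -1
        else:  # exog: idx refers to spec.exog_names; remap to ANN exog rows
            name = spec.exog_names[idx]
            src[l] = -2 - ann_exog.index(name)
    q = spec.n_rates
    psi_idx = np.full(q, -1, np.int64)
    if spec.psi is not None:
        for j, term in enumerate(spec.psi):
            if isinstance(term, str):
                psi_idx[j] = spec.state_index(term)

    t_int = t0 + h * np.arange(n + 1)

    def interp_run(exog_run, name):
        if exog_run is None or name not in exog_run:
            raise FastPathUnavailable(f"exogenous record {name!r} missing from the run")
        te, ve = exog_run[name]
        te = np.asarray(te, float)
        if te[0] > t0 + 1e-9 or te[-1] < t_end - 1e-9:
            raise ValueError("exogenous records must cover the integration interval")
        return np.interp(t_int, te, np.asarray(ve, float))

    D = np.zeros((B, n + 1))
    useries = np.zeros((B, n + 1, m))
    n_ex = max(1, len(ann_exog))
    exseries = np.zeros((B, n_ex, n + 1))
    needs_exog = (
        isinstance(spec.dilution, str) or spec.feed_terms or ann_exog
    )
    if needs_exog and exog_list is None:
        raise FastPathUnavailable("model needs exogenous records but none were given")
    for b in range(B):
        exog_run = None if exog_list is None else exog_list[b if len(exog_list) > 1 else 0]
        if isinstance(spec.dilution, str):
            D[b] = interp_run(exog_run, spec.dilution)
        elif spec.dilution is not None:
            D[b] = float(spec.dilution)
        for state, ex, coef in spec.feed_terms:
            useries[b, :, spec.state_index(state)] += coef * interp_run(exog_run, ex)
        for e, name in enumerate(ann_exog):
            exseries[b, e] = interp_run(exog_run, name)

    obs_pos = np.clip((t_grid - t0) / h, 0, n)
    obs_idx = np.minimum(obs_pos.astype(np.int64), n - 1)
    obs_w = obs_pos - obs_idx

    return FastPlan(
        spec=spec,
        c0=np.ascontiguousarray(c0_batch),
        src=src,
        off=off,
        itanh=np.ascontiguousarray(spec.input_tanh_mask()),
        K=np.ascontiguousarray(spec.K),
        A=np.ascontiguousarray(spec.A if spec.A is not None else np.zeros((m, m))),
        u0=np.ascontiguousarray(spec.u0 if spec.u0 is not None else np.zeros(m)),
        psi_idx=psi_idx,
        scale=np.ascontiguousarray(spec.output_scale),
        dmask=np.ascontiguousarray(spec.dilution_mask.astype(float)),
        D=D,
        useries=useries,
        exseries=exseries,
        t0=t0,
        h=h,
        tscale=spec.time_input.scale if spec.time_input is not None else 1.0,
        obs_idx=obs_idx,
        obs_w=obs_w,
        t_grid=t_grid,
    )


def run(plan: FastPlan, params: MLPParams, with_sens: bool = False):
    """Integrate the batch; returns states (B, T, m) and sens (B, T, m, n_w)."""
    spec = plan.spec
    if params.n_inputs != plan.src.shape[0] or params.n_outputs != spec.n_rates:
        raise ValueError("parameter shapes do not match the plan")
    states, sens, ok = _heun_kernel(
        plan.c0,
        np.ascontiguousarray(params.w1),
        np.ascontiguousarray(params.b1),
        np.ascontiguousarray(params.w2),
        np.ascontiguousarray(params.b2),
        plan.itanh,
        plan.src,
        plan.off,
        plan.K,
        plan.A,
        plan.u0,
        plan.psi_idx,
        plan.scale,
        plan.dmask,
        plan.D,
        plan.useries,
        plan.exseries,
        plan.t0,
        plan.h,
        plan.tscale,
        with_sens,
    )
    if not ok:
        from .dde_integration import DivergenceError

        bad = np.argwhere(~np.isfinite(states))
        t_bad = plan.t0 + plan.h * (bad[0][1] if len(bad) else plan.n_steps)
        raise DivergenceError(t_bad)
    i, w = plan.obs_idx, plan.obs_w
    out_states = (1 - w)[None, :, None] * states[:, i] + w[None, :, None] * states[:, i + 1]
    out_sens = None
    if with_sens:
        out_sens = (
            (1 - w)[None, :, None, None] * sens[:, i]
            + w[None, :, None, None] * sens[:, i + 1]
        )
    return out_states, out_sens


@njit(cache=True)
def _heun_kernel(
    c0, w1, b1, w2, b2, itanh, src, off, K, A, u0, psi_idx, scale, dmask,
    D, useries, exseries, t0, h, tscale, with_sens,
):  # pragma: no cover - exercised via run()
    B, m = c0.shape
    n = D.shape[1] - 1
    H, L = w1.shape
    q = b2.shape[0]
    nw = H * L + H + q * H + q

    states = np.zeros((B, n + 1, m))
    if with_sens:
        sens = np.zeros((B, n + 1, m, nw))
    else:
        sens = np.zeros((1, 1, 1, 1))

    X = np.empty(L)
    g = np.empty(H)
    gp = np.empty(H)
    rho = np.empty(q)
    psiv = np.empty(q)
    rate = np.empty(q)
    fbuf = np.empty((2, m))
    dX = np.empty((q, L))
    drho = np.empty((q, nw))
    dr = np.empty((q, nw))
    Gbuf = np.empty((2, m, nw))
    ok = True

    for b in range(B):
        for i in range(m):
            states[b, 0, i] = c0[b, i]
        for k in range(n):
            for stage in range(2):
                ks = k + stage
                t = t0 + ks * h
                # ---- lagged input vector -------------------------
                for l in range(L):
                    s = src[l]
                    if s == -1:
                        v = t / tscale
                    elif s >= 0:
                        j = ks - off[l]
                        if j < 0:
                            j = 0
                        v = states[b, j, s]
                    else:
                        e = -2 - s
                        j = ks - off[l]
                        if j < 0:
                            j = 0
                        v = exseries[b, e, j]
                    if itanh[l]:
                        v = np.tanh(v)
                    X[l] = v
                # ---- network forward -----------------------------
                for i in range(H):
                    acc = b1[i]
                    for l in range(L):
                        acc += w1[i, l] * X[l]
                    g[i] = np.tanh(acc)
                    gp[i] = 1.0 - g[i] * g[i]
                for o in range(q):
                    acc = b2[o]
                    for i in range(H):
                        acc += w2[o, i] * g[i]
                    rho[o] = acc
                    pv = 1.0
                    if psi_idx[o] >= 0:
                        pv = states[b, ks, psi_idx[o]]
                    psiv[o] = pv
                    rate[o] = scale[o] * pv * acc
                # ---- material balance ----------------------------
                for i in range(m):
                    acc = u0[i] + useries[b, ks, i]
                    for o in range(q):
                        acc += K[i, o] * rate[o]
                    for j2 in range(m):
                        acc += A[i, j2] * states[b, ks, j2]
                    acc -= D[b, ks] * dmask[i] * states[b, ks, i]
                    fbuf[stage, i] = acc
                # ---- sensitivity right-hand side ------------------
                if with_sens:
                    for o in range(q):
                        for l in range(L):
                            acc = 0.0
                            for i in range(H):
                                acc += w2[o, i] * gp[i] * w1[i, l]
                            dX[o, l] = acc
                    for o in range(q):
                        for i in range(H):
                            a = w2[o, i] * gp[i]
                            base = i * L
                            for l in range(L):
                                drho[o, base + l] = a * X[l]
                            drho[o, H * L + i] = a
                        for o2 in range(q):
                            for i in range(H):
                                drho[o, H * L + H + o2 * H + i] = g[i] if o2 == o else 0.0
                        for o2 in range(q):
                            drho[o, H * L + H + q * H + o2] = 1.0 if o2 == o else 0.0
                    for l in range(L):
                        s = src[l]
                        if s >= 0:
                            j = ks - off[l]
                            if j < 0:
                                j = 0  # sens[b, 0] is zero: pre-history clamp
                            corr = 1.0
                            if itanh[l]:
                                corr = 1.0 - X[l] * X[l]
                            for o in range(q):
                                cc = dX[o, l] * corr
                                if cc != 0.0:
                                    for pp in range(nw):
                                        drho[o, pp] += cc * sens[b, j, s, pp]
                    for o in range(q):
                        for pp in range(nw):
                            v = scale[o] * psiv[o] * drho[o, pp]
                            if psi_idx[o] >= 0:
                                v += scale[o] * rho[o] * sens[b, ks, psi_idx[o], pp]
                            dr[o, pp] = v
                    for i in range(m):
                        for pp in range(nw):
                            acc = 0.0
                            for o in range(q):
                                acc += K[i, o] * dr[o, pp]
                            for j2 in range(m):
                                acc += A[i, j2] * sens[b, ks, j2, pp]
                            acc -= D[b, ks] * dmask[i] * sens[b, ks, i, pp]
                            Gbuf[stage, i, pp] = acc
                # ---- predictor ----------------------------------
                if stage == 0:
                    for i in range(m):
                        states[b, k + 1, i] = states[b, k, i] + h * fbuf[0, i]
                    if with_sens:
                        for i in range(m):
                            for pp in range(nw):
                                sens[b, k + 1, i, pp] = sens[b, k, i, pp] + h * Gbuf[0, i, pp]
            # ---- corrector (averaged rates) ----------------------
            bad = False
            for i in range(m):
                val = states[b, k, i] + 0.5 * h * (fbuf[0, i] + fbuf[1, i])
                states[b, k + 1, i] = val
                if not np.isfinite(val):
                    bad = True
            if with_sens:
                for i in range(m):
                    for pp in range(nw):
                        sens[b, k + 1, i, pp] = sens[b, k, i, pp] + 0.5 * h * (
                            Gbuf[0, i, pp] + Gbuf[1, i, pp]
                        )
            if bad:
                ok = False
                break
        if not ok:
            break
    return states, sens, ok
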