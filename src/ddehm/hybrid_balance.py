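"""Hybrid material-balance right-hand sides.

The hybrid model is

    dc/dt = K . (psi(X) * rho(X, w)) - D(t) . c + u(t)        (bioreactor)
    dc/dt = K . r + b - mu . c                                 (growth dilution)

with ``K`` the stoichiometric matrix, ``rho`` the neural network fed by
the lagged input vector ``X``, and ``psi`` optional parametric kinetic
factors.  With ``psi`` identically one, r = rho(X, w).

This module assembles the right-hand side from a declarative
:class:`HybridModelSpec` and provides the two case-study configurations:
a transcription-factor autoregulation model (structures "1B" without and
"1C" with prior knowledge) and a fed-batch *Pichia pastoris* model whose
network maps lagged methanol concentrations to the specific uptake,
growth and product-synthesis rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .lagged_inputs import HistoryBuffer, LagSeries, LagSpec, assemble_input_vector
from .neural_kinetics import MLPParams, forward, init_weights

__all__ = [
    "ConfigurationError",
    "TimeInput",
    "HybridModelSpec",
    "kinetic_rates",
    "rhs",
    "configure_tfa",
    "configure_pichia",
]


class ConfigurationError(ValueError):
    """Inconsistent hybrid model configuration."""


@dataclass(frozen=True)
class TimeInput:
    """Absolute-time ANN input.

    The raw feature is t / scale; with ``tanh`` set (the default, per the
    network layout with a hyperbolic-tangential transition at the time
    node) the feature passes through the activation at the input layer.
    """

    scale: float
    tanh: bool = True


# psi entries: None (factor 1), a state name (factor c_state(t)), or a
# (f, dfdc) pair of callables f(t, c) -> float, dfdc(t, c) -> (m,) array.
PsiTerm = object


@dataclass(frozen=True)
class HybridModelSpec:
    """Declarative structure of a hybrid DDE model.

    ``K`` has one row per state and one column per kinetic rate (= ANN
    output).  ``psi`` holds one parametric factor per rate.  Dilution is
    either a constant, the name of an exogenous record (e.g. "D" = F/V
    logged with the dataset), or — in growth mode — the designated
    growth-rate component of the rate vector itself.  ``A`` and ``u0``
    carry parametric linear loss terms and constant inputs (e.g. a
    first-order degradation and a basal synthesis rate);``feed_terms``
    adds coef * exog(t) to a state row (e.g. D*S_F on the substrate
    balance, F on the volume balance).
    """

    states: tuple[str, ...]
    K: np.ndarray
    lags: LagSpec
    hidden: int
    psi: tuple | None = None
    output_scale: np.ndarray | None = None
    time_input: TimeInput | None = None
    dilution: float | str | None = None
    dilution_mask: np.ndarray | None = None
    A: np.ndarray | None = None
    u0: np.ndarray | None = None
    feed_terms: tuple[tuple[str, str, float], ...] = ()
    growth_output: int | None = None
    b: np.ndarray | None = None
    name: str = "hybrid"

    def __post_init__(self):
        K = np.atleast_2d(np.asarray(self.K, float))
        object.__setattr__(self, "K", K)
        m, q = K.shape
        if len(self.states) != m:
            raise ConfigurationError("K must have one row per state")
        if self.psi is not None and len(self.psi) != q:
            raise ConfigurationError("psi must have one entry per kinetic rate")
        for s in self.lags.states:
            if s not in self.states:
                raise ConfigurationError(f"lag spec references unknown state {s!r}")
        scale = (
            np.ones(q) if self.output_scale is None else np.asarray(self.output_scale, float) * np.ones(q)
        )
        object.__setattr__(self, "output_scale", scale)
        mask = (
            np.ones(m, bool)
            if self.dilution_mask is None
            else np.asarray(self.dilution_mask, bool)
        )
        object.__setattr__(self, "dilution_mask", mask)
        if self.A is not None:
            object.__setattr__(self, "A", np.asarray(self.A, float).reshape(m, m))
        if self.u0 is not None:
            object.__setattr__(self, "u0", np.asarray(self.u0, float).reshape(m))
        if self.b is not None:
            object.__setattr__(self, "b", np.asarray(self.b, float).reshape(m))
        if self.growth_output is not None and not (0 <= self.growth_output < q):
            raise ConfigurationError("growth_output out of range")

    # -- dimensions -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_rates(self) -> int:
        return self.K.shape[1]

    @property
    def input_dim(self) -> int:
        """ANN input width: lagged variables plus the optional time node."""
        return self.lags.input_dim + (1 if self.time_input is not None else 0)

    @property
    def exog_names(self) -> tuple[str, ...]:
        """Exogenous records the model needs, in a fixed order."""
        names = list(self.lags.exog)
        if isinstance(self.dilution, str) and self.dilution not in names:
            names.append(self.dilution)
        for _, ex, _ in self.feed_terms:
            if ex not in names:
                names.append(ex)
        return tuple(names)

    def input_tanh_mask(self) -> np.ndarray:
        mask = np.zeros(self.input_dim, bool)
        if self.time_input is not None and self.time_input.tanh:
            mask[-1] = True
        return mask

    def init_params(self, seed) -> MLPParams:
        return init_weights(seed, self.input_dim, self.hidden, self.n_rates, self.input_tanh_mask())

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    # -- input assembly ---------------------------------------------
    def assemble_X(self, history: HistoryBuffer, exog_history, t: float) -> np.ndarray:
        X = assemble_input_vector(history, exog_history, t, self.lags)
        if self.time_input is not None:
            X = np.append(X, t / self.time_input.scale)
        return X

    def psi_values(self, t: float, c: np.ndarray) -> np.ndarray:
        vals = np.ones(self.n_rates)
        if self.psi is None:
            return vals
        for j, term in enumerate(self.psi):
            if term is None:
                continue
            if isinstance(term, str):
                vals[j] = c[self.state_index(term)]
            else:
                f, _ = term
                vals[j] = f(t, c)
        return vals


def _exog_value(exog_history: HistoryBuffer | None, name: str, t: float) -> float:
    if exog_history is None:
        raise ConfigurationError(f"model needs exogenous record {name!r} but none was given")
    return float(exog_history.evaluate(t)[exog_history.index(name)])


def kinetic_rates(
    t: float,
    history: HistoryBuffer,
    spec: HybridModelSpec,
    p: MLPParams,
    exog_history: HistoryBuffer | None = None,
    c: np.ndarray | None = None,
) -> np.ndarray:
    """Kinetic rate vector r = psi(X) * rho(X, w) (element-wise).

    ``c`` is the current state; if omitted it is read from the history
    head.  Lagged inputs clamp to their initial values before t0.
    """
    if c is None:
        c = history.evaluate(t)
    X = spec.assemble_X(history, exog_history, t)
    rho = forward(X, p)
    return spec.output_scale * spec.psi_values(t, c) * rho


def rhs(
    t: float,
    c: np.ndarray,
    history: HistoryBuffer,
    spec: HybridModelSpec,
    p: MLPParams,
    exog_history: HistoryBuffer | None = None,
) -> np.ndarray:
    """Hybrid balance dc/dt = K.r - D.c + u (or K.r + b - mu.c in growth mode)."""
    c = np.asarray(c, float)
    r = kinetic_rates(t, history, spec, p, exog_history, c=c)
    dc = spec.K @ r
    if spec.growth_output is not None:
        mu = r[spec.growth_output]
        dc = dc - mu * c
        if spec.b is not None:
            dc = dc + spec.b
    else:
        D = 0.0
        if isinstance(spec.dilution, str):
            D = _exog_value(exog_history, spec.dilution, t)
        elif spec.dilution is not None:
            D = float(spec.dilution)
        if D != 0.0:
            dc = dc - D * np.where(spec.dilution_mask, c, 0.0)
    if spec.A is not None:
        dc = dc + spec.A @ c
    if spec.u0 is not None:
        dc = dc + spec.u0
    for state, ex, coef in spec.feed_terms:
        dc[spec.state_index(state)] += coef * _exog_value(exog_history, ex, t)
    return dc


# ----------------------------------------------------------------------
# Case-study configurations
# ----------------------------------------------------------------------

def configure_tfa(
    structure: str = "1C",
    hidden: int = 5,
    lagspec: LagSpec | None = None,
    *,
    tau: float = 120.0,
    n_lags: int = 1,
    kd_deg: float = 0.05,
    r_bas: float = 0.005,
    time_scale: float = 240.0,
    time_input: bool = True,
    output_scale: float = 0.1,
) -> HybridModelSpec:
    """Transcription-factor hybrid structure.

    "1B": dx/dt = rho(X, w) — no mechanistic term at all.
    "1C": dx/dt = rho1(X, w) - kd_deg*x + R_bas — the network covers the
    (delayed) synthesis kinetics, degradation and basal production are
    parametric.  Both carry an absolute-time input node (tanh transition)
    so the network can represent the unmeasured induction event.
    """
    if structure not in ("1B", "1C"):
        raise ConfigurationError(f"unknown TF-A structure {structure!r} (use '1B' or '1C')")
    if lagspec is None:
        lagspec = LagSpec(states={"x": LagSeries(tau=tau, n_lags=n_lags)})
    kw = dict(
        states=("x",),
        K=np.array([[1.0]]),
        lags=lagspec,
        hidden=hidden,
        output_scale=np.array([output_scale]),
        time_input=TimeInput(scale=time_scale) if time_input else None,
        name=f"tfa-{structure}",
    )
    if structure == "1C":
        kw["A"] = np.array([[-kd_deg]])
        kw["u0"] = np.array([r_bas])
    return HybridModelSpec(**kw)


def configure_pichia(
    hidden: int = 5,
    lagspec: LagSpec | None = None,
    *,
    tau: float = 2.5,
    n_lags: int = 4,
    s_feed: float = 100.0,
    output_scale: Sequence[float] = (0.1, 0.03, 0.003),
) -> HybridModelSpec:
    """Fed-batch *Pichia pastoris* hybrid structure.

    States (X, S, P, V); the network maps present and lagged methanol
    concentrations S to the specific rates (r_S, mu, r_P), each
    multiplied by biomass X; balances:

        dX/dt = mu*X - D*X          dS/dt = -r_S*X - D*(S - S_F)
        dP/dt = r_P*X - D*P         dV/dt = F

    D = F/V and F are exogenous records carried by the dataset.
    """
    if lagspec is None:
        lagspec = LagSpec(states={"S": LagSeries(tau=tau, n_lags=n_lags)})
    for name in lagspec.states:
        if name != "S":
            raise ConfigurationError(
                "Pichia structure takes only the substrate S as network input"
            )
    if lagspec.exog:
        raise ConfigurationError("Pichia structure takes no exogenous network inputs")
    # rate order: (r_S, mu, r_P)
    K = np.array(
        [
            [0.0, 1.0, 0.0],   # X: + mu*X
            [-1.0, 0.0, 0.0],  # S: - r_S*X
            [0.0, 0.0, 1.0],   # P: + r_P*X
            [0.0, 0.0, 0.0],   # V: feed only
        ]
    )
    return HybridModelSpec(
        states=("X", "S", "P", "V"),
        K=K,
        lags=lagspec,
        hidden=hidden,
        psi=("X", "X", "X"),
        output_scale=np.asarray(output_scale, float),
        dilution="D",
        dilution_mask=np.array([1, 1, 1, 0], bool),
        feed_terms=(("S", "D", s_feed), ("V", "F", 1.0)),
        name="pichia",
    )
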