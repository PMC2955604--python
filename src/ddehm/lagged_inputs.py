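"""Discrete time-lagged input vectors for hybrid kinetic models.

The nonparametric kinetic term is fed with an input vector

    X = [c_i(t), c_i(t-tau_i), ..., c_i(t-N_i*tau_i),
         s_j(t), s_j(t-tau_j), ..., s_j(t-M_j*tau_j)]

containing the present and discrete past values of the state variables
``c`` and exogenous inputs ``s``.  Lag interval and lag count are chosen
independently per variable.  Before the initial time all lagged values
clamp to the value at ``t0`` (states and exogenous inputs alike).

Ordering convention (fixed, serialized with the spec): all lags of the
first declared state, then the second state, ..., then exogenous inputs
in declared order; within a variable, lags in increasing offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LagSeries",
    "LagSpec",
    "HistoryBuffer",
    "lag_times",
    "evaluate_delayed",
    "assemble_input_vector",
]


class UnknownVariableError(KeyError):
    """A variable name not present in the lag specification."""


@dataclass(frozen=True)
class LagSeries:
    """Lag series of one variable.

    Either a uniform series (``tau``, ``n_lags`` -> offsets 0, tau, ...,
    n_lags*tau) or an explicit tuple of positive ``offsets`` (offset 0,
    the instantaneous value, is always included implicitly).  Explicit
    offsets cover mixed delay sets such as {80, 120} min.
    """

    tau: float = 0.0
    n_lags: int = 0
    offsets: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.offsets is not None:
            off = tuple(float(o) for o in self.offsets)
            if any(o <= 0 for o in off):
                raise ValueError("explicit lag offsets must be positive")
            if list(off) != sorted(off) or len(set(off)) != len(off):
                raise ValueError("explicit lag offsets must be strictly increasing")
            object.__setattr__(self, "offsets", off)
            return
        if self.n_lags < 0:
            raise ValueError("lag count must be non-negative")
        if self.n_lags > 0 and self.tau <= 0:
            raise ValueError("lag interval tau must be positive when n_lags > 0")

    @property
    def lag_offsets(self) -> np.ndarray:
        """Offsets [0, tau, 2 tau, ..., N tau] (or [0, *offsets])."""
        if self.offsets is not None:
            return np.concatenate([[0.0], np.asarray(self.offsets, float)])
        return self.tau * np.arange(self.n_lags + 1, dtype=float)

    @property
    def width(self) -> int:
        return len(self.offsets) + 1 if self.offsets is not None else self.n_lags + 1

    def to_dict(self) -> dict:
        if self.offsets is not None:
            return {"offsets": list(self.offsets)}
        return {"tau": self.tau, "n_lags": self.n_lags}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LagSeries":
        if "offsets" in d:
            return cls(offsets=tuple(d["offsets"]))
        return cls(tau=float(d.get("tau", 0.0)), n_lags=int(d.get("n_lags", 0)))


@dataclass(frozen=True)
class LagSpec:
    """Per-variable lag structure of the ANN input vector.

    ``states`` and ``exog`` map variable name -> :class:`LagSeries` in
    declaration order.  A variable absent from the mapping is not an ANN
    input at all; a variable with ``n_lags == 0`` contributes only its
    instantaneous value (the "no delay" model).
    """

    states: Mapping[str, LagSeries] = field(default_factory=dict)
    exog: Mapping[str, LagSeries] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", dict(self.states))
        object.__setattr__(self, "exog", dict(self.exog))

    @property
    def input_dim(self) -> int:
        """Total ANN input width, sum_i (N_i+1) + sum_j (M_j+1)."""
        return sum(s.width for s in self.states.values()) + sum(
            s.width for s in self.exog.values()
        )

    @property
    def max_delay(self) -> float:
        offs = [s.lag_offsets[-1] for s in list(self.states.values()) + list(self.exog.values())]
        return float(max(offs)) if offs else 0.0

    @property
    def all_offsets(self) -> np.ndarray:
        """Sorted unique positive lag offsets across all variables."""
        offs = np.concatenate(
            [s.lag_offsets for s in list(self.states.values()) + list(self.exog.values())]
            or [np.empty(0)]
        )
        offs = np.unique(offs)
        return offs[offs > 0]

    def series(self, variable: str) -> LagSeries:
        if variable in self.states:
            return self.states[variable]
        if variable in self.exog:
            return self.exog[variable]
        raise UnknownVariableError(variable)

    def to_dict(self) -> dict:
        return {
            "states": {k: v.to_dict() for k, v in self.states.items()},
            "exog": {k: v.to_dict() for k, v in self.exog.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LagSpec":
        return cls(
            states={k: LagSeries.from_dict(v) for k, v in d.get("states", {}).items()},
            exog={k: LagSeries.from_dict(v) for k, v in d.get("exog", {}).items()},
        )


def lag_times(spec: LagSpec, variable: str) -> np.ndarray:
    """Lag offsets [0, tau, 2 tau, ..., N tau] for ``variable``.

    Raises :class:`UnknownVariableError` for names absent from the spec.
    """
    return spec.series(variable).lag_offsets


class HistoryBuffer:
    """Ordered record of (time, state-vector) pairs from ``t0`` onwards.

    Queries below ``t0`` return ``c(t0)`` exactly (pre-history clamping);
    queries between stored points are linearly interpolated; queries
    beyond the stored range raise (the integrator must never look into
    the future).
    """

    def __init__(self, names: tuple[str, ...], t0: float, c0: np.ndarray, capacity: int = 64):
        c0 = np.atleast_1d(np.asarray(c0, float))
        if len(names) != c0.shape[0]:
            raise ValueError("names/state dimension mismatch")
        self.names = tuple(names)
        self._t = np.empty(capacity)
        self._c = np.empty((capacity, c0.shape[0]))
        self._t[0] = t0
        self._c[0] = c0
        self._n = 1

    @property
    def t0(self) -> float:
        return float(self._t[0])

    @property
    def c0(self) -> np.ndarray:
        return self._c[0]

    @property
    def t_last(self) -> float:
        return float(self._t[self._n - 1])

    @property
    def times(self) -> np.ndarray:
        return self._t[: self._n]

    @property
    def values(self) -> np.ndarray:
        return self._c[: self._n]

    def append(self, t: float, c: np.ndarray) -> None:
        if t <= self.t_last:
            raise ValueError("history times must be strictly increasing")
        if self._n == self._t.shape[0]:
            self._t = np.concatenate([self._t, np.empty_like(self._t)])
            self._c = np.concatenate([self._c, np.empty_like(self._c)])
        self._t[self._n] = t
        self._c[self._n] = np.asarray(c, float)
        self._n += 1

    def replace_last(self, t: float, c: np.ndarray) -> None:
        """Overwrite the most recent record (predictor -> corrector update)."""
        self._t[self._n - 1] = t
        self._c[self._n - 1] = np.asarray(c, float)

    def evaluate(self, t: float) -> np.ndarray:
        """State at time ``t`` (clamped below ``t0``, interpolated inside)."""
        if t <= self.t0:
            return self._c[0].copy()
        if t > self.t_last + 1e-12 * max(1.0, abs(self.t_last)):
            raise ValueError(
                f"query at t={t} beyond buffered range (last stored t={self.t_last})"
            )
        t = min(t, self.t_last)
        i = int(np.searchsorted(self._t[: self._n], t, side="right")) - 1
        if i >= self._n - 1:
            return self._c[self._n - 1].copy()
        t_lo, t_hi = self._t[i], self._t[i + 1]
        w = (t - t_lo) / (t_hi - t_lo)
        return (1.0 - w) * self._c[i] + w * self._c[i + 1]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise UnknownVariableError(name) from None


def evaluate_delayed(history: HistoryBuffer, t: float, offset: float) -> np.ndarray:
    """State vector at ``t - offset``; exactly ``c(t0)`` for ``t - offset < t0``."""
    if offset < 0:
        raise ValueError("lag offset must be non-negative")
    return history.evaluate(t - offset)


def assemble_input_vector(
    history: HistoryBuffer,
    exog_history: HistoryBuffer | None,
    t: float,
    spec: LagSpec,
) -> np.ndarray:
    """Assemble the lagged ANN input vector X at time ``t``.

    Ordering: states in spec declaration order (lags in increasing
    offset), then exogenous inputs likewise.  Length equals
    ``spec.input_dim``.
    """
    parts: list[float] = []
    for name, series in spec.states.items():
        i = history.index(name)
        for off in series.lag_offsets:
            parts.append(evaluate_delayed(history, t, off)[i])
    if spec.exog:
        if exog_history is None:
            raise ValueError("lag spec references exogenous inputs but no exogenous history given")
        for name, series in spec.exog.items():
            j = exog_history.index(name)
            for off in series.lag_offsets:
                parts.append(evaluate_delayed(exog_history, t, off)[j])
    return np.asarray(parts, float)
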