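"""Three-layer feed-forward network for nonparametric kinetic rates.

rho(X, w) = w2 . g(w1 . X + b1) + b2, with the hyperbolic tangential
activation g(y) = (1 - e^(-2y)) / (1 + e^(-2y)) = tanh(y).  Input and
output nodes are linear, except inputs flagged ``input_tanh`` (used for
an absolute-time input), which pass through g before the first weight
layer.  Analytic first derivatives with respect to both the inputs and
the flattened weight vector are provided; they are what makes exact
sensitivity-equation gradients possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MLPParams",
    "activation",
    "forward",
    "jacobian_inputs",
    "jacobian_weights",
    "init_weights",
]


def activation(y):
    """Hyperbolic tangential activation, (1 - e^(-2y)) / (1 + e^(-2y)).

    Algebraically identical to tanh(y); evaluated as ``numpy.tanh`` so it
    saturates to +-1 without overflow for large |y|.
    """
    return np.tanh(y)


@dataclass
class MLPParams:
    """Weights and biases of the three-layer network.

    Shapes: ``w1`` (hidden, input), ``b1`` (hidden,), ``w2`` (output,
    hidden), ``b2`` (output,).  ``input_tanh`` flags inputs that pass
    through the activation before ``w1`` (all-False by default).  The
    flattening order of the parameter vector is fixed as
    ``[w1.ravel(), b1, w2.ravel(), b2]`` and round-trips through both
    :meth:`flatten`/:meth:`with_flat` and JSON serialization.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    input_tanh: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, float)
        self.b1 = np.asarray(self.b1, float)
        self.w2 = np.asarray(self.w2, float)
        self.b2 = np.asarray(self.b2, float)
        H, L = self.w1.shape
        q = self.b2.shape[0]
        if self.b1.shape != (H,) or self.w2.shape != (q, H):
            raise ValueError("inconsistent layer shapes")
        if self.input_tanh is None:
            self.input_tanh = np.zeros(L, dtype=bool)
        else:
            self.input_tanh = np.asarray(self.input_tanh, bool)
            if self.input_tanh.shape != (L,):
                raise ValueError("input_tanh must have one flag per input")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.w2.shape[0]

    @property
    def n_w(self) -> int:
        """Total scalar parameter count."""
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def with_flat(self, w: np.ndarray) -> "MLPParams":
        """New params with the same shapes from a flat vector."""
        w = np.asarray(w, float)
        if w.shape != (self.n_w,):
            raise ValueError("flat parameter vector has wrong length")
        H, L, q = self.n_hidden, self.n_inputs, self.n_outputs
        i = 0
        w1 = w[i : i + H * L].reshape(H, L); i += H * L
        b1 = w[i : i + H]; i += H
        w2 = w[i : i + q * H].reshape(q, H); i += q * H
        b2 = w[i : i + q]
        return MLPParams(w1, b1, w2, b2, self.input_tanh.copy())

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "input_tanh": self.input_tanh.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d) -> "MLPParams":
        return cls(
            np.array(d["w1"], float),
            np.array(d["b1"], float),
            np.array(d["w2"], float),
            np.array(d["b2"], float),
            np.array(d.get("input_tanh", np.zeros(len(d["w1"][0]))), bool),
        )


def _effective_input(X: np.ndarray, p: MLPParams) -> np.ndarray:
    if p.input_tanh.any():
        X = np.where(p.input_tanh, np.tanh(X), X)
    return X


def forward(X: np.ndarray, p: MLPParams) -> np.ndarray:
    """rho = w2 . g(w1 . X + b1) + b2 for a single input vector or a batch.

    ``X`` of shape (L,) returns (q,); shape (B, L) returns (B, q).
    """
    X = np.asarray(X, float)
    if X.shape[-1] != p.n_inputs:
        raise ValueError(
            f"input width {X.shape[-1]} does not match network input layer {p.n_inputs}"
        )
    Xe = _effective_input(X, p)
    g = np.tanh(Xe @ p.w1.T + p.b1)
    return g @ p.w2.T + p.b2


def jacobian_inputs(X: np.ndarray, p: MLPParams) -> np.ndarray:
    """d rho / d X, shape (q, L), for a single input vector.

    w2 . diag(1 - g(h)^2) . w1 with h = w1.X + b1, corrected by the
    input-tanh flags where set.
    """
    X = np.asarray(X, float)
    Xe = _effective_input(X, p)
    g = np.tanh(p.w1 @ Xe + p.b1)
    J = (p.w2 * (1.0 - g**2)) @ p.w1
    if p.input_tanh.any():
        J = J * np.where(p.input_tanh, 1.0 - np.tanh(X) ** 2, 1.0)
    return J


def jacobian_weights(X: np.ndarray, p: MLPParams) -> np.ndarray:
    """d rho / d w, shape (q, n_w), flat order [w1, b1, w2, b2]."""
    X = np.asarray(X, float)
    Xe = _effective_input(X, p)
    H, L, q = p.n_hidden, p.n_inputs, p.n_outputs
    g = np.tanh(p.w1 @ Xe + p.b1)
    gp = 1.0 - g**2
    J = np.zeros((q, p.n_w))
    a = p.w2 * gp  # (q, H): d rho_o / d h_i
    J[:, : H * L] = (a[:, :, None] * Xe[None, None, :]).reshape(q, H * L)
    J[:, H * L : H * L + H] = a
    i0 = H * L + H
    for o in range(q):
        J[o, i0 + o * H : i0 + (o + 1) * H] = g
    J[:, i0 + q * H :] = np.eye(q)
    return J


def init_weights(
    seed,
    input_dim: int,
    hidden_dim: int,
    output_dim: int,
    input_tanh: np.ndarray | None = None,
) -> MLPParams:
    """Random small-scale symmetric initialization.

    Weights and biases are uniform on [-0.5, 0.5] scaled by 1/sqrt(fan-in),
    which keeps hidden units in the active region of the activation.
    ``seed`` may be an int or a ``numpy`` Generator; the same seed always
    yields identical parameters.
    """
    if input_dim <= 0 or hidden_dim <= 0 or output_dim <= 0:
        raise ValueError("layer dimensions must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s1 = 1.0 / np.sqrt(input_dim)
    s2 = 1.0 / np.sqrt(hidden_dim)
    w1 = rng.uniform(-0.5, 0.5, (hidden_dim, input_dim)) * s1
    b1 = rng.uniform(-0.5, 0.5, hidden_dim) * s1
    w2 = rng.uniform(-0.5, 0.5, (output_dim, hidden_dim)) * s2
    b2 = rng.uniform(-0.5, 0.5, output_dim) * s2
    return MLPParams(w1, b1, w2, b2, input_tanh)
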