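"""Single-hidden-layer feed-forward network for flux soft-sensing.

Architecture: tansig (hyperbolic tangent sigmoid) hidden units and a purelin
(identity) output,

    yhat = w_out . tanh(W_in x + b_hidden) + b_out.

Two trainers are provided. ``train_gdm`` is full-batch gradient descent with
momentum: dw(t) = mc * dw(t-1) - lr * grad E(w), with E the mean squared
error. ``train_lm`` is Levenberg-Marquardt on the Jacobian of per-sample
residuals: solve (J'J + mu I) step = -J'e, accept the step when the error sum
of squares decreases (mu shrinks by 10) and reject otherwise (mu grows by 10,
up to a ceiling). LM ignores the learning rate and momentum — they may still
appear in a TrainConfig because hyperparameter studies vary them across both
algorithms — and only the damping schedule governs its steps.

Inputs and the target are expected on a common [0, 1] min-max scale (see
:func:`normalize`); error metrics are then on the normalized scale too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Network",
    "TrainConfig",
    "NormalizationParams",
    "TrainingDivergedError",
    "TrainingStalledError",
    "normalize",
    "denormalize",
    "fit_normalization",
    "init_network",
    "forward",
    "gradient",
    "jacobian",
    "train_gdm",
    "train_lm",
    "train",
    "check_neuron_bounds",
    "mse",
    "corr_coeff",
]


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite error; carries the epoch index."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged to non-finite MSE at epoch {epoch}")


class TrainingStalledError(RuntimeError):
    """LM normal equations became unsolvable at the damping ceiling."""


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel min/max in original units, fitted on training data only."""

    y_min: np.ndarray
    y_max: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.y_min, dtype=float))
        hi = np.atleast_1d(np.asarray(self.y_max, dtype=float))
        if np.any(hi <= lo):
            bad = int(np.flatnonzero(hi <= lo)[0])
            raise ValueError(f"channel {bad} is constant (min {lo[bad]} >= max {hi[bad]})")
        object.__setattr__(self, "y_min", lo)
        object.__setattr__(self, "y_max", hi)


def fit_normalization(data: np.ndarray) -> NormalizationParams:
    """Min-max parameters per column of ``data`` (2-D) or of a single series."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return NormalizationParams(arr.min(axis=0), arr.max(axis=0))


def normalize(data, params: NormalizationParams) -> np.ndarray:
    """Scale to [0, 1] channel-wise: (y - y_min) / (y_max - y_min)."""
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = (arr - params.y_min) / (params.y_max - params.y_min)
    return out[:, 0] if squeeze else out


def denormalize(data, params: NormalizationParams) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = arr * (params.y_max - params.y_min) + params.y_min
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# network

@dataclass
class Network:
    """Weights and biases of a tansig/purelin single-hidden-layer net."""

    input_weights: np.ndarray   # (n_hidden, n_inputs)
    hidden_biases: np.ndarray   # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    output_bias: float
    hidden_transfer: str = "tansig"
    output_transfer: str = "purelin"

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]

    @property
    def n_params(self) -> int:
        return self.n_hidden * (self.n_inputs + 2) + 1

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [
                self.input_weights.ravel(),
                self.hidden_biases,
                self.output_weights,
                [self.output_bias],
            ]
        )

    def unpack(self, theta: np.ndarray) -> "Network":
        nh, ni = self.input_weights.shape
        w_in = theta[: nh * ni].reshape(nh, ni)
        b_h = theta[nh * ni : nh * ni + nh]
        w_out = theta[nh * ni + nh : nh * ni + 2 * nh]
        b_out = float(theta[-1])
        return Network(w_in.copy(), b_h.copy(), w_out.copy(), b_out)

    def copy(self) -> "Network":
        return Network(
            self.input_weights.copy(),
            self.hidden_biases.copy(),
            self.output_weights.copy(),
            self.output_bias,
        )

    def to_json(self, norm_in: NormalizationParams | None = None,
                norm_out: NormalizationParams | None = None) -> str:
        payload = {
            "input_weights": self.input_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "hidden_transfer": self.hidden_transfer,
            "output_transfer": self.output_transfer,
        }
        if norm_in is not None:
            payload["input_norm"] = {"min": norm_in.y_min.tolist(), "max": norm_in.y_max.tolist()}
        if norm_out is not None:
            payload["output_norm"] = {"min": norm_out.y_min.tolist(), "max": norm_out.y_max.tolist()}
        return json.dumps(payload)

    @staticmethod
    def from_json(text: str) -> "Network":
        d = json.loads(text)
        return Network(
            np.asarray(d["input_weights"], dtype=float),
            np.asarray(d["hidden_biases"], dtype=float),
            np.asarray(d["output_weights"], dtype=float),
            float(d["output_bias"]),
            d.get("hidden_transfer", "tansig"),
            d.get("output_transfer", "purelin"),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters: the five tunable factors plus bookkeeping."""

    n_hidden: int = 16
    learning_rate: float = 0.16
    momentum: float = 0.75
    epochs: int = 850
    algorithm: str = "lm"  # "lm" | "gdm"
    seed: int = 0
    goal_mse: float | None = None
    matlab_momentum: bool = False  # scale the gradient step by (1 - momentum)

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.algorithm not in ("lm", "gdm"):
            raise ValueError("algorithm must be 'lm' or 'gdm'")


def init_network(n_inputs: int, config: TrainConfig) -> Network:
    """Seeded Nguyen-Widrow-style initialization.

    Hidden input weights are drawn uniform in [-1, 1] and row-scaled to the
    Nguyen-Widrow magnitude 0.7 * n_hidden**(1/n_inputs); hidden biases are
    spread uniformly across the active region. Identical seeds give identical
    networks.
    """
    rng = np.random.default_rng(config.seed)
    nh, ni = config.n_hidden, n_inputs
    w = rng.uniform(-1.0, 1.0, size=(nh, ni))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scale = 0.7 * nh ** (1.0 / ni)
    w = scale * w / norms
    if nh > 1:
        b = scale * np.linspace(-1.0, 1.0, nh) * np.sign(w[:, 0])
    else:
        b = np.zeros(1)
    w_out = rng.uniform(-0.5, 0.5, size=nh)
    b_out = float(rng.uniform(-0.5, 0.5))
    return Network(w, b, w_out, b_out)


def forward(net: Network, X: np.ndarray) -> np.ndarray:
    """Predictions for samples in rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.n_inputs:
        raise ValueError(f"expected {net.n_inputs} input columns, got {X.shape[1]}")
    h = np.tanh(X @ net.input_weights.T + net.hidden_biases)
    return h @ net.output_weights + net.output_bias


def _forward_hidden(net: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.tanh(X @ net.input_weights.T + net.hidden_biases)
    return h, h @ net.output_weights + net.output_bias


def jacobian(net: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian d yhat_i / d theta (n_samples x n_params) and predictions.

    Parameter order matches :meth:`Network.pack`: input weights (row-major),
    hidden biases, output weights, output bias.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    h, yhat = _forward_hidden(net, X)
    n, nh, ni = X.shape[0], net.n_hidden, net.n_inputs
    dtanh = (1.0 - h ** 2) * net.output_weights  # (n, nh)
    J = np.empty((n, net.n_params))
    # d/dW_in[j, l] = w_out_j * (1 - h_j^2) * x_l
    J[:, : nh * ni] = (dtanh[:, :, None] * X[:, None, :]).reshape(n, nh * ni)
    J[:, nh * ni : nh * ni + nh] = dtanh
    J[:, nh * ni + nh : nh * ni + 2 * nh] = h
    J[:, -1] = 1.0
    return J, yhat


def gradient(net: Network, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of the mean squared error with respect to packed parameters."""
    J, yhat = jacobian(net, X)
    e = yhat - np.asarray(y, dtype=float)
    return (2.0 / len(e)) * (J.T @ e)


def train_gdm(net: Network, X: np.ndarray, y: np.ndarray, config: TrainConfig):
    """Full-batch gradient descent with momentum; returns (net, per-epoch MSE).

    The update is dw(t) = mc*dw(t-1) - lr*grad E; with ``matlab_momentum`` the
    gradient step is additionally scaled by (1 - mc), matching MATLAB's
    traingdm convention. Raises :class:`TrainingDivergedError` on non-finite
    error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    theta = net.pack()
    velocity = np.zeros_like(theta)
    mc, lr = config.momentum, config.learning_rate
    step_scale = lr * (1.0 - mc) if config.matlab_momentum else lr
    trace = []
    current = net.copy()
    for epoch in range(config.epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            g = gradient(current, X, y)
            velocity = mc * velocity - step_scale * g
            theta = theta + velocity
            current = net.unpack(theta)
            e = forward(current, X) - y
            m = float(np.mean(e ** 2))
        if not np.isfinite(m):
            raise TrainingDivergedError(epoch)
        trace.append(m)
        if config.goal_mse is not None and m <= config.goal_mse:
            break
    return current, np.asarray(trace)


def train_lm(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    mu0: float = 1e-3,
    mu_factor: float = 10.0,
    mu_max: float = 1e10,
):
    """Levenberg-Marquardt training; returns (net, per-epoch MSE trace).

    Each epoch solves (J'J + mu I) step = -J'e and accepts the step only if
    the SSE decreases, so the trace is strictly decreasing over accepted
    steps. Stops at the epoch budget, the MSE goal, or when mu exceeds
    ``mu_max``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    current = net.copy()
    theta = current.pack()
    mu = mu0
    e = forward(current, X) - y
    sse = float(e @ e)
    trace = []
    eye = np.eye(net.n_params)
    for epoch in range(config.epochs):
        J, yhat = jacobian(current, X)
        e = yhat - y
        g = J.T @ e
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * eye, -g)
            except np.linalg.LinAlgError:
                if mu >= mu_max:
                    raise TrainingStalledError(
                        f"singular normal equations at mu ceiling (epoch {epoch})"
                    )
                mu *= mu_factor
                continue
            trial = current.unpack(theta + step)
            e_trial = forward(trial, X) - y
            sse_trial = float(e_trial @ e_trial)
            if np.isfinite(sse_trial) and sse_trial < sse:
                theta = theta + step
                current = trial
                sse = sse_trial
                mu = max(mu / mu_factor, 1e-20)
                accepted = True
                break
            mu *= mu_factor
        if not accepted:
            break  # mu ceiling reached with no improving step
        m = sse / len(y)
        trace.append(m)
        if config.goal_mse is not None and m <= config.goal_mse:
            break
    return current, np.asarray(trace)


def train(net: Network, X, y, config: TrainConfig):
    """Dispatch on ``config.algorithm``."""
    if config.algorithm == "gdm":
        return train_gdm(net, X, y, config)
    return train_lm(net, X, y, config)


# ---------------------------------------------------------------------------
# diagnostics and metrics

@dataclass(frozen=True)
class NeuronBoundReport:
    n_hidden: int
    structural_bound: int       # 2*n_inputs + 1
    sample_bound: float         # n_train / (n_inputs + 1)
    structural_ok: bool
    sample_ok: bool


def check_neuron_bounds(n_hidden: int, n_inputs: int, n_train_samples: int) -> NeuronBoundReport:
    """Check the two rule-of-thumb hidden-neuron bounds and warn on violation.

    The structural bound caps hidden units at 2*inputs + 1; the sample bound
    at training-samples / (inputs + 1). Both are advisory — exceeding them is
    common practice — so violations emit warnings, never errors.
    """
    if min(n_hidden, n_inputs, n_train_samples) < 1:
        raise ValueError("counts must be positive")
    structural = 2 * n_inputs + 1
    sample = n_train_samples / (n_inputs + 1)
    rep = NeuronBoundReport(
        n_hidden, structural, sample, n_hidden <= structural, n_hidden <= sample
    )
    if not rep.structural_ok:
        warnings.warn(
            f"{n_hidden} hidden neurons exceeds the structural bound {structural}",
            stacklevel=2,
        )
    if not rep.sample_ok:
        warnings.warn(
            f"{n_hidden} hidden neurons exceeds the sample-size bound {sample:.0f}",
            stacklevel=2,
        )
    return rep


def mse(y, yhat) -> float:
    """Mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    return float(np.mean((yhat - y) ** 2))


def corr_coeff(y, yhat) -> float:
    """Pearson correlation coefficient between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    sy = y - y.mean()
    sh = yhat - yhat.mean()
    denom = np.sqrt((sy @ sy) * (sh @ sh))
    if denom == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(np.clip((sy @ sh) / denom, -1.0, 1.0))
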