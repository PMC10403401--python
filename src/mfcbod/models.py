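"""Multilayer perceptrons for direct BOD5 regression and voltage curve completion.

Twelve fixed architectures are registered: for each of the six input windows
there is a *direct* network (window -> one BOD5 value, learning rate 1e-3)
and an *indirect* network (window -> remaining voltage curve, learning rate
1e-4).  All have three ReLU hidden layers, per-layer dropout, a linear
output, and are trained full-batch with Adam on a mean-squared-error loss.

The networks are implemented directly in NumPy (forward, backprop, Adam) so
training is deterministic given a seed and carries no framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .core import CANONICAL_LENGTH, WINDOW_HOURS, WindowSpec

Approach = Literal["direct", "indirect"]

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-7  # Keras default

LEARNING_RATE_DIRECT = 1e-3
LEARNING_RATE_INDIRECT = 1e-4

#: Default epoch counts.  The source study selected epochs per network by
#: cross-validation and did not publish them; these defaults were tuned on
#: synthetic data and are meant to be overridden by ``cross_validate``.
DEFAULT_EPOCHS = {"direct": 600, "indirect": 500}

# (hidden widths, dropout rates) keyed by input size; registry of the 12
# published architectures.
_DIRECT_REGISTRY: dict[int, tuple[tuple[int, int, int], tuple[float, float, float]]] = {
    25: ((128, 128, 64), (0.30, 0.30, 0.50)),
    73: ((128, 128, 64), (0.10, 0.50, 0.50)),
    97: ((128, 64, 64), (0.10, 0.30, 0.50)),
    145: ((96, 96, 64), (0.10, 0.10, 0.40)),
    193: ((128, 128, 128), (0.10, 0.30, 0.30)),
    289: ((128, 128, 64), (0.10, 0.10, 0.30)),
}
_INDIRECT_REGISTRY: dict[int, tuple[tuple[int, int, int], tuple[float, float, float]]] = {
    25: ((128, 128, 64), (0.30, 0.30, 0.50)),
    73: ((128, 64, 64), (0.20, 0.50, 0.50)),
    97: ((128, 128, 64), (0.25, 0.50, 0.50)),
    145: ((128, 64, 64), (0.10, 0.30, 0.50)),
    193: ((128, 64, 64), (0.10, 0.10, 0.50)),
    289: ((128, 128, 64), (0.10, 0.20, 0.50)),
}


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of one network."""

    n_input: int
    hidden: tuple[int, int, int]
    dropout: tuple[float, float, float]
    n_output: int
    learning_rate: float
    loss: Literal["mse_direct", "mse_indirect"]
    epochs: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) != 3 or len(self.dropout) != 3:
            raise ValueError("exactly three hidden layers are supported")
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be positive")
        if any(not 0 <= p < 1 for p in self.dropout):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.n_input < 1 or self.n_output < 1:
            raise ValueError("n_input and n_output must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def approach(self) -> Approach:
        return "direct" if self.loss == "mse_direct" else "indirect"


def registry_config(
    window: WindowSpec,
    approach: Approach,
    epochs: Optional[int] = None,
    seed: int = 0,
) -> MLPConfig:
    """The registered architecture for a given window and approach."""
    if approach == "direct":
        table, n_output, lr, loss = _DIRECT_REGISTRY, 1, LEARNING_RATE_DIRECT, "mse_direct"
    elif approach == "indirect":
        table = _INDIRECT_REGISTRY
        n_output, lr, loss = CANONICAL_LENGTH - window.n_input, LEARNING_RATE_INDIRECT, "mse_indirect"
    else:
        raise ValueError(f"unknown approach {approach!r}")
    try:
        hidden, dropout = table[window.n_input]
    except KeyError:  # pragma: no cover - WindowSpec already validates hours
        raise KeyError(f"no registered architecture for input size {window.n_input}")
    return MLPConfig(
        n_input=window.n_input,
        hidden=hidden,
        dropout=dropout,
        n_output=n_output,
        learning_rate=lr,
        loss=loss,
        epochs=epochs if epochs is not None else DEFAULT_EPOCHS[approach],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# network internals


def _init_weights(config: MLPConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Glorot-uniform weights, zero biases."""
    dims = [config.n_input, *config.hidden, config.n_output]
    layers = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        layers.append((w, np.zeros(fan_out)))
    return layers


def _forward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    x: np.ndarray,
    dropout: Sequence[float],
    rng: Optional[np.random.Generator],
):
    """Forward pass; dropout masks are drawn only when ``rng`` is given.

    Returns (output, caches) where caches hold the per-layer activations and
    dropout masks needed by backprop.  Inverted dropout keeps inference
    activations on the training scale.
    """
    a = x
    caches = []
    n_hidden = len(weights) - 1
    for li, (w, b) in enumerate(weights):
        z = a @ w + b
        if li < n_hidden:
            h = np.maximum(z, 0.0)
            p = dropout[li]
            if rng is not None and p > 0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h_out = h * mask
            else:
                mask = None
                h_out = h
            caches.append((a, z, mask))
            a = h_out
        else:
            caches.append((a, z, None))
            a = z
    return a, caches


def _backward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    caches,
    dropout: Sequence[float],
    grad_out: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights)  # type: ignore[list-item]
    delta = grad_out
    n_hidden = len(weights) - 1
    for li in range(len(weights) - 1, -1, -1):
        a_in, z, mask = caches[li]
        if li < n_hidden:
            if mask is not None:
                delta = delta * mask
            delta = delta * (z > 0)
        grads[li] = (a_in.T @ delta, delta.sum(axis=0))
        if li > 0:
            delta = delta @ weights[li][0].T
    return grads


@dataclass
class TrainedModel:
    """A trained network: config, weights, and per-epoch training losses."""

    config: MLPConfig
    weights: list[tuple[np.ndarray, np.ndarray]]
    training_log: list[float] = field(default_factory=list)
    validation_log: list[float] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference (dropout disabled)."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        if x.shape[1] != self.config.n_input:
            raise ValueError(
                f"expected input of length {self.config.n_input}, got {x.shape[1]}"
            )
        out, _ = _forward(self.weights, x, self.config.dropout, rng=None)
        return out[0] if squeeze else out


def train(
    config: MLPConfig,
    inputs: np.ndarray,
    targets: np.ndarray,
    seed: Optional[int] = None,
    validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> TrainedModel:
    """Full-batch Adam minimisation of the mean-squared-error loss.

    The loss averages over every output element (experiments x output
    dimension), which is the per-element MSE for both the direct (one output)
    and indirect (curve) cases.  Training is bit-reproducible for a given
    seed.  When ``validation`` is given, the validation loss is recorded
    after every epoch (dropout off), which ``cross_validate`` uses for epoch
    selection.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("inputs and targets must be 2-D matrices")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"row mismatch: {x.shape[0]} inputs vs {y.shape[0]} targets")
    if x.shape[1] != config.n_input:
        raise ValueError(f"expected {config.n_input} input columns, got {x.shape[1]}")
    if y.shape[1] != config.n_output:
        raise ValueError(f"expected {config.n_output} target columns, got {y.shape[1]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    weights = _init_weights(config, rng)
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]

    if validation is not None:
        x_val = np.asarray(validation[0], dtype=float)
        y_val = np.asarray(validation[1], dtype=float)
        if y_val.ndim == 1:
            y_val = y_val[:, None]

    model = TrainedModel(config=config, weights=weights)
    n_elems = y.size
    lr = config.learning_rate
    for t in range(1, config.epochs + 1):
        pred, caches = _forward(weights, x, config.dropout, rng=rng)
        resid = pred - y
        loss = float(np.mean(resid**2))
        grads = _backward(weights, caches, config.dropout, 2.0 * resid / n_elems)

        bc1 = 1.0 - ADAM_BETA1**t
        bc2 = 1.0 - ADAM_BETA2**t
        for li, ((w, b), (gw, gb)) in enumerate(zip(weights, grads)):
            mw, mb = m_state[li]
            vw, vb = v_state[li]
            mw = ADAM_BETA1 * mw + (1 - ADAM_BETA1) * gw
            mb = ADAM_BETA1 * mb + (1 - ADAM_BETA1) * gb
            vw = ADAM_BETA2 * vw + (1 - ADAM_BETA2) * gw**2
            vb = ADAM_BETA2 * vb + (1 - ADAM_BETA2) * gb**2
            m_state[li] = (mw, mb)
            v_state[li] = (vw, vb)
            w -= lr * (mw / bc1) / (np.sqrt(vw / bc2) + ADAM_EPS)
            b -= lr * (mb / bc1) / (np.sqrt(vb / bc2) + ADAM_EPS)

        model.training_log.append(loss)
        if validation is not None:
            val_pred, _ = _forward(weights, x_val, config.dropout, rng=None)
            model.validation_log.append(float(np.mean((val_pred - y_val) ** 2)))
    return model


def predict_direct(model: TrainedModel, window_input: np.ndarray) -> float:
    """One BOD5 mass estimate (mg) from a truncated window, clamped at 0."""
    if model.config.approach != "direct":
        raise ValueError("predict_direct requires a direct-approach model")
    out = model.predict(np.asarray(window_input, dtype=float))
    return max(0.0, float(out[0]))


def predict_continuation(model: TrainedModel, window_input: np.ndarray) -> np.ndarray:
    """Predicted voltage continuation (samples n_input .. 1510)."""
    if model.config.approach != "indirect":
        raise ValueError("predict_continuation requires an indirect-approach model")
    return np.asarray(model.predict(np.asarray(window_input, dtype=float)), dtype=float)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class FoldPlan:
    """K disjoint, equally sized, ordered blocks of experiment indices."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = [i for b in self.blocks for i in b]
        if len(set(flat)) != len(flat):
            raise ValueError("fold blocks must be disjoint")
        sizes = {len(b) for b in self.blocks}
        if len(sizes) != 1:
            raise ValueError("fold blocks must have equal sizes")

    @property
    def k(self) -> int:
        return len(self.blocks)


def plan_folds(n_experiments: int, k: int = 5) -> FoldPlan:
    """Partition ``n_experiments`` indices into ``k`` contiguous equal blocks."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_experiments % k != 0:
        raise ValueError(
            f"{n_experiments} experiments do not divide into {k} equal blocks"
        )
    size = n_experiments // k
    return FoldPlan(
        blocks=tuple(
            tuple(range(b * size, (b + 1) * size)) for b in range(k)
        )
    )


@dataclass
class CVResult:
    """Outcome of cross-validation for one candidate set."""

    selected: MLPConfig
    best_mean_loss: float
    fold_losses: dict[int, list[list[float]]]  # candidate idx -> per-fold val curves
    mean_curves: dict[int, np.ndarray]  # candidate idx -> mean val loss per epoch


def cross_validate(
    configs: Sequence[MLPConfig],
    inputs: np.ndarray,
    targets: np.ndarray,
    plan: FoldPlan,
    seed: int = 0,
    max_epochs: Optional[int] = None,
) -> CVResult:
    """K-fold block cross-validation with epoch selection.

    Each candidate is trained on K-1 blocks and evaluated on the held-out
    block, rotating through all K blocks.  For every epoch the K validation
    losses are averaged; the (config, epoch) pair minimising that mean is
    selected and returned as a config with ``epochs`` set accordingly.
    """
    if not configs:
        raise ValueError("no candidate configs")
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(targets, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if sorted(i for b in plan.blocks for i in b) != list(range(n)):
        raise ValueError("fold plan must cover exactly the training rows")

    ss = np.random.SeedSequence(seed)
    fold_losses: dict[int, list[list[float]]] = {}
    mean_curves: dict[int, np.ndarray] = {}
    best: tuple[float, int, int] | None = None  # (loss, candidate, epoch)
    for ci, config in enumerate(configs):
        epochs = max_epochs if max_epochs is not None else config.epochs
        run_cfg = replace(config, epochs=epochs)
        curves = []
        for fi, block in enumerate(plan.blocks):
            val_idx = np.asarray(block)
            train_idx = np.asarray(
                [i for b in plan.blocks for i in b if i not in set(block)]
            )
            fold_seed = np.random.SeedSequence(entropy=ss.entropy,
                                               spawn_key=(ci, fi)).generate_state(1)[0]
            model = train(
                run_cfg,
                x[train_idx],
                y[train_idx],
                seed=int(fold_seed),
                validation=(x[val_idx], y[val_idx]),
            )
            curves.append(model.validation_log)
        fold_losses[ci] = curves
        mean_curve = np.mean(np.asarray(curves), axis=0)
        mean_curves[ci] = mean_curve
        e_best = int(np.argmin(mean_curve))
        if best is None or mean_curve[e_best] < best[0]:
            best = (float(mean_curve[e_best]), ci, e_best + 1)

    assert best is not None
    loss, ci, epoch = best
    return CVResult(
        selected=replace(configs[ci], epochs=epoch),
        best_mean_loss=loss,
        fold_losses=fold_losses,
        mean_curves=mean_curves,
    )


# ---------------------------------------------------------------------------
# optional preprocessing


def minimax_normalize(x: np.ndarray, v_min: float, v_max: float) -> np.ndarray:
    """Min-max scale voltages with *explicitly supplied* expert bounds.

    The bounds must come from knowledge of the whole experiment, never be
    inferred from a truncated window (the window may not contain the peak).
    Off by default throughout the pipeline.
    """
    if v_max <= v_min:
        raise ValueError("v_max must exceed v_min")
    return (np.asarray(x, dtype=float) - v_min) / (v_max - v_min)


def minimax_denormalize(x: np.ndarray, v_min: float, v_max: float) -> np.ndarray:
    """Inverse of :func:`minimax_normalize`."""
    if v_max <= v_min:
        raise ValueError("v_max must exceed v_min")
    return np.asarray(x, dtype=float) * (v_max - v_min) + v_min
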