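"""Training loop, loss, and prediction-error metrics.

Training minimises the batch Euclidean norm of the prediction residual,
``loss = ||y_o - y_real||_2``, with Adam and a two-stage learning-rate
schedule: 1e-4 for the first 5 epochs (coarse localisation of a good
parameter region), then 1e-5 for the remaining epochs (refinement), 20
epochs in total. The returned parameters are those of the epoch with the
lowest validation loss. Per-epoch curves are recorded as root-mean-square
loss per window so they are comparable across batch sizes.

Metrics follow the normalised-signal convention: the respiration signal is
scaled to [-1, 1], so one normalised unit equals half the fitted
peak-to-peak range, and RMSE% / maximum-error% are percentages of that
unit. Millimetre-scale errors are recovered by de-normalising the residual
and back-projecting it along the primary motion axis onto the camera x/y/z
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SplitCorpus
from .model import ModelParams, backward_batch, forward_batch
from .pca import PrincipalFrame

__all__ = [
    "TrainConfig",
    "l2_loss",
    "train",
    "predict_batch",
    "rmse_pct",
    "max_error_pct",
    "per_axis_errors",
]


class DivergenceError(RuntimeError):
    """Non-finite loss encountered during training."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; defaults reproduce the clinical protocol."""

    epochs: int = 20
    lr_initial: float = 1e-4
    lr_after: float = 1e-5
    lr_switch_epoch: int = 5
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_initial <= 0 or self.lr_after <= 0:
            raise ValueError("learning rates must be positive")
        if self.lr_switch_epoch > self.epochs:
            raise ValueError("lr_switch_epoch must be <= epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index."""
        return self.lr_initial if epoch <= self.lr_switch_epoch else self.lr_after


def l2_loss(y_o: np.ndarray, y_real: np.ndarray) -> float:
    """Euclidean norm of the residual vector over the batch."""
    y_o = np.asarray(y_o, dtype=float)
    y_real = np.asarray(y_real, dtype=float)
    if y_o.shape != y_real.shape:
        raise ValueError(f"shape mismatch: {y_o.shape} vs {y_real.shape}")
    return float(np.linalg.norm(y_o - y_real))


def predict_batch(X: np.ndarray, params: ModelParams, chunk: int = 256) -> np.ndarray:
    """Forward pass over many windows, chunked to bound memory."""
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X))
    for a in range(0, len(X), chunk):
        out[a : a + chunk] = forward_batch(X[a : a + chunk], params)[0]
    return out


def _rms(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


def train(
    corpus: SplitCorpus, model: ModelParams, cfg: TrainConfig
) -> tuple[ModelParams, dict[str, list[float]]]:
    """Adam training against the batch-L2 loss with best-validation checkpointing.

    Returns the parameters of the epoch with minimum validation loss and the
    learning curves ``{"train": [...], "val": [...]}`` (RMS loss per window,
    one entry per epoch). Fully reproducible given ``cfg.seed``.
    """
    X_train, y_train = corpus.stacked("train")
    X_val, y_val = corpus.stacked("val")
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = model.copy()
    names = list(params.as_dict().keys())
    # Adam state kept on one flat vector; parameter fields become views into
    # it so in-place updates propagate without a per-parameter python loop.
    shapes = {k: v.shape for k, v in params.as_dict().items()}
    flat = np.concatenate([getattr(params, k).ravel() for k in names])
    pos = 0
    for k in names:
        size = int(np.prod(shapes[k])) if shapes[k] else 1
        setattr(params, k, flat[pos : pos + size].reshape(shapes[k]))
        pos += size
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    curves: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_params = params.copy()
    n = len(X_train)
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        sq_sum = 0.0
        for a in range(0, n, cfg.batch_size):
            idx = order[a : a + cfg.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            y_pred, cache = forward_batch(Xb, params, want_cache=True)
            e = y_pred - yb
            norm = float(np.linalg.norm(e))
            if not np.isfinite(norm):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            sq_sum += norm * norm
            # d||e||/dy = e / ||e||  (zero residual: zero subgradient)
            dy = e / norm if norm > 0 else np.zeros_like(e)
            grads = backward_batch(dy, cache, params)
            g = np.concatenate([grads[k].ravel() for k in names])
            step += 1
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**step)
            vhat = v / (1 - beta2**step)
            flat -= lr * mhat / (np.sqrt(vhat) + eps)
        curves["train"].append(float(np.sqrt(sq_sum / n)))
        val_res = predict_batch(X_val, params) - y_val
        val_loss = _rms(val_res)
        curves["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = params.copy()
    return best_params, curves


def rmse_pct(y_o: np.ndarray, y_real: np.ndarray) -> float:
    """Root-mean-square error as a percent of one normalised unit."""
    y_o = np.asarray(y_o, dtype=float)
    y_real = np.asarray(y_real, dtype=float)
    if y_o.size == 0:
        raise ValueError("empty input")
    return 100.0 * _rms(y_o - y_real)


def max_error_pct(y_o: np.ndarray, y_real: np.ndarray) -> float:
    """Largest absolute error as a percent of one normalised unit."""
    y_o = np.asarray(y_o, dtype=float)
    y_real = np.asarray(y_real, dtype=float)
    if y_o.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.max(np.abs(y_o - y_real)))


def per_axis_errors(
    y_o: np.ndarray,
    y_real: np.ndarray,
    frame: PrincipalFrame,
    norm_scale: float,
) -> tuple[np.ndarray, float]:
    """Millimetre-scale worst-case errors per camera axis and in 3-D.

    Normalised residuals are scaled back to mm along PC1 (one normalised
    unit = ``norm_scale`` mm) and decomposed onto the camera axes through
    the PC1 components. Per-axis maxima are taken independently; the
    Cartesian maximum is the largest Euclidean norm of the 3-vector
    residual (equal to the largest |residual| since PC1 is a unit vector).
    """
    if frame is None:
        raise ValueError("a fitted PrincipalFrame is required")
    residual_mm = (np.asarray(y_o, dtype=float) - np.asarray(y_real, dtype=float)) * norm_scale
    axis = frame.primary_axis
    per_axis = np.abs(residual_mm[:, None] * axis[None, :])  # (n, 3)
    per_axis_max = per_axis.max(axis=0)
    cartesian_max = float(np.max(np.linalg.norm(residual_mm[:, None] * axis[None, :], axis=1)))
    return per_axis_max, cartesian_max
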