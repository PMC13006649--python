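"""Multi-layer-perceptron recognition of the DO baseline from 60-point windows.

The recogniser maps a sliding window of the 60 most recent one-minute DO
readings to the baseline value at the window's final minute.  The network is a
fully connected ReLU MLP, 60 -> 1024 -> 512 -> 256 -> 128 -> 1, trained with
Adam on a mean-squared-error loss.  Inputs and labels are divided by 100 (the
fixed physical %-air-saturation scale) rather than per-dataset extremes, so a
deployed window is never rescaled by its own min/max — which would erase the
absolute level the model must recover.

MSE is reported on the raw %DO scale (loss is optimised on the /100 scale;
the conversion factor is exactly 100**2).
"""

from __future__ import annotations

import dataclasses
import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import WINDOW_LEN, SyntheticDataset, split_dataset

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "EvalMetrics",
    "TrainedBaselineModel",
    "TrainingDivergence",
    "build_model",
    "train",
    "predict_baseline",
    "evaluate",
    "save_model",
    "load_model",
    "BaselineRecognition",
    "BaselineRecognitionResults",
]

DO_SCALE = 100.0  # fixed physical normalisation, % air saturation


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = WINDOW_LEN
    hidden_sizes: tuple[int, ...] = (1024, 512, 256, 128)
    activation: str = "relu"
    output_size: int = 1

    def __post_init__(self) -> None:
        if self.output_size != 1:
            raise ValueError("output_size is fixed at 1 (a single baseline value)")
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if self.activation != "relu":
            raise ValueError("only the ReLU activation is supported")
        if self.input_size < 1:
            raise ValueError("input_size must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, self.output_size)


@dataclass(frozen=True)
class TrainingConfig:
    """Adam/MSE training schedule.

    The learning rate follows a cosine decay from ``learning_rate`` to
    ``min_learning_rate`` over ``epochs``; training stops early when the
    validation loss has not improved for ``patience`` epochs, and the
    best-validation parameters are restored.
    """

    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    min_learning_rate: float = 1e-5
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patience) <= 0:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class EvalMetrics:
    """R-squared and raw-scale MSE of baseline predictions.

    ``r2 = 1 - SS_res / SS_tot`` with ``SS_tot`` centred on the label mean.
    When the labels have zero variance R-squared is undefined; ``r2`` is then
    NaN and ``r2_defined`` is False (never a silent NaN from division).
    """

    r2: float
    mse: float
    n: int
    r2_defined: bool = True


@dataclass
class TrainedBaselineModel:
    """Weights, biases and normalisation of the baseline-recognition MLP."""

    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_scale: float = DO_SCALE
    y_scale: float = DO_SCALE
    training_meta: dict = field(default_factory=dict)

    def _forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        h = Xn
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < last:
                np.maximum(h, 0.0, out=h)
        return h[:, 0]

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Predict baselines (%DO) for an (n, 60) batch of DO windows."""
        windows = np.asarray(windows, dtype=np.float32)
        squeeze = windows.ndim == 1
        if squeeze:
            windows = windows[None, :]
        if windows.ndim != 2 or windows.shape[1] != self.config.input_size:
            raise ValueError(f"windows must have {self.config.input_size} values")
        if not np.isfinite(windows).all():
            raise ValueError("windows must be finite")
        out = self._forward_normalized(windows / self.x_scale) * self.y_scale
        return out[0] if squeeze else out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> TrainedBaselineModel:
    """Allocate an untrained model with seeded He-normal initialisation."""
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    sizes = config.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = math.sqrt(2.0 / fan_in)
        weights.append(
            rng.normal(0.0, scale, size=(fan_in, fan_out)).astype(np.float32)
        )
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return TrainedBaselineModel(config, weights, biases)


def train(
    model: TrainedBaselineModel,
    train_set: SyntheticDataset,
    cfg: TrainingConfig | None = None,
) -> TrainedBaselineModel:
    """Fit the MLP by mini-batch Adam on the MSE loss (in place; returns model).

    A ``val_fraction`` slice of ``train_set`` is held out for early stopping.
    Raises :class:`TrainingDivergence` if the loss goes non-finite.
    """
    cfg = cfg or TrainingConfig()
    if len(train_set) == 0:
        raise ValueError("train_set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    X = (train_set.X / model.x_scale).astype(np.float32)
    y = (train_set.y / model.y_scale).astype(np.float32)
    n = X.shape[0]
    n_val = int(n * cfg.val_fraction)
    if n_val > 0:
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, yv = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]
        n = X.shape[0]
    W, b = model.weights, model.biases
    L = len(W)
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mb = [np.zeros_like(x) for x in b]
    vb = [np.zeros_like(x) for x in b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = math.inf
    best = None
    bad_epochs = 0
    epochs_run = 0
    last_train_loss = math.nan

    def val_loss() -> float:
        if n_val == 0:
            return math.nan
        r = model._forward_normalized(Xv) - yv
        return float(np.mean(r * r))

    for epoch in range(cfg.epochs):
        # cosine decay over the configured epoch budget
        frac = epoch / max(cfg.epochs - 1, 1)
        lr = cfg.min_learning_rate + 0.5 * (
            cfg.learning_rate - cfg.min_learning_rate
        ) * (1 + math.cos(math.pi * frac))
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            # forward, keeping activations for backprop
            acts = [xb]
            h = xb
            for i in range(L):
                h = h @ W[i] + b[i]
                if i < L - 1:
                    np.maximum(h, 0.0, out=h)
                acts.append(h)
            resid = acts[-1][:, 0] - yb
            loss = float(np.mean(resid * resid))
            epoch_loss += loss * len(idx)
            if not math.isfinite(loss):
                raise TrainingDivergence(
                    f"loss became non-finite at epoch {epoch}, step {step}"
                )
            # backward
            grad = (2.0 / len(idx)) * resid[:, None]
            step += 1
            t_corr = math.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i in range(L - 1, -1, -1):
                gW = acts[i].T @ grad
                gb = grad.sum(axis=0)
                if i > 0:
                    grad = grad @ W[i].T
                    grad *= acts[i] > 0
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW * gW
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb * gb
                W[i] -= lr * t_corr * mW[i] / (np.sqrt(vW[i]) + eps)
                b[i] -= lr * t_corr * mb[i] / (np.sqrt(vb[i]) + eps)
        last_train_loss = epoch_loss / n
        epochs_run = epoch + 1
        if n_val > 0:
            vl = val_loss()
            if vl < best_val - 1e-12:
                best_val = vl
                best = ([w.copy() for w in W], [x.copy() for x in b])
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
    if best is not None:
        model.weights, model.biases = best
    model.training_meta = {
        "seed": cfg.seed,
        "epochs_run": epochs_run,
        "final_train_loss_normalized": last_train_loss,
        "best_val_loss_normalized": None if n_val == 0 else best_val,
        "n_train": int(n),
        "n_val": int(n_val),
    }
    return model


def predict_baseline(model: TrainedBaselineModel, window) -> float:
    """Baseline estimate (%DO) for a single 60-point window."""
    window = np.asarray(window, dtype=float)
    if window.shape != (model.config.input_size,):
        raise ValueError(f"window must have exactly {model.config.input_size} values")
    return float(model.predict(window))


def evaluate(model: TrainedBaselineModel, ds: SyntheticDataset) -> EvalMetrics:
    """Raw-scale MSE and centred R-squared of the model on a labelled dataset."""
    if len(ds) == 0:
        raise ValueError("dataset must be non-empty")
    pred = model.predict(ds.X)
    resid = ds.y - pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((ds.y - ds.y.mean()) ** 2))
    if ss_tot == 0.0:
        return EvalMetrics(r2=math.nan, mse=mse, n=len(ds), r2_defined=False)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return EvalMetrics(r2=r2, mse=mse, n=len(ds))


_FORMAT_VERSION = 1


def save_model(model: TrainedBaselineModel, path: str | Path) -> None:
    """Write a single-file checkpoint (weights + config + normalisation)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "x_scale": model.x_scale,
        "y_scale": model.y_scale,
        "training_meta": model.training_meta,
        "n_layers": len(model.weights),
    }
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, (w, bb) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = bb
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> TrainedBaselineModel:
    """Load a checkpoint written by :func:`save_model`; errors on corruption."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != _FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta.get('format_version')!r}"
                )
            cfg_d = meta["config"]
            config = ModelConfig(
                input_size=cfg_d["input_size"],
                hidden_sizes=tuple(cfg_d["hidden_sizes"]),
                activation=cfg_d["activation"],
                output_size=cfg_d["output_size"],
            )
            n_layers = meta["n_layers"]
            weights = [np.asarray(data[f"W{i}"]) for i in range(n_layers)]
            biases = [np.asarray(data[f"b{i}"]) for i in range(n_layers)]
    except (KeyError, OSError, ValueError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "checkpoint version" in str(exc):
            raise
        raise ValueError(f"not a valid model checkpoint: {path} ({exc})") from exc
    expected = config.layer_sizes
    for i, w in enumerate(weights):
        if w.shape != (expected[i], expected[i + 1]):
            raise ValueError("checkpoint weight shapes do not match its config")
    return TrainedBaselineModel(
        config,
        weights,
        biases,
        x_scale=meta["x_scale"],
        y_scale=meta["y_scale"],
        training_meta=meta.get("training_meta", {}),
    )


class BaselineRecognition:
    """Baseline-recognition model bound to a labelled window dataset.

    Statsmodels-style front end: construct from a :class:`SyntheticDataset`
    (split internally into train/test halves), then :meth:`fit` returns a
    :class:`BaselineRecognitionResults` carrying the trained network and its
    train/test metrics.
    """

    def __init__(
        self,
        dataset: SyntheticDataset,
        config: ModelConfig | None = None,
        split_ratio: float = 0.5,
        split_seed: int = 0,
    ) -> None:
        self.config = config or ModelConfig()
        self.train_set, self.test_set = split_dataset(dataset, split_ratio, split_seed)

    def fit(self, training: TrainingConfig | None = None) -> "BaselineRecognitionResults":
        training = training or TrainingConfig()
        model = build_model(self.config, seed=training.seed)
        train(model, self.train_set, training)
        return BaselineRecognitionResults(
            model,
            train_metrics=evaluate(model, self.train_set),
            test_metrics=evaluate(model, self.test_set),
            recognition=self,
        )


@dataclass
class BaselineRecognitionResults:
    model: TrainedBaselineModel
    train_metrics: EvalMetrics
    test_metrics: EvalMetrics
    recognition: "BaselineRecognition | None" = None

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.model.predict(windows)

    def save(self, path: str | Path) -> None:
        save_model(self.model, path)

    def plot_fit(self, ax=None):
        """Scatter predicted vs ground-truth baselines on the test half."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        te = self.recognition.test_set if self.recognition is not None else None
        if te is None:
            raise ValueError("results carry no bound dataset to plot")
        pred = self.model.predict(te.X)
        ax.scatter(te.y, pred, s=2, alpha=0.3)
        lim = [0, 100]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("true baseline (%DO)")
        ax.set_ylabel("predicted baseline (%DO)")
        ax.set_title(f"test R² = {self.test_metrics.r2:.4f}")
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        meta = self.model.training_meta
        lines = [
            "DO baseline recognition (ReLU MLP, Adam/MSE)",
            "=" * 46,
            f"architecture   {' -> '.join(map(str, cfg.layer_sizes))}",
            f"epochs run     {meta.get('epochs_run', '?')}",
            f"train windows  {meta.get('n_train', '?')} (+{meta.get('n_val', 0)} val)",
            f"train  R2 = {self.train_metrics.r2:.4f}   "
            f"MSE = {self.train_metrics.mse:.4f} (%DO)^2  n = {self.train_metrics.n}",
            f"test   R2 = {self.test_metrics.r2:.4f}   "
            f"MSE = {self.test_metrics.mse:.4f} (%DO)^2  n = {self.test_metrics.n}",
        ]
        return "\n".join(lines)
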