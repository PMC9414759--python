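"""Training and inference for the four peak-acceleration regressors.

Each model regresses the pre-impact window onto the trial's peak A_SVM (g).
Training follows the study conditions: batch size 1, ReLU hidden activations,
MAE or MSE loss, Adam (lr 1e-3), early stopping on a held-out validation
fraction of the training split with best-epoch restoration.  CNN variants run
up to 200 epochs with patience 100; LSTM variants up to 50 epochs with
patience 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocessing import ARCHITECTURES, FeatureWindow, assemble_inputs

LOSSES = ("mae", "mse")
_EPOCH_DEFAULTS = {"cnn1d": (200, 100), "cnn2d": (200, 100),
                   "lstm": (50, 10), "convlstm": (50, 10)}
_N_SIZES = {"cnn1d": 2, "cnn2d": 2, "lstm": 2, "convlstm": 4}

__all__ = ["ModelConfig", "TrainedRegressor", "build_model", "train",
           "predict", "save_model", "load_model", "LOSSES"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture identity plus the training hyperparameters."""

    architecture: str
    layer_sizes: tuple
    loss: str = "mae"
    max_epochs: int | None = None
    patience: int | None = None
    batch_size: int = 1
    seed: int = 0
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        need = _N_SIZES[self.architecture]
        if len(sizes) != need:
            raise ValueError(
                f"{self.architecture} takes {need} layer sizes, got {len(sizes)}: {sizes}")
        if any(s < 1 for s in sizes):
            raise ValueError(f"layer sizes must be positive, got {sizes}")
        loss = self.loss.lower()
        if loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        object.__setattr__(self, "loss", loss)
        ep, pat = _EPOCH_DEFAULTS[self.architecture]
        if self.max_epochs is None:
            object.__setattr__(self, "max_epochs", ep)
        if self.patience is None:
            object.__setattr__(self, "patience", pat)
        if self.max_epochs < 1 or self.patience < 0:
            raise ValueError("max_epochs must be >= 1 and patience >= 0")


@dataclass
class TrainedRegressor:
    config: ModelConfig
    network: nn.Network
    history: pd.DataFrame = field(repr=False)
    stopped_epoch: int = 0
    best_val_loss: float = float("nan")

    @property
    def n_params(self) -> int:
        return self.network.n_params()


def build_model(config: ModelConfig) -> nn.Network:
    """Instantiate an untrained, seeded network for the config."""
    rng = np.random.default_rng(config.seed)
    return nn.build_network(config.architecture, config.layer_sizes, rng)


def _sample_loss(pred, target: float, loss: str):
    err = pred - target
    return err.abs() if loss == "mae" else err.square()


def _batch_loss(network: nn.Network, X: np.ndarray, y: np.ndarray, loss: str) -> float:
    total = 0.0
    for i in range(len(y)):
        p = network.forward(X[i]).item()
        total += abs(p - y[i]) if loss == "mae" else (p - y[i]) ** 2
    return total / len(y)


def _stratified_val_split(categories, frac: float, rng: np.random.Generator):
    """Per-category validation indices; at least one validation sample."""
    categories = np.asarray(categories)
    val_idx = []
    for cat in np.unique(categories):
        idx = np.flatnonzero(categories == cat)
        rng.shuffle(idx)
        n_val = int(round(frac * len(idx)))
        val_idx.extend(idx[:n_val])
    if not val_idx:
        val_idx = [int(rng.integers(len(categories)))]
    val = np.sort(np.asarray(val_idx, dtype=int))
    train = np.setdiff1d(np.arange(len(categories)), val)
    if len(train) == 0:
        train, val = val[:1], val[1:] if len(val) > 1 else val
    return train, val


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
            p.grad = None


def train(model: nn.Network, train_windows, config: ModelConfig) -> TrainedRegressor:
    """Fit with batch size 1, Adam, and patience-based early stopping.

    A seeded, category-stratified validation slice of the training windows
    monitors the configured loss; the best-epoch parameters are restored.
    """
    windows = list(train_windows)
    if len(windows) < 10:
        raise ValueError(f"need at least 10 training windows, got {len(windows)}")
    X, y = assemble_inputs(windows, config.architecture)
    cats = [w.category for w in windows]

    rng = np.random.default_rng(config.seed)
    tr_idx, val_idx = _stratified_val_split(cats, config.val_fraction, rng)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    model.dropout_p = config.dropout
    opt = _Adam(model.params(), config.learning_rate)
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    best_val = np.inf
    best_state = model.get_state()
    wait = 0
    rows = []
    stopped = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(ytr))
        running = 0.0
        for i in order:
            pred = model.forward(Xtr[i], drop_rng=drop_rng)
            loss = _sample_loss(pred, ytr[i], config.loss)
            lval = loss.item()
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"({config.architecture}, sizes {config.layer_sizes})")
            loss.backward()
            opt.step()
            running += lval
        val_loss = _batch_loss(model, Xval, yval, config.loss)
        rows.append({"epoch": epoch, "train_loss": running / len(ytr),
                     "val_loss": val_loss})
        stopped = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    model.set_state(best_state)
    return TrainedRegressor(config=config, network=model,
                            history=pd.DataFrame(rows),
                            stopped_epoch=stopped, best_val_loss=float(best_val))


def predict(trained: TrainedRegressor, windows) -> np.ndarray:
    """Predicted peak accelerations (g), one per window, order preserved."""
    windows = list(windows)
    if not windows:
        return np.empty(0)
    X, _ = assemble_inputs(windows, trained.config.architecture)
    return np.array([trained.network.forward(X[i]).item() for i in range(len(windows))])


def save_model(trained: TrainedRegressor, path) -> None:
    """Checkpoint: npz of parameter arrays + JSON config sidecar + history CSV."""
    path = Path(path)
    arrays = {f"p{i}": arr for i, arr in enumerate(trained.network.get_state())}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = asdict(trained.config)
    meta.update(stopped_epoch=trained.stopped_epoch,
                best_val_loss=trained.best_val_loss,
                n_params=trained.n_params)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    trained.history.to_csv(path.with_suffix(".history.csv"), index=False)


def load_model(path) -> TrainedRegressor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(
        architecture=meta["architecture"], layer_sizes=tuple(meta["layer_sizes"]),
        loss=meta["loss"], max_epochs=meta["max_epochs"], patience=meta["patience"],
        seed=meta["seed"], learning_rate=meta["learning_rate"],
        val_fraction=meta["val_fraction"], dropout=meta["dropout"])
    network = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        state = [data[f"p{i}"] for i in range(len(data.files))]
    network.set_state(state)
    hist_path = path.with_suffix(".history.csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return TrainedRegressor(config=config, network=network, history=history,
                            stopped_epoch=int(meta["stopped_epoch"]),
                            best_val_loss=float(meta["best_val_loss"]))
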