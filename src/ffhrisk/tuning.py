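"""Exhaustive grid search over the layer-size candidates.

The CNN and LSTM architectures draw both layer sizes from {8, 16, 32, 64};
the Conv-LSTM draws its two convolution filter counts and two LSTM unit
counts from {16, 64}.  Every grid point trains with the same seed (hence the
same validation slice) and is scored by its best validation loss; ties go to
the configuration with fewer trainable parameters, then lexicographically
smaller layer sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .models import ModelConfig, build_model, train
from .preprocessing import ARCHITECTURES

_GRID_VALUES = {"cnn1d": (8, 16, 32, 64), "cnn2d": (8, 16, 32, 64),
                "lstm": (8, 16, 32, 64), "convlstm": (16, 64)}
_GRID_REPEAT = {"cnn1d": 2, "cnn2d": 2, "lstm": 2, "convlstm": 4}

__all__ = ["enumerate_grid", "grid_search", "GridResult"]


def enumerate_grid(architecture: str) -> list[tuple]:
    """All layer-size tuples for one architecture (16 per architecture)."""
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    return list(itertools.product(_GRID_VALUES[architecture],
                                  repeat=_GRID_REPEAT[architecture]))


@dataclass
class GridResult:
    architecture: str
    loss: str
    rows: pd.DataFrame
    best: ModelConfig

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _n_params(config: ModelConfig) -> int:
    return build_model(config).n_params()


def grid_search(architecture: str, loss: str, train_windows, seed: int = 0,
                evaluator=None, **config_overrides) -> GridResult:
    """Train every grid point and select the best validation error.

    `evaluator(config) -> (val_error, stopped_epoch)` may replace the actual
    training (used for selection-logic tests); per-point training failures are
    recorded in the result table rather than aborting the scan.
    `config_overrides` (e.g. max_epochs) apply to every grid point.
    """
    rows = []
    for sizes in enumerate_grid(architecture):
        config = ModelConfig(architecture=architecture, layer_sizes=sizes,
                             loss=loss, seed=seed, **config_overrides)
        n_params = _n_params(config)
        row = {"architecture": architecture, "loss": loss,
               **{f"size{i + 1}": s for i, s in enumerate(sizes)},
               "n_params": n_params, "val_error": float("nan"),
               "stopped_epoch": 0, "error": ""}
        try:
            if evaluator is not None:
                val_err, stopped = evaluator(config)
            else:
                fitted = train(build_model(config), train_windows, config)
                val_err, stopped = fitted.best_val_loss, fitted.stopped_epoch
            row["val_error"] = float(val_err)
            row["stopped_epoch"] = int(stopped)
        except Exception as exc:          # noqa: BLE001 - recorded per-row
            row["error"] = str(exc)
        rows.append((sizes, row))

    table = pd.DataFrame([r for _, r in rows])
    ok = [(sizes, r) for sizes, r in rows
          if r["error"] == "" and r["val_error"] == r["val_error"]]
    if not ok:
        raise RuntimeError(f"all {len(rows)} grid points failed for {architecture}/{loss}")
    best_sizes, _ = min(ok, key=lambda sr: (sr[1]["val_error"], sr[1]["n_params"], sr[0]))
    table["selected"] = [sizes == best_sizes for sizes, _ in rows]
    best = ModelConfig(architecture=architecture, layer_sizes=best_sizes,
                       loss=loss, seed=seed, **config_overrides)
    return GridResult(architecture=architecture, loss=loss, rows=table, best=best)
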