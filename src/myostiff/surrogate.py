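"""The MFNN inverse surrogate: scaling, training, prediction, metrics, CV.

The network maps the 114 input features (12 geometric, 2 fiber angles, 100
EDPVR volumes) to the two fiber material constants (a_f, b_f).  Inputs are
standardized (zero mean, unit variance, statistics from the training rows
only); targets are normalized by their per-column maximum absolute value.
Training minimizes the mean absolute error of the normalized targets with
Adam at learning rate 1e-4 and batch size 32; the weights with the lowest
validation loss over the epoch budget are kept ("best checkpoint"), which
realizes early stopping without halting.

Error metrics, all computed on the held-out targets in physical units unless
stated otherwise:

    MAE    = (1/n) sum_i sum_j |ybar - ybarhat|        (normalized units)
    NMAE_i = sum_j |y - yhat| / (n (max y_i - min y_i)) * 100%
    R2_i   = 1 - SS_res / SS_tot                        * 100%
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._mlp import MLP
from .dataset import Dataset, INPUT_NAMES, TARGET_NAMES

__all__ = [
    "SurrogateConfig",
    "InputScaler",
    "OutputScaler",
    "TrainedSurrogate",
    "Metrics",
    "fit_scalers",
    "train",
    "predict",
    "metrics",
    "cross_validate",
    "save_model",
    "load_model",
]

#: Floor applied to predicted material constants (the sampling lower bound).
PREDICTION_FLOOR = 0.01


@dataclass(frozen=True)
class SurrogateConfig:
    """Hyperparameters of the MFNN.

    Defaults follow the tuned final structure (two hidden layers of 1024
    units, 10,000 epochs); cross-validation scans conventionally use a
    reduced 2,000-epoch budget.
    """

    hidden_layers: int = 2
    units: int = 1024
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10_000
    cv_folds: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.hidden_layers <= 3:
            raise ValueError("hidden_layers must be 1..3")
        if not 16 <= self.units <= 1024:
            raise ValueError("units must be 16..1024")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass(frozen=True)
class InputScaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass(frozen=True)
class OutputScaler:
    max_abs: np.ndarray

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return Y / self.max_abs

    def inverse(self, Yn: np.ndarray) -> np.ndarray:
        return Yn * self.max_abs


def fit_scalers(X_train: np.ndarray, Y_train: np.ndarray) -> tuple[InputScaler, OutputScaler]:
    """Per-column standardizer for inputs, max-abs normalizer for targets.

    A zero-variance input column is flagged and its scale clamped to 1.
    """
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    zero = sd == 0
    if np.any(zero):
        cols = [INPUT_NAMES[i] if i < len(INPUT_NAMES) else str(i)
                for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance input column(s) {cols}; scale clamped to 1")
        sd = np.where(zero, 1.0, sd)
    max_abs = np.abs(Y_train).max(axis=0)
    if np.any(max_abs == 0):
        raise ValueError("degenerate target column (all zeros)")
    return InputScaler(mean, sd), OutputScaler(max_abs)


@dataclass
class TrainedSurrogate:
    mlp: MLP
    input_scaler: InputScaler
    output_scaler: OutputScaler
    config: SurrogateConfig
    history: pd.DataFrame            # per-epoch train/validation loss
    feature_names: tuple = tuple(INPUT_NAMES)
    best_epoch: int = -1

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _train_arrays(X_tr, Y_tr, X_val, Y_val, cfg: SurrogateConfig,
                  feature_names=tuple(INPUT_NAMES)) -> TrainedSurrogate:
    in_scaler, out_scaler = fit_scalers(X_tr, Y_tr)
    Xs = in_scaler.transform(X_tr).astype(np.float32)
    Ys = out_scaler.transform(Y_tr).astype(np.float32)
    Xv = in_scaler.transform(X_val).astype(np.float32)
    Yv = out_scaler.transform(Y_val).astype(np.float32)

    sizes = (X_tr.shape[1],) + (cfg.units,) * cfg.hidden_layers + (Y_tr.shape[1],)
    mlp = MLP(sizes, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)

    best_val = np.inf
    best_weights = mlp.get_weights()
    best_epoch = -1
    hist = np.empty((cfg.epochs, 2))
    for epoch in range(cfg.epochs):
        tr_loss = mlp.train_epoch(Xs, Ys, rng, lr=cfg.learning_rate,
                                  batch_size=cfg.batch_size)
        val_loss = mlp.mae(Xv, Yv)
        if not np.isfinite(tr_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        hist[epoch] = (tr_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = mlp.get_weights()
            best_epoch = epoch
    mlp.set_weights(best_weights)
    history = pd.DataFrame(hist, columns=["train_loss", "val_loss"])
    return TrainedSurrogate(mlp, in_scaler, out_scaler, cfg, history,
                            tuple(feature_names), best_epoch)


def train(ds: Dataset, cfg: SurrogateConfig | None = None) -> TrainedSurrogate:
    """Train on the dataset's training portion with a validation holdout.

    ``validation_fraction`` of the training rows (seeded draw) monitors the
    per-epoch loss for best-checkpoint selection; test rows are untouched.
    """
    cfg = cfg or SurrogateConfig()
    idx = ds.train_indices if ds.train_indices is not None else np.arange(len(ds))
    if len(idx) < 2:
        raise ValueError("training portion too small")
    X, Y = ds.subset_X(idx), ds.subset_Y(idx)
    rng = np.random.default_rng(cfg.seed + 2)
    perm = rng.permutation(len(idx))
    n_val = max(1, int(round(cfg.validation_fraction * len(idx))))
    val, tr = perm[:n_val], perm[n_val:]
    return _train_arrays(X[tr], Y[tr], X[val], Y[val], cfg)


def predict(model: TrainedSurrogate, inputs: np.ndarray) -> np.ndarray:
    """Predict (a_f, b_f) in physical units for one input vector or a batch."""
    X = np.asarray(inputs, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    Yn = model.mlp.forward(model.input_scaler.transform(X).astype(np.float32))
    Y = model.output_scaler.inverse(Yn.astype(float))
    if np.any(Y < PREDICTION_FLOOR):
        warnings.warn("prediction(s) clipped at the sampling floor 0.01")
        Y = np.maximum(Y, PREDICTION_FLOOR)
    return Y[0] if single else Y


@dataclass(frozen=True)
class Metrics:
    mae: float                 # normalized units, summed over targets
    nmae: Mapping[str, float]  # percent, per target
    r2: Mapping[str, float]    # percent, per target

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"NMAE_%": self.nmae, "R2_%": self.r2})


def metrics(actual: np.ndarray, predicted: np.ndarray,
            output_scaler: OutputScaler | None = None,
            target_names: Sequence[str] = TARGET_NAMES) -> Metrics:
    """MAE / NMAE / R^2 on paired target arrays (rows = cases).

    MAE uses normalized targets (via ``output_scaler`` when given, else
    max-abs of the actual values); NMAE and R^2 are scale-invariant per
    their definitions and are computed in physical units.
    """
    y = np.atleast_2d(np.asarray(actual, float))
    yhat = np.atleast_2d(np.asarray(predicted, float))
    if y.shape != yhat.shape:
        raise ValueError("actual and predicted must have the same shape")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two cases")
    scaler = output_scaler or OutputScaler(np.abs(y).max(axis=0))
    mae = float(np.abs(scaler.transform(y) - scaler.transform(yhat)).sum(axis=1).mean())
    nmae, r2 = {}, {}
    for i, name in enumerate(target_names):
        span = y[:, i].max() - y[:, i].min()
        if span == 0:
            raise ValueError(f"target {name} has zero range; NMAE undefined")
        nmae[name] = float(np.abs(y[:, i] - yhat[:, i]).sum() / (n * span) * 100.0)
        ss_res = float(np.sum((y[:, i] - yhat[:, i]) ** 2))
        ss_tot = float(np.sum((y[:, i] - y[:, i].mean()) ** 2))
        r2[name] = float((1.0 - ss_res / ss_tot) * 100.0)
    return Metrics(mae, nmae, r2)


def cross_validate(ds: Dataset, structures: Sequence[tuple[int, int]],
                   folds: int = 10, cfg: SurrogateConfig | None = None) -> pd.DataFrame:
    """K-fold scan over network structures (layers, units).

    Each fold holds out 1/folds of the training portion for validation and
    scoring; per-structure rows report fold-averaged MAE, NMAE and R^2.
    """
    cfg = cfg or SurrogateConfig(epochs=2000)
    idx = np.asarray(ds.train_indices if ds.train_indices is not None
                     else np.arange(len(ds)))
    rng = np.random.default_rng(cfg.seed + 3)
    perm = rng.permutation(len(idx))
    fold_ids = np.array_split(perm, folds)
    X, Y = ds.subset_X(idx), ds.subset_Y(idx)
    rows = []
    for layers, units in structures:
        scfg = replace(cfg, hidden_layers=layers, units=units)
        accum = []
        for f in range(folds):
            val = fold_ids[f]
            tr = np.concatenate([fold_ids[g] for g in range(folds) if g != f])
            model = _train_arrays(X[tr], Y[tr], X[val], Y[val], scfg)
            pred = predict(model, X[val])
            m = metrics(Y[val], pred, model.output_scaler)
            accum.append((m.mae, m.nmae[TARGET_NAMES[0]], m.nmae[TARGET_NAMES[1]],
                          m.r2[TARGET_NAMES[0]], m.r2[TARGET_NAMES[1]]))
        mean = np.mean(accum, axis=0)
        rows.append({"layers": layers, "units": units, "MAE": mean[0],
                     "NMAE_a_f_%": mean[1], "NMAE_b_f_%": mean[2],
                     "R2_a_f_%": mean[3], "R2_b_f_%": mean[4]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model persistence: npz weights + json manifest + csv history

def save_model(model: TrainedSurrogate, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (w, b) in enumerate(zip(model.mlp.W, model.mlp.b)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    arrays["input_mean"] = model.input_scaler.mean
    arrays["input_sd"] = model.input_scaler.sd
    arrays["output_max_abs"] = model.output_scaler.max_abs
    np.savez(d / "weights.npz", **arrays)
    manifest = {
        "layer_sizes": list(model.mlp.layer_sizes),
        "feature_names": list(model.feature_names),
        "best_epoch": model.best_epoch,
        "config": {k: getattr(model.config, k) for k in (
            "hidden_layers", "units", "learning_rate", "batch_size", "epochs",
            "cv_folds", "validation_fraction", "seed")},
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    model.history.to_csv(d / "history.csv", index=False)


def load_model(directory) -> TrainedSurrogate:
    from pathlib import Path

    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    data = np.load(d / "weights.npz")
    sizes = manifest["layer_sizes"]
    mlp = MLP(sizes, seed=0)
    mlp.W = [data[f"W{i}"] for i in range(len(sizes) - 1)]
    mlp.b = [data[f"b{i}"] for i in range(len(sizes) - 1)]
    cfg = SurrogateConfig(**manifest["config"])
    history = pd.read_csv(d / "history.csv")
    return TrainedSurrogate(
        mlp, InputScaler(data["input_mean"], data["input_sd"]),
        OutputScaler(data["output_max_abs"]), cfg, history,
        tuple(manifest["feature_names"]), manifest.get("best_epoch", -1))
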