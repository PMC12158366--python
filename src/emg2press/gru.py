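"""Compact GRU sequence-to-sequence regressor, implemented in NumPy.

Architecture: GRU(64 units, full sequence output) → ReLU → dropout(0.4,
training only) → per-timestep linear dense(4).  The GRU cell is the
gate-coupled ("reset-after") variant with separate input and recurrent
bias vectors, which is the convention whose trainable-parameter count is
3·(D·H + H² + 2·H) — 13,440 for a 4-dimensional RMS input and 64 units,
plus 260 for the dense head, 13,700 in total.  Training minimizes MSE
with Adam (default learning rate 5e-4) one sequence at a time (batch
size 1 preserves sequence integrity); MAE is tracked as the evaluation
metric.

Cell equations, with h' the previous hidden state:

    z  = σ(x Wz + bz  + h' Uz + cz)          (update gate)
    r  = σ(x Wr + br  + h' Ur + cr)          (reset gate)
    ĥ  = tanh(x Wh + bh + r ⊙ (h' Uh + ch))  (candidate state)
    h  = z ⊙ h' + (1 − z) ⊙ ĥ

Gradients are exact backpropagation through time; a finite-difference
oracle in the test suite checks them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .windows import WindowedDataset, channel_subset

__all__ = [
    "GRUConfig",
    "ParamCount",
    "Metrics",
    "TrainingResult",
    "GRUModel",
    "count_params",
    "build_model",
    "train",
    "evaluate",
    "predict",
    "compute_metrics",
    "sensor_ablation",
    "save_model",
    "load_model",
]


@dataclass
class GRUConfig:
    input_dim: int = 4
    units: int = 64
    dropout: float = 0.4
    output_dim: int = 4
    learning_rate: float = 0.0005
    epochs: int = 200
    batch_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_dim", "units", "output_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ParamCount:
    gru: int
    dense: int

    @property
    def total(self) -> int:
        return self.gru + self.dense


@dataclass
class Metrics:
    mse: float
    mae: float


@dataclass
class TrainingResult:
    loss_curve: np.ndarray           # per-epoch training MSE
    mae_curve: np.ndarray            # per-epoch training MAE
    final_train: Metrics
    final_val: Metrics | None
    best_epoch: int                  # epoch with lowest training loss (0-based)
    config: GRUConfig
    seed: int


def count_params(cfg: GRUConfig) -> ParamCount:
    """Trainable parameters of the GRU layer and dense head.

    The GRU term 3·(D·H + H² + 2·H) counts, per gate, the input kernel,
    recurrent kernel, and the two (input and recurrent) bias vectors of the
    reset-after formulation.
    """
    d, h, o = cfg.input_dim, cfg.units, cfg.output_dim
    return ParamCount(gru=3 * (d * h + h * h + 2 * h), dense=h * o + o)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRUModel:
    """Sequence-in/sequence-out GRU regressor with explicit parameters."""

    def __init__(self, cfg: GRUConfig):
        cfg.validate()
        self.cfg = cfg
        d, h, o = cfg.input_dim, cfg.units, cfg.output_dim
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {
            "Wx": _glorot(rng, d, 3 * h, (d, 3 * h)),
            "bx": np.zeros(3 * h),
            "Wh": np.concatenate([_orthogonal(rng, h) for _ in range(3)], axis=1),
            "bh": np.zeros(3 * h),
            "Wd": _glorot(rng, h, o, (h, o)),
            "bd": np.zeros(o),
        }
        self._dropout_rng = np.random.default_rng([cfg.seed, 0x5eed])

    # -- parameter bookkeeping ---------------------------------------------
    def n_params(self) -> ParamCount:
        """Parameter counts as actually allocated (matches count_params)."""
        gru = sum(self.params[k].size for k in ("Wx", "bx", "Wh", "bh"))
        dense = sum(self.params[k].size for k in ("Wd", "bd"))
        return ParamCount(gru=gru, dense=dense)

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.cfg.input_dim:
            raise ValueError(f"expected input of shape (T, {self.cfg.input_dim}), "
                             f"got {X.shape}")
        p, h_units = self.params, self.cfg.units
        t_len = X.shape[0]
        gx = X @ p["Wx"] + p["bx"]

        h = np.zeros(h_units)
        H_prev = np.empty((t_len, h_units))
        Z = np.empty((t_len, h_units))
        R = np.empty((t_len, h_units))
        HH = np.empty((t_len, h_units))
        GH_H = np.empty((t_len, h_units))
        H_seq = np.empty((t_len, h_units))
        Wh, bh = p["Wh"], p["bh"]
        for t in range(t_len):
            gh = h @ Wh + bh
            z = _sigmoid(gx[t, :h_units] + gh[:h_units])
            r = _sigmoid(gx[t, h_units:2 * h_units] + gh[h_units:2 * h_units])
            gh_h = gh[2 * h_units:]
            hh = np.tanh(gx[t, 2 * h_units:] + r * gh_h)
            H_prev[t], Z[t], R[t], HH[t], GH_H[t] = h, z, r, hh, gh_h
            h = z * h + (1.0 - z) * hh
            H_seq[t] = h

        A = np.maximum(H_seq, 0.0)
        if training and self.cfg.dropout > 0.0:
            keep = 1.0 - self.cfg.dropout
            mask = (self._dropout_rng.random(A.shape) < keep) / keep
        else:
            mask = None
        A_d = A if mask is None else A * mask
        Yhat = A_d @ p["Wd"] + p["bd"]
        cache = {"X": X, "H_prev": H_prev, "Z": Z, "R": R, "HH": HH,
                 "GH_H": GH_H, "H_seq": H_seq, "A_d": A_d, "mask": mask}
        return Yhat, cache

    def backward(self, cache: dict, dYhat: np.ndarray) -> dict[str, np.ndarray]:
        p, h_units = self.params, self.cfg.units
        X, H_seq = cache["X"], cache["H_seq"]
        t_len = X.shape[0]

        grads = {"Wd": cache["A_d"].T @ dYhat, "bd": dYhat.sum(axis=0)}
        dA = dYhat @ p["Wd"].T
        if cache["mask"] is not None:
            dA = dA * cache["mask"]
        dH = dA * (H_seq > 0.0)

        Z, R, HH, GH_H, H_prev = (cache[k] for k in ("Z", "R", "HH", "GH_H", "H_prev"))
        Wh = p["Wh"]
        dgx = np.empty((t_len, 3 * h_units))
        dgh = np.empty((t_len, 3 * h_units))
        dh_next = np.zeros(h_units)
        for t in range(t_len - 1, -1, -1):
            dh = dH[t] + dh_next
            z, r, hh, gh_h, h_prev = Z[t], R[t], HH[t], GH_H[t], H_prev[t]
            da_z = dh * (h_prev - hh) * z * (1.0 - z)
            da_h = dh * (1.0 - z) * (1.0 - hh * hh)
            da_r = da_h * gh_h * r * (1.0 - r)
            dgx[t, :h_units] = da_z
            dgx[t, h_units:2 * h_units] = da_r
            dgx[t, 2 * h_units:] = da_h
            dgh[t, :h_units] = da_z
            dgh[t, h_units:2 * h_units] = da_r
            dgh[t, 2 * h_units:] = da_h * r
            dh_next = dh * z + dgh[t] @ Wh.T

        grads["Wx"] = X.T @ dgx
        grads["bx"] = dgx.sum(axis=0)
        grads["Wh"] = H_prev.T @ dgh
        grads["bh"] = dgh.sum(axis=0)
        return grads


def build_model(cfg: GRUConfig | None = None) -> GRUModel:
    return GRUModel(cfg or GRUConfig())


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _as_list(ds) -> list[WindowedDataset]:
    return list(ds) if isinstance(ds, (list, tuple)) else [ds]


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """MSE and MAE averaged over all timesteps and output channels."""
    err = np.asarray(y_pred, dtype=float) - np.asarray(y_true, dtype=float)
    return Metrics(mse=float(np.mean(err * err)), mae=float(np.mean(np.abs(err))))


def train(model: GRUModel, train_ds, val_ds=None,
          cfg: GRUConfig | None = None) -> TrainingResult:
    """Fit with Adam on MSE, one sequence per optimizer step.

    Per-epoch curves are timestep-weighted averages of the per-sequence
    training losses (dropout active).  Final metrics are recomputed with
    dropout disabled.  A non-finite loss aborts with a diagnostic.
    """
    cfg = cfg or model.cfg
    train_list = _as_list(train_ds)
    if not train_list:
        raise ValueError("training set is empty")
    for ds in train_list:
        if ds.X.shape[1] != model.cfg.input_dim or ds.Y.shape[1] != model.cfg.output_dim:
            raise ValueError(f"dataset dims {ds.X.shape[1]}->{ds.Y.shape[1]} do not match "
                             f"model {model.cfg.input_dim}->{model.cfg.output_dim}")

    opt = _Adam(model.params, cfg.learning_rate)
    loss_curve = np.empty(cfg.epochs)
    mae_curve = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        sq_sum = abs_sum = 0.0
        n_elems = 0
        for ds in train_list:
            yhat, cache = model.forward(ds.X, training=True)
            err = yhat - ds.Y
            size = err.size
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; try a lower "
                    "learning rate or check the input data for outliers")
            grads = model.backward(cache, 2.0 * err / size)
            opt.step(model.params, grads)
            sq_sum += float(np.sum(err * err))
            abs_sum += float(np.sum(np.abs(err)))
            n_elems += size
        loss_curve[epoch] = sq_sum / n_elems
        mae_curve[epoch] = abs_sum / n_elems

    final_train = evaluate(model, train_list)
    final_val = evaluate(model, val_ds) if val_ds is not None else None
    return TrainingResult(loss_curve=loss_curve, mae_curve=mae_curve,
                          final_train=final_train, final_val=final_val,
                          best_epoch=int(np.argmin(loss_curve)),
                          config=cfg, seed=cfg.seed)


def evaluate(model: GRUModel, ds) -> Metrics:
    """Dropout-free metrics aggregated over all sequences, timesteps, channels."""
    sq_sum = abs_sum = 0.0
    n_elems = 0
    for d in _as_list(ds):
        yhat, _ = model.forward(d.X, training=False)
        err = yhat - d.Y
        sq_sum += float(np.sum(err * err))
        abs_sum += float(np.sum(np.abs(err)))
        n_elems += err.size
    return Metrics(mse=sq_sum / n_elems, mae=abs_sum / n_elems)


def predict(model: GRUModel, X: np.ndarray) -> np.ndarray:
    """Predicted pressure sequence, clipped to the normalized [0, 1] range."""
    yhat, _ = model.forward(X, training=False)
    return np.clip(yhat, 0.0, 1.0)


def save_model(model: GRUModel, path: str) -> None:
    """Portable weights file (NumPy archive) including the config."""
    import json
    cfg_json = json.dumps(model.cfg.__dict__)
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **model.params)


def load_model(path: str) -> GRUModel:
    import json
    with np.load(path) as data:
        cfg = GRUConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = GRUModel(cfg)
        for k in model.params:
            model.params[k] = data[k].astype(np.float64)
    return model


def sensor_ablation(train_ds, val_ds, subsets: Sequence[Sequence[str]],
                    cfg: GRUConfig | None = None) -> list[dict]:
    """Retrain per EMG-channel subset and report validation MAE.

    Each row carries the subset, its validation MAE, and the relative change
    versus the full four-channel baseline (trained here as well if not among
    the subsets).  Training errors are recorded per row without aborting the
    remaining subsets.
    """
    cfg = cfg or GRUConfig()
    train_list, val_list = _as_list(train_ds), _as_list(val_ds)
    full = train_list[0].feature_channels
    subsets = [tuple(s) for s in subsets]
    if not subsets:
        raise ValueError("no subsets given")
    if tuple(full) not in subsets:
        subsets = [tuple(full)] + subsets

    rows: list[dict] = []
    baseline_mae: float | None = None
    for subset in subsets:
        row: dict = {"subset": subset}
        try:
            sub_cfg = replace(cfg, input_dim=len(subset))
            sub_train = [channel_subset(d, subset) for d in train_list]
            sub_val = [channel_subset(d, subset) for d in val_list]
            result = train(GRUModel(sub_cfg), sub_train, sub_val, sub_cfg)
            row["mae"] = result.final_val.mae
            row["mse"] = result.final_val.mse
        except Exception as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        if subset == tuple(full):
            baseline_mae = row["mae"]
        rows.append(row)
    for row in rows:
        if "mae" in row and baseline_mae:
            row["rel_change_vs_baseline"] = row["mae"] / baseline_mae - 1.0
    return rows
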