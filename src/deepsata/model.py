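"""Model construction, training and checkpointing.

`DeepSATA` is built from encoded training/validation arrays plus a
:class:`ModelConfig`; `fit()` runs seeded SGD and returns a
:class:`FitResult` holding the best-validation-AUC weights, the per-epoch
history, and prediction/serialization methods.

The published architecture uses 320/480/960 convolution kernels with a
925-unit hidden layer and learning rate 1.0 (0.5 for the pig datasets);
those are the defaults here, with a `small()` preset sized for desk-scale
synthetic benchmarks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .nn import ACTIVATION_FLOOR, DeepSATANet, SGD, bce_loss_and_grad, thresholded_relu

logger = logging.getLogger(__name__)

#: learning rates used for the published species-scale models
LEARNING_RATE_PRESETS = {
    "mouse": 1.0, "chicken": 1.0, "human": 1.0, "cattle": 1.0, "pig": 0.5,
}


@dataclass
class ModelConfig:
    n_features: int
    n_tf_layers: int = 10
    mode: str = "3d"                      # "3d" (one-hot + TF planes) or "flat" (4+N channels)
    conv_filters: tuple[int, int, int] = (320, 480, 960)
    conv_widths: tuple[int, int, int] = (8, 8, 8)
    pool: int = 4
    dropout: tuple[float, float, float] = (0.2, 0.2, 0.5)
    hidden_units: int = 925
    learning_rate: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-6
    grad_clip: float | None = 1.0
    leak: float = 0.1
    activation_floor: float = ACTIVATION_FLOOR
    epochs: int = 20
    batch_size: int = 64
    patience: int = 5
    min_epochs: int = 0
    seed: int = 0
    per_plane_filters: bool = False

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.mode not in ("3d", "flat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.conv_filters) != 3 or any(f <= 0 for f in self.conv_filters):
            raise ValueError("conv_filters must be exactly three positive integers")
        if any(not (0 <= d < 1) for d in self.dropout):
            raise ValueError("dropout rates must be in [0, 1)")

    @property
    def planes(self) -> int:
        return 1 if self.mode == "flat" else self.n_tf_layers + 1

    @property
    def in_channels(self) -> int:
        return 4 + self.n_tf_layers if self.mode == "flat" else 4

    @classmethod
    def small(cls, n_features: int, n_tf_layers: int = 10, **kw) -> "ModelConfig":
        """A desk-scale configuration for synthetic benchmarks."""
        defaults = dict(
            conv_filters=(32, 48, 64), hidden_units=128,
            learning_rate=0.1, epochs=60, batch_size=16,
            dropout=(0.1, 0.1, 0.2), patience=8, min_epochs=45,
        )
        defaults.update(kw)
        return cls(n_features=n_features, n_tf_layers=n_tf_layers, **defaults)


def _to_net_layout(X: np.ndarray, mode: str) -> np.ndarray:
    """Encoded arrays -> network layout (B, planes, channels, window)."""
    if mode == "flat":
        if X.ndim != 3:
            raise ValueError(f"flat mode expects (n, window, 4+N), got {X.shape}")
        return np.ascontiguousarray(X.transpose(0, 2, 1))[:, None]
    if X.ndim != 4:
        raise ValueError(f"3d mode expects (n, window, 4, N+1), got {X.shape}")
    return np.ascontiguousarray(X.transpose(0, 3, 2, 1))


class DeepSATA:
    """The chromatin-accessibility model, built from encoded arrays.

    Parameters
    ----------
    train_X, train_y : encoded training windows and their binary labels.
        ``train_X`` is (n, window, 4, N+1) for the 3-D encoding (N may be 0,
        the one-hot baseline) or (n, window, 4+N) for the flat ablation.
    val_X, val_y : the validation split, used for early stopping and
        checkpoint selection by mean AUC.
    """

    def __init__(
        self,
        train_X: np.ndarray,
        train_y: np.ndarray,
        val_X: np.ndarray,
        val_y: np.ndarray,
        config: ModelConfig,
        feature_names: list[str] | None = None,
        tf_order: list[str] | None = None,
    ):
        if len(train_X) == 0 or len(val_X) == 0:
            raise ValueError("training and validation sets must be non-empty")
        if train_y.shape[1] != config.n_features:
            raise ValueError("train_y width does not match config.n_features")
        self.config = config
        self.train_X = _to_net_layout(np.asarray(train_X, dtype=np.float32), config.mode)
        self.val_X = _to_net_layout(np.asarray(val_X, dtype=np.float32), config.mode)
        self.train_y = np.asarray(train_y, dtype=np.float32)
        self.val_y = np.asarray(val_y, dtype=np.float32)
        self.feature_names = feature_names or [f"feature_{i}" for i in range(config.n_features)]
        self.tf_order = tf_order or []

    def fit(self, seed: int | None = None) -> "FitResult":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        net = DeepSATANet(
            planes=cfg.planes,
            n_features=cfg.n_features,
            in_channels=cfg.in_channels,
            conv_filters=cfg.conv_filters,
            conv_widths=cfg.conv_widths,
            pool=cfg.pool,
            dropout=cfg.dropout,
            hidden_units=cfg.hidden_units,
            seq_len=self.train_X.shape[3],
            activation_floor=cfg.activation_floor,
            seed=seed,
            per_plane=cfg.per_plane_filters,
            leak=cfg.leak,
        )
        # start the output at the per-feature base rates so the first epochs
        # are spent on signal rather than on learning the class priors
        prior = np.clip(self.train_y.mean(axis=0), 1e-3, 1 - 1e-3)
        net.bo[:] = np.log(prior / (1 - prior))
        opt = SGD(net, cfg.learning_rate, cfg.momentum, cfg.weight_decay, cfg.grad_clip)

        # features with a single class in training are excluded from the loss
        mask = np.ones(cfg.n_features, dtype=np.float32)
        for f in range(cfg.n_features):
            if len(np.unique(self.train_y[:, f])) < 2:
                mask[f] = 0.0
                warnings.warn(
                    f"feature {self.feature_names[f]!r} has a single class in "
                    "training and is excluded from the loss"
                )

        n = len(self.train_X)
        history: list[dict] = []
        best_auc, best_params, best_epoch = -np.inf, None, -1
        since_best = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                probs, cache = net.forward(self.train_X[idx], train=True, rng=rng)
                loss, dlogits = bce_loss_and_grad(probs, self.train_y[idx], mask)
                grads = net.backward(dlogits, cache)
                opt.step(grads)
                epoch_loss += loss
                n_batches += 1
            val_probs = _predict(net, self.val_X, cfg.batch_size)
            val_auc = _mean_auc(self.val_y, val_probs, mask)
            history.append(
                {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1), "val_auc": val_auc}
            )
            if val_auc > best_auc:
                best_auc, best_epoch, since_best = val_auc, epoch, 0
                best_params = {k: v.copy() for k, v in net.parameters().items()}
            else:
                since_best += 1
                # the optimizer typically spends the first epochs in a flat
                # region; don't stop before min_epochs
                if since_best >= cfg.patience and epoch + 1 >= cfg.min_epochs:
                    break
        if best_params is not None:
            net.set_parameters(best_params)
        return FitResult(
            net=net,
            config=cfg,
            feature_names=list(self.feature_names),
            tf_order=list(self.tf_order),
            history=pd.DataFrame(history),
            best_epoch=best_epoch,
            feature_mask=mask,
        )


def _predict(net: DeepSATANet, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
    outs = []
    for s in range(0, len(X), batch_size):
        probs, _ = net.forward(X[s : s + batch_size], train=False)
        outs.append(probs)
    return np.concatenate(outs) if outs else np.zeros((0, net.n_features))


def _mean_auc(y: np.ndarray, probs: np.ndarray, mask: np.ndarray | None = None) -> float:
    aucs = []
    for f in range(y.shape[1]):
        if mask is not None and mask[f] == 0:
            continue
        if len(np.unique(y[:, f])) < 2:
            continue
        aucs.append(roc_auc_score(y[:, f], probs[:, f]))
    return float(np.mean(aucs)) if aucs else float("nan")


@dataclass
class FitResult:
    """A trained model: best-validation weights plus training diagnostics."""

    net: DeepSATANet
    config: ModelConfig
    feature_names: list[str]
    tf_order: list[str]
    history: pd.DataFrame
    best_epoch: int
    feature_mask: np.ndarray

    def predict(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Per-feature accessibility probabilities, batch order preserved.

        ``X`` uses the encoder layout: (n, window, 4, N+1) in 3-D mode or
        (n, window, 4+N) in flat mode.
        """
        Xn = _to_net_layout(np.asarray(X, dtype=np.float32), self.config.mode)
        return _predict(self.net, Xn, batch_size)

    def weights_digest(self) -> str:
        return self.net.digest()

    @property
    def validation_auc(self) -> float:
        return float(self.history["val_auc"].iloc[self.best_epoch])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "DeepSATA fit summary",
            "====================",
            f"mode:               {cfg.mode} "
            f"({'one-hot baseline' if cfg.n_tf_layers == 0 else f'{cfg.n_tf_layers} TF layers'})",
            f"conv filters:       {cfg.conv_filters}, widths {cfg.conv_widths}",
            f"hidden units:       {cfg.hidden_units}",
            f"learning rate:      {cfg.learning_rate} (momentum {cfg.momentum})",
            f"epochs run:         {len(self.history)} (best epoch {self.best_epoch})",
            f"best val mean AUC:  {self.validation_auc:.4f}",
            f"features:           {', '.join(self.feature_names)}",
        ]
        if self.tf_order:
            lines.append(f"TF layer order:     {', '.join(self.tf_order)}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        meta = {
            "config": {**asdict(self.config)},
            "feature_names": self.feature_names,
            "tf_order": self.tf_order,
            "best_epoch": self.best_epoch,
            "history": self.history.to_dict(orient="list"),
            "feature_mask": self.feature_mask.tolist(),
        }
        arrays = {f"param::{k}": v for k, v in self.net.parameters().items()}
        np.savez(path, __meta__=np.array(json.dumps(meta), dtype="U"), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            cfg_d = meta["config"]
            for key in ("conv_filters", "conv_widths", "dropout"):
                cfg_d[key] = tuple(cfg_d[key])
            cfg = ModelConfig(**cfg_d)
            net = DeepSATANet(
                planes=cfg.planes,
                n_features=cfg.n_features,
                in_channels=cfg.in_channels,
                conv_filters=cfg.conv_filters,
                conv_widths=cfg.conv_widths,
                pool=cfg.pool,
                dropout=cfg.dropout,
                hidden_units=cfg.hidden_units,
                activation_floor=cfg.activation_floor,
                seed=cfg.seed,
                per_plane=cfg.per_plane_filters,
                leak=cfg.leak,
            )
            net.set_parameters(
                {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
            )
            return cls(
                net=net,
                config=cfg,
                feature_names=meta["feature_names"],
                tf_order=meta["tf_order"],
                history=pd.DataFrame(meta["history"]),
                best_epoch=meta["best_epoch"],
                feature_mask=np.array(meta["feature_mask"], dtype=np.float32),
            )
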