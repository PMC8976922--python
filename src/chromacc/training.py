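"""Supervised training with the study's optimization recipe.

Adam at learning rate 1e-3, divided by 10 every 30 epochs, cross-entropy
loss, 90 epochs at full scale (desk recipes use fewer).  Datasets are
split 90/10 with held-out object shape seeds and, when illumination
varies, held-out illuminant ids.  Inputs are scaled channel-wise by the
white point's cone excitations — a fixed unit convention applied to every
image, not an adaptive correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ConvClassifier, LinearReadout, ReadoutSpec, build_readout


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 90
    lr: float = 1e-3
    lr_decay_every: int = 30
    lr_decay_factor: float = 0.1
    batch_size: int = 128
    seed: int = 0
    n_instances: int = 3

    def __post_init__(self):
        if self.epochs <= 0 or self.lr <= 0:
            raise ValueError("epochs and lr must be positive")
        if self.lr_decay_every <= 0:
            raise ValueError("lr_decay_every must be positive")


def lr_for_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch index under the step schedule."""
    return cfg.lr * cfg.lr_decay_factor ** ((epoch - 1) // cfg.lr_decay_every)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    heldout_shape_seeds: frozenset = frozenset()
    heldout_illum_ids: frozenset = frozenset()


def split_dataset(
    manifest: pd.DataFrame,
    seed: int = 0,
    train_fraction: float = 0.9,
    holdout_illums: bool = False,
):
    """Split a trial manifest into train/validation parts.

    Validation rows use held-out object shape seeds exclusively; when
    ``holdout_illums`` is set (varying-illumination training) a matching
    fraction of illuminant ids is additionally reserved for validation.
    Returns ``(train_manifest, val_manifest, SplitSpec)``.
    """
    rng = np.random.default_rng(seed)
    if holdout_illums:
        illums = sorted(manifest["illum_id"].unique())
        n_held = max(1, int(round((1 - train_fraction) * len(illums))))
        if len(illums) - n_held < 1:
            raise ValueError("too few illuminants to hold any out")
        held = frozenset(rng.choice(illums, size=n_held, replace=False))
        val_rows = manifest["illum_id"].isin(held)
    else:
        held = frozenset()
        n_val = int(round((1 - train_fraction) * len(manifest)))
        if n_val < 1 or n_val >= len(manifest):
            raise ValueError("dataset too small to split")
        idx = rng.permutation(len(manifest))[:n_val]
        val_rows = np.zeros(len(manifest), dtype=bool)
        val_rows[idx] = True
        val_rows = pd.Series(val_rows, index=manifest.index)

    train = manifest[~val_rows]
    val = manifest[val_rows]
    overlap = set(train["object_shape_seed"]) & set(val["object_shape_seed"])
    if overlap:
        # shape seeds are drawn from 2^31 values, collisions are rare;
        # drop colliding validation rows to keep the pools disjoint
        val = val[~val["object_shape_seed"].isin(overlap)]
    spec = SplitSpec(
        train_fraction,
        frozenset(val["object_shape_seed"].tolist()),
        held,
    )
    return train.reset_index(drop=True), val.reset_index(drop=True), spec


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(arr) for k, _, _, arr in params}
        self.v = {k: np.zeros_like(arr) for k, _, _, arr in params}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for key, layer, name, arr in params:
            g = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            arr -= (
                self.lr
                * (self.m[key] / b1t)
                / (np.sqrt(self.v[key] / b2t) + self.eps)
            )


def softmax_xent(logits, y):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


# ---------------------------------------------------------------------------
# training loops


@dataclass
class TrainedInstance:
    model: object  # ConvClassifier or LinearReadout
    log: pd.DataFrame
    cfg: TrainConfig
    input_scale: np.ndarray | None = None

    def predict_logits(self, X, batch_size=256):
        out = []
        for k in range(0, len(X), batch_size):
            xb = X[k : k + batch_size]
            if self.input_scale is not None:
                xb = xb / self.input_scale
            out.append(self.model.forward(xb, train=False))
        return np.concatenate(out)

    @property
    def final_val_accuracy(self):
        return float(self.log["val_acc"].iloc[-1])

    @property
    def best_val_accuracy(self):
        return float(self.log["val_acc"].max())


def default_input_scale(ctx) -> np.ndarray:
    """Fixed per-channel unit: the white chip's cone excitations under D65."""
    from .colorimetry import project

    white_lms = project(ctx.d65 * ctx.white_reflectance, ctx.lms_sensors).values
    return white_lms.astype(np.float32)


def _accuracy(logits, y):
    return float(np.mean(np.argmax(logits, axis=1) == y))


def train_classifier(
    model: ConvClassifier,
    train_data,
    val_data,
    cfg: TrainConfig,
    input_scale: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedInstance:
    """Train a classifier; deterministic given seeds and thread contract.

    ``train_data``/``val_data`` are ``(X, y)`` with X as N x H x W x 3 cone
    images and integer labels.  Raises on divergence (non-finite loss).
    """
    X, y = train_data
    Xv, yv = val_data
    if input_scale is not None:
        X = X / input_scale
        Xv = Xv / input_scale
    X = X.astype(np.float32)
    Xv = Xv.astype(np.float32)
    rng = np.random.default_rng(cfg.seed + 1)
    model.dropout.rng = np.random.default_rng(cfg.seed + 2)
    opt = Adam(model.parameters(), lr=cfg.lr)
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_for_epoch(cfg, epoch)
        order = rng.permutation(len(X))
        losses, accs = [], []
        for k in range(0, len(X), cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = softmax_xent(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            model.backward(dlogits)
            opt.step(model.parameters(), model.gradients())
            losses.append(loss)
            accs.append(_accuracy(logits, y[idx]))
        val_logits = np.concatenate(
            [
                model.forward(Xv[k : k + 512], train=False)
                for k in range(0, len(Xv), 512)
            ]
        )
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.mean(losses)),
                "train_acc": float(np.mean(accs)),
                "val_acc": _accuracy(val_logits, yv),
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d} lr={opt.lr:.1e} "
                f"loss={rows[-1]['train_loss']:.3f} "
                f"train={rows[-1]['train_acc']:.3f} val={rows[-1]['val_acc']:.3f}"
            )
    return TrainedInstance(model, pd.DataFrame(rows), cfg, input_scale)


def train_readouts(
    backbone: TrainedInstance,
    taps: list[ReadoutSpec],
    train_data,
    val_data,
    cfg: TrainConfig,
) -> list[TrainedInstance]:
    """Train one frozen-backbone linear readout per tap.

    Uses the same data, loss and optimizer family as the backbone; the
    backbone's weights are never touched (checked bit-exactly).
    """
    X, y = train_data
    Xv, yv = val_data
    scale = backbone.input_scale
    if scale is not None:
        X = (X / scale).astype(np.float32)
        Xv = (Xv / scale).astype(np.float32)
    model: ConvClassifier = backbone.model
    before = model.state_dict()
    out = []
    for spec in taps:
        readout = build_readout(model, spec, seed=cfg.seed)
        feats = np.concatenate(
            [readout.features(X[k : k + 256]) for k in range(0, len(X), 256)]
        )
        featsv = np.concatenate(
            [readout.features(Xv[k : k + 256]) for k in range(0, len(Xv), 256)]
        )
        rng = np.random.default_rng(cfg.seed + 3)
        opt = Adam(readout.parameters(), lr=cfg.lr)
        rows = []
        for epoch in range(1, cfg.epochs + 1):
            opt.lr = lr_for_epoch(cfg, epoch)
            order = rng.permutation(len(feats))
            losses, accs = [], []
            for k in range(0, len(feats), cfg.batch_size):
                idx = order[k : k + cfg.batch_size]
                logits = readout.forward_features(feats[idx], train=True)
                loss, dlogits = softmax_xent(logits, y[idx])
                readout.backward(dlogits)
                opt.step(readout.parameters(), readout.gradients())
                losses.append(loss)
                accs.append(_accuracy(logits, y[idx]))
            vl = np.concatenate(
                [
                    readout.forward_features(featsv[k : k + 1024])
                    for k in range(0, len(featsv), 1024)
                ]
            )
            rows.append(
                {
                    "epoch": epoch,
                    "lr": opt.lr,
                    "train_loss": float(np.mean(losses)),
                    "train_acc": float(np.mean(accs)),
                    "val_acc": _accuracy(vl, yv),
                }
            )
        out.append(TrainedInstance(readout, pd.DataFrame(rows), cfg, scale))
    after = model.state_dict()
    for k in before:
        if not np.array_equal(before[k], after[k]):
            raise RuntimeError("frozen-backbone contract violated")
    return out
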