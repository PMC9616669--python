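"""Binary cross-entropy training of any network variant.

Optimization follows the protocol the architecture was designed around:
Adam with learning rate 1e-4 and weight decay 1e-4, batch size 16.  All
randomness (parameter init is the network's own; here: data order) is
seeded, validation loss and pixel AUC are logged per epoch, and the best
validation checkpoint is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import roc_auc
from .network import SFANet
from .nn import Adam
from .nn import functional as F
from .nn.tensor import Tensor
from .patches import PatchSet

log = logging.getLogger(__name__)

BCE_EPS = 1e-7   # probability clamp: the loss is undefined at p in {0, 1}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning rate and weight decay must be >= 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch size must be >= 1 and epochs >= 0")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_auc: list = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self):
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "val_auc": self.val_auc, "best_epoch": self.best_epoch}


def bce_loss(pred: Tensor, target, eps: float = BCE_EPS) -> Tensor:
    """Mean binary cross entropy -[y log p + (1-y) log(1-p)] over all pixels.

    Predictions are clamped to [eps, 1-eps]; the gradient is zero where the
    clamp is active.
    """
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    y = target.data if isinstance(target, Tensor) else np.asarray(target, dtype=np.float64)
    if y.shape != pred.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {y.shape}")
    p = F.clip(pred, eps, 1.0 - eps)
    one = Tensor(np.ones(1))
    term = F.add(F.mul(Tensor(y), F.log(p)),
                 F.mul(Tensor(1.0 - y), F.log(F.add(one, F.scale(p, -1.0)))))
    return F.mean(F.scale(term, -1.0))


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _validate(net: SFANet, val: PatchSet, batch_size: int):
    net.eval()
    losses, scores, labels = [], [], []
    for i in range(0, len(val), batch_size):
        xb = val.patches[i : i + batch_size]
        yb = val.labels[i : i + batch_size].astype(np.float64)
        pred = net(Tensor(xb))
        losses.append((float(bce_loss(pred, yb).data), len(xb)))
        scores.append(pred.data.ravel())
        labels.append(yb.ravel())
    net.train()
    total = sum(n for _, n in losses)
    loss = sum(v * n for v, n in losses) / total
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    if labels.min() == labels.max():      # degenerate validation set
        auc = float("nan")
    else:
        _, auc = roc_auc(scores, labels)
    return loss, auc


def train(net: SFANet, train_set: PatchSet, val_set: PatchSet,
          cfg: TrainConfig):
    """Optimize ``net`` in place; returns (net, TrainHistory).

    Keeps the parameters of the best-validation-loss epoch.  Aborts with a
    diagnostic if the loss goes non-finite.
    """
    if cfg.batch_size > len(train_set):
        raise ValueError("batch size exceeds the training set size")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state, best_val = None, np.inf
    net.train()
    for epoch in range(cfg.epochs):
        epoch_loss, n_seen = 0.0, 0
        for idx in _epoch_batches(len(train_set), cfg.batch_size, rng):
            xb = train_set.patches[idx]
            yb = train_set.labels[idx].astype(np.float64)
            pred = net(Tensor(xb))
            loss = bce_loss(pred, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(batch of {len(idx)}): {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        val_loss, val_auc = _validate(net, val_set, cfg.batch_size)
        history.train_loss.append(epoch_loss / n_seen)
        history.val_loss.append(val_loss)
        history.val_auc.append(val_auc)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
            history.best_epoch = epoch
        log.info("epoch %d: train loss %.4f, val loss %.4f, val AUC %.4f",
                 epoch + 1, history.train_loss[-1], val_loss, val_auc)
    if best_state is not None:
        net.load_state_dict(best_state)
    if cfg.checkpoint_path is not None:
        save_checkpoint(net, cfg.checkpoint_path, history=history, train_cfg=cfg)
    return net, history


def leave_one_out_splits(samples):
    """n folds over samples: fold i tests sample i, trains on the rest."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    return [(samples[:i] + samples[i + 1 :], samples[i])
            for i in range(len(samples))]


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(net: SFANet, path, history: TrainHistory | None = None,
                    train_cfg: TrainConfig | None = None):
    """One .npz file holding the architecture config, all parameter and
    buffer arrays, and training metadata."""
    import json

    meta = {"config": net.config.to_dict()}
    if history is not None:
        meta["history"] = history.to_dict()
    if train_cfg is not None:
        meta["train"] = {k: v for k, v in vars(train_cfg).items()}
    arrays = {"state/" + k: v for k, v in net.state_dict().items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SFANet, dict]:
    """Rebuild the network from a checkpoint; returns (net, metadata)."""
    import json

    from .network import NetworkConfig, build

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    net = build(NetworkConfig.from_dict(meta["config"]))
    net.load_state_dict(state)
    net.eval()
    return net, meta
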