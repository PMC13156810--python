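"""Shared training loop, schedule and checkpointing for both network stages.

The schedule mirrors the study's settings: SGD with Nesterov momentum 0.99,
initial learning rate 0.01 under polynomial decay with exponent 0.9 over
1000 epochs, a 1:1 binary cross-entropy : Dice loss, deep supervision, and
batch sizes of 12 (2D localization) and 4 (3D segmentation).  Epoch counts
and batch sizes are configurable so the same loop drives the desk-scale
profile.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import SGDNesterov, UNet, UNetSpec, clip_grad_norm, deep_supervision_loss, poly_lr

__all__ = ["TrainSchedule", "train_network", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainSchedule:
    """Optimization schedule for one network."""

    batch_size: int = 4
    total_epochs: int = 1000
    initial_lr: float = 0.01
    poly_exponent: float = 0.9
    momentum: float = 0.99
    w_bce: float = 1.0
    w_dice: float = 1.0
    deep_supervision: bool = True
    grad_clip: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.total_epochs < 0:
            raise ValueError("total_epochs must be >= 0")
        if self.w_bce < 0 or self.w_dice < 0 or self.w_bce + self.w_dice == 0:
            raise ValueError("loss weights must be positive")

    @classmethod
    def for_2d(cls, **kw) -> "TrainSchedule":
        kw.setdefault("batch_size", 12)
        return cls(**kw)

    @classmethod
    def for_3d(cls, **kw) -> "TrainSchedule":
        kw.setdefault("batch_size", 4)
        return cls(**kw)

    def lr_at(self, epoch: int) -> float:
        return poly_lr(epoch, self.total_epochs, self.initial_lr, self.poly_exponent)


def train_network(
    model: UNet,
    dataset,
    schedule: TrainSchedule,
    rng: np.random.Generator | None = None,
    epoch_data_fn=None,
) -> list[dict]:
    """Train ``model`` on a list of ``(input, target)`` array pairs.

    Items must share one shape (patch sampling upstream guarantees this).
    ``epoch_data_fn(epoch, rng)``, when given, regenerates the training list
    each epoch (fresh random patches).  Returns the per-epoch history
    (epoch, mean loss, learning rate).
    """
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    opt = SGDNesterov(model.layers(), momentum=schedule.momentum)
    ndim = model.spec.ndim
    history: list[dict] = []
    for epoch in range(schedule.total_epochs):
        data = epoch_data_fn(epoch, rng) if epoch_data_fn is not None else dataset
        if not data:
            raise ValueError("empty training dataset")
        lr = schedule.lr_at(epoch)
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(order), schedule.batch_size):
            idx = order[start : start + schedule.batch_size]
            x = np.stack([np.asarray(data[i][0], dtype=np.float32) for i in idx])[:, None]
            t = np.stack([np.asarray(data[i][1], dtype=np.float32) for i in idx])[:, None]
            logits = model.forward(x, train=True)
            if not schedule.deep_supervision:
                logits = logits[:1]
            loss, grads = deep_supervision_loss(logits, t, ndim, schedule.w_bce, schedule.w_dice)
            if len(grads) < len(model.heads):
                grads = grads + [None] * (len(model.heads) - len(grads))
            opt.zero_grad()
            model.backward(grads)
            clip_grad_norm(model.layers(), schedule.grad_clip)
            opt.step(lr)
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})
    return history


def save_checkpoint(path, model: UNet, extra: dict | None = None) -> None:
    """Persist network spec + weights (npz with a JSON sidecar entry)."""
    meta = {"spec": asdict(model.spec), "extra": extra or {}}
    arrays = model.state_dict()
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path) -> tuple[UNet, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        spec_d = dict(meta["spec"])
        spec_d["avgpool_stages"] = tuple(spec_d.get("avgpool_stages", ()))
        model = UNet(UNetSpec(**spec_d))
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model, meta["extra"]
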