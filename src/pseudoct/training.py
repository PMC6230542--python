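"""Optimisation loop and least-loss model selection.

Training minimises the mean squared error between the network output
and the normalised CT target in the Softsign domain, with Adam at a
fixed learning rate, a fixed mini-batch size, and seed-shuffled epoch
order.  A checkpoint is taken after every epoch and the one with the
least training loss is returned — ties broken toward the earlier epoch.
Everything is pure numpy, so two runs with the same seed are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pseudoct._seeding import rng_for
from pseudoct.nn import Adam, EncoderDecoder, checkpoint_bytes, network_from_bytes
from pseudoct.preprocess import SlicePair

__all__ = ["TrainConfig", "LossCurve", "train", "select_model",
           "iterations_per_epoch", "total_iterations"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe.

    Defaults mirror the full-scale configuration: Adam at a fixed
    learning rate of 0.001 with MSE computed over mini-batches of 12
    slices; 50 epochs correspond to 20,000 iterations when the training
    set holds 4,800 slices.
    """

    learning_rate: float = 0.001
    batch_size: int = 12
    n_epochs: int = 50
    loss: str = "mse"
    optimizer: str = "adam"
    seed: int = 0
    holdout_fraction: float = 0.0  # optional selection split; 0 = select on training loss

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("invalid training config")
        if self.loss != "mse" or self.optimizer != "adam":
            raise ValueError("only mse loss with adam is supported")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")


@dataclass
class LossCurve:
    """Per-epoch mean MSE (Softsign domain) and the selected epoch."""

    train_loss: list[float] = field(default_factory=list)
    holdout_loss: list[float] | None = None

    @property
    def selection_curve(self) -> list[float]:
        return self.holdout_loss if self.holdout_loss else self.train_loss

    @property
    def best_epoch(self) -> int:
        """1-based index of the least-loss epoch; ties → earliest."""
        curve = self.selection_curve
        return int(np.argmin(curve)) + 1

    def to_frame(self):
        import pandas as pd
        d = {"epoch": np.arange(1, len(self.train_loss) + 1),
             "train_loss": self.train_loss}
        if self.holdout_loss:
            d["holdout_loss"] = self.holdout_loss
        return pd.DataFrame(d)


def iterations_per_epoch(n_slices: int, batch_size: int) -> int:
    """Number of optimiser updates per epoch (last partial batch included)."""
    return math.ceil(n_slices / batch_size)


def total_iterations(n_slices: int, batch_size: int, n_epochs: int) -> int:
    return iterations_per_epoch(n_slices, batch_size) * n_epochs


def _stack(pairs: list[SlicePair], dtype=np.float32,
           target_shape: tuple[int, int] | None = None
           ) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_slice for p in pairs])[:, None].astype(dtype)
    t = np.stack([p.target_slice for p in pairs])[:, None].astype(dtype)
    if target_shape is not None and x.shape[2:] != tuple(target_shape):
        # pad with the normalised-air constant (0 in the Softsign domain)
        hp, wp = target_shape
        h, w = x.shape[2:]
        if h > hp or w > wp:
            raise ValueError(f"slices {h}x{w} exceed network input {hp}x{wp}")
        xp = np.zeros((x.shape[0], 1, hp, wp), dtype=dtype)
        tp = np.zeros_like(xp)
        xp[..., :h, :w] = x
        tp[..., :h, :w] = t
        x, t = xp, tp
    return x, t


def _mean_loss(net: EncoderDecoder, x: np.ndarray, t: np.ndarray,
               batch_size: int) -> float:
    total = 0.0
    for i in range(0, x.shape[0], batch_size):
        xb, tb = x[i:i + batch_size], t[i:i + batch_size]
        y = net.forward(xb, train=False)
        total += float(((y - tb) ** 2).sum())
    return total / x.size


def train(net: EncoderDecoder, dataset: list[SlicePair], cfg: TrainConfig
          ) -> tuple[EncoderDecoder, LossCurve]:
    """Train and return the network at the least-loss epoch.

    The running loss accumulated over an epoch's mini-batches is the
    selection signal by default; with ``holdout_fraction > 0`` a fixed
    seed-determined split is evaluated after every epoch and used for
    selection instead.

    Raises on a non-finite loss, naming the offending batch.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = rng_for(cfg.seed, "epoch-shuffle")

    idx = rng.permutation(len(dataset))
    n_hold = int(round(cfg.holdout_fraction * len(dataset)))
    hold = [dataset[i] for i in idx[:n_hold]]
    work = [dataset[i] for i in idx[n_hold:]]
    if not work:
        raise ValueError("holdout_fraction leaves no training data")
    x_all, t_all = _stack(work, net.dtype, net.input_shape)
    x_hold, t_hold = (_stack(hold, net.dtype, net.input_shape)
                      if hold else (None, None))

    opt = Adam(net, lr=cfg.learning_rate)
    curve = LossCurve(holdout_loss=[] if hold else None)
    checkpoints: list[bytes] = []

    n = x_all.shape[0]
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for b, i in enumerate(range(0, n, cfg.batch_size)):
            sel = order[i:i + cfg.batch_size]
            xb, tb = x_all[sel], t_all[sel]
            net.zero_grad()
            y = net.forward(xb, train=True)
            diff = y - tb
            loss = float((diff ** 2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch {b}")
            net.backward(2.0 * diff / diff.size)
            opt.step()
            sq_sum += float((diff ** 2).sum())
        curve.train_loss.append(sq_sum / x_all.size)
        if hold:
            curve.holdout_loss.append(_mean_loss(net, x_hold, t_hold, cfg.batch_size))
        checkpoints.append(checkpoint_bytes(net))

    return select_model(curve, checkpoints), curve


def select_model(curve: LossCurve, checkpoints: list[bytes]) -> EncoderDecoder:
    """Restore the checkpoint at the least-loss epoch (ties → earliest)."""
    if not checkpoints:
        raise ValueError("no checkpoints available")
    best = curve.best_epoch
    if best > len(checkpoints):
        raise ValueError(f"checkpoint for epoch {best} missing")
    return network_from_bytes(checkpoints[best - 1])
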