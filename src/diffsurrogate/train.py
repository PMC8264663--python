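"""Minibatch ADAM training with roll-back on loss jumps and best-checkpoint
retention.

Stochastic training of the surrogate occasionally takes an unfavorable step
that raises the epoch loss by one or two orders of magnitude and resets the
downward trend ("jump"). The roll-back rule guards against this: after a
warm-up of ``m`` epochs, an epoch whose training loss exceeds ``C`` times
the mean loss of the previous ``m`` accepted epochs is rejected, and the
model and optimizer are restored to their snapshot from ``s`` epochs
earlier before training continues (with freshly advanced shuffle/dropout
streams, so the retry does not deterministically reproduce the jump).
Reference values: C = 5, m = 20, s = 5, 800 epochs.

Independently of roll-back, the returned model is the checkpoint with the
lowest recorded epoch loss, regardless of when it was achieved.

The roll-back/checkpoint engine (`train_loop`) is separated from the
network-specific epoch step so it can be exercised with scripted loss
sequences.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .loss import LossConfig, weighted_loss_grad
from .model import SurrogateModel
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainState",
    "LogRow",
    "rollback_threshold",
    "should_rollback",
    "train_loop",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 800
    lr: float = 1e-3
    batch_size: int = 32
    loss: LossConfig = field(default_factory=LossConfig)
    rollback_C: float = 5.0  # jump threshold multiple; math.inf disables roll-back
    rollback_m: int = 20  # trailing-mean window and warm-up length
    rollback_s: int = 5  # how many epochs to revert on a jump
    max_rollbacks: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.rollback_m < 1 or self.rollback_s < 1:
            raise ValueError("epochs, rollback_m and rollback_s must be >= 1")
        if self.max_rollbacks < 0:
            raise ValueError("max_rollbacks must be >= 0")
        if not (self.rollback_C > 0):
            raise ValueError("rollback_C must be positive")


@dataclass
class LogRow:
    epoch: int
    loss: float
    rolled_back: bool
    rollback_count: int


@dataclass
class TrainState:
    """Outcome of a training run.

    ``loss_history`` holds the accepted per-epoch training losses (rejected
    jump epochs appear only in ``log``). ``best_epoch``/``best_loss`` always
    point at the minimum of the history; ``best_state`` is its snapshot.
    """

    loss_history: list[float] = field(default_factory=list)
    log: list[LogRow] = field(default_factory=list)
    rollback_count: int = 0
    best_epoch: int = -1
    best_loss: float = math.inf
    best_state: Any = None


def rollback_threshold(loss_history: Sequence[float], C: float, m: int) -> float:
    """C times the mean loss of the last min(m, available) epochs."""
    if len(loss_history) == 0:
        raise ValueError("loss history is empty")
    window = loss_history[-m:]
    return C * float(np.mean(window))


def should_rollback(
    candidate_loss: float, loss_history: Sequence[float], cfg: TrainConfig
) -> bool:
    """True iff the candidate epoch loss exceeds the jump threshold.

    No roll-back during the first ``m`` epochs (warm-up): the trailing mean
    is not yet representative.
    """
    if len(loss_history) < cfg.rollback_m:
        return False
    if math.isinf(cfg.rollback_C):
        return False
    return candidate_loss > rollback_threshold(
        loss_history, cfg.rollback_C, cfg.rollback_m
    )


def train_loop(
    run_epoch: Callable[[int], float],
    snapshot: Callable[[], Any],
    restore: Callable[[Any], None],
    cfg: TrainConfig,
) -> TrainState:
    """Drive epochs with roll-back and best-checkpoint bookkeeping.

    ``run_epoch(epoch)`` performs one optimization epoch and returns its
    training loss; ``snapshot()`` captures the full trainable state (model
    parameters, batch-norm buffers, optimizer moments) and ``restore``
    reinstates such a capture bit-for-bit. Every call to ``run_epoch``
    consumes one unit of the fixed epoch budget, whether or not the epoch is
    later rejected, so roll-backs do not extend training.
    """
    state = TrainState()
    # ring of the last s+1 accepted snapshots: index 0 is the epoch-(n-s) state
    ring: deque[tuple[int, Any]] = deque(maxlen=cfg.rollback_s + 1)
    ring.append((0, snapshot()))

    for epoch in range(1, cfg.epochs + 1):
        loss = run_epoch(epoch)
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss}")
        if should_rollback(loss, state.loss_history, cfg):
            state.rollback_count += 1
            if state.rollback_count > cfg.max_rollbacks:
                raise RuntimeError(
                    f"exceeded max_rollbacks={cfg.max_rollbacks} at epoch {epoch}"
                )
            back_epoch, snap = ring[0]
            restore(snap)
            ring.clear()
            ring.append((back_epoch, snap))
            state.log.append(LogRow(epoch, loss, True, state.rollback_count))
            continue
        state.loss_history.append(loss)
        snap = snapshot()
        ring.append((epoch, snap))
        if loss < state.best_loss:
            state.best_loss = loss
            state.best_epoch = epoch
            state.best_state = snap
        state.log.append(LogRow(epoch, loss, False, state.rollback_count))
    return state


def train(
    model: SurrogateModel,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    cfg: TrainConfig,
    progress: bool = False,
    epoch_callback: Callable[[int, float], None] | None = None,
) -> TrainState:
    """Train the surrogate on (n, L, L) paired arrays; returns the run record.

    On return the model carries the best checkpoint's parameters. The seed
    expands into independent shuffle and dropout streams; both advance
    monotonically across roll-backs.
    """
    n = len(train_inputs)
    if n == 0:
        raise ValueError("training set is empty")
    x = np.asarray(train_inputs, dtype=np.float64)[:, None]
    y = np.asarray(train_targets, dtype=np.float64)[:, None]
    opt = Adam(model.parameters(), lr=cfg.lr)
    shuffle_rng, dropout_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    ]

    def snapshot():
        return (
            {k: v.copy() for k, v in model.state_dict().items()},
            opt.state_dict(),
        )

    def restore(snap) -> None:
        model_state, opt_state = snap
        model.load_state_dict(model_state)
        opt.load_state_dict(opt_state)

    epoch_iter = [None]  # placeholder for tqdm handle

    def run_epoch(epoch: int) -> float:
        perm = shuffle_rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(x[idx], training=True, rng=dropout_rng)
            loss, grad = weighted_loss_grad(pred, y[idx], cfg.loss)
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        epoch_loss = total / seen
        if epoch_callback is not None:
            epoch_callback(epoch, epoch_loss)
        if epoch_iter[0] is not None:
            epoch_iter[0].update(1)
            epoch_iter[0].set_postfix(loss=f"{epoch_loss:.3e}")
        return epoch_loss

    if progress:
        from tqdm import tqdm

        epoch_iter[0] = tqdm(total=cfg.epochs, desc="training", unit="epoch")
    try:
        state = train_loop(run_epoch, snapshot, restore, cfg)
    finally:
        if epoch_iter[0] is not None:
            epoch_iter[0].close()
    restore(state.best_state)
    return state
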