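"""Poisson-loss training: optimizer schedule, clipping, augmentation,
alternating-organism batching, and best-checkpoint selection.

The loss is the Poisson negative log-likelihood mean(lambda - y*log(lambda));
the data-dependent log(y!) term is dropped, so absolute loss values are
comparable only within this implementation.  The learning rate ramps linearly
from zero over the warm-up steps and is constant afterwards; gradients are
clipped to a maximum global norm before each update.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .autodiff import Tensor, no_grad
from .model import SeqToTracksModel
from .sequence_io import BinnedTracks, OneHotSequence, reverse_complement, shift_sequence


@dataclass
class OptimizerSchedule:
    target_lr: float = 5e-4
    warmup_steps: int = 5000
    clip_norm: float = 0.2
    total_steps: int = 150_000
    fine_tune_lr: float = 1e-4
    eval_every: int = 1000
    lr_decay: str = "none"  # "none" (constant after warm-up) or "cosine"

    def __post_init__(self):
        if min(self.target_lr, self.clip_norm, self.fine_tune_lr) <= 0 or self.total_steps <= 0:
            raise ValueError("schedule values must be positive")
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must not exceed total_steps")


@dataclass
class AugmentationConfig:
    max_shift: int = 3
    reverse_complement: bool = True
    enabled: bool = True


@dataclass
class TrainState:
    step: int = 0
    best_metric: float = -np.inf
    best_step: int = -1
    best_state: Optional[dict] = None
    log: list = field(default_factory=list)  # (step, loss, lr, val_metric or nan)
    optimizer: Optional["Adam"] = None  # carried so training can be resumed seamlessly


def poisson_nll(pred, target) -> Tensor:
    """mean(lambda - y log lambda) over all entries; log(y!) dropped."""
    lam = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=float))
    y = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=lam.dtype)
    if lam.data.shape != y.shape:
        raise ValueError(f"shape mismatch: {lam.data.shape} vs {y.shape}")
    if not np.all(np.isfinite(lam.data)):
        raise FloatingPointError("non-finite Poisson rates (training diverged?)")
    if np.any(lam.data <= 0):
        raise ValueError("Poisson rates must be strictly positive")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return (lam - Tensor(y) * lam.log()).mean()


def lr_at_step(step: int, schedule: OptimizerSchedule) -> float:
    """Linear warm-up from 0 to target over warmup_steps, then constant
    (or cosine-decayed to 10% of target when ``lr_decay == "cosine"``)."""
    if schedule.warmup_steps > 0 and step < schedule.warmup_steps:
        return schedule.target_lr * step / schedule.warmup_steps
    if schedule.lr_decay == "cosine" and schedule.total_steps > schedule.warmup_steps:
        frac = (step - schedule.warmup_steps) / (schedule.total_steps - schedule.warmup_steps)
        return schedule.target_lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0))))
    return schedule.target_lr


def clip_global_norm(grads: list[np.ndarray], bound: float) -> tuple[list[np.ndarray], float]:
    """Scale all gradients by a common factor so the global norm <= bound."""
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads)))
    if total <= bound or total == 0.0:
        return grads, total
    scale = bound / total
    return [g * scale for g in grads], total


def alternate_batches(streams: dict[str, Iterable]):
    """Cycle organisms in fixed order, one batch each; streams restart on exhaustion."""
    iters = {org: itertools.cycle(stream) for org, stream in streams.items()}
    for org in itertools.cycle(sorted(iters)):
        yield org, next(iters[org])


class Adam:
    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data = p.data - lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def augment_batch(x: np.ndarray, y: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator):
    """Random small shift and orientation flip applied jointly to (x, y)."""
    if not cfg.enabled:
        return x, y
    xs, ys = [], []
    for xi, yi in zip(x, y):
        k = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
        seq = shift_sequence(OneHotSequence(xi), k, cfg.max_shift)
        tracks = BinnedTracks(yi.T)
        if cfg.reverse_complement and rng.random() < 0.5:
            seq, tracks = reverse_complement(seq, tracks)
        xs.append(seq.matrix)
        ys.append(tracks.values.T)
    return np.stack(xs), np.stack(ys)


def train(
    model: SeqToTracksModel,
    datasets: dict[str, Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]],
    schedule: OptimizerSchedule,
    augmentation: AugmentationConfig = None,
    seed: int = 0,
    eval_fn: Optional[Callable[[SeqToTracksModel], float]] = None,
    trainable: Optional[list] = None,
    lr_override: Optional[float] = None,
    log_every: int = 50,
    verbose: bool = False,
    optimizer: Optional[Adam] = None,
) -> TrainState:
    """Run the training loop.

    ``datasets`` maps organism name to a sampler ``rng -> (x, y)`` with x of
    shape (B, L, 4) and y of shape (B, bins, tracks).  Batches alternate
    between organisms in fixed order.  Every ``schedule.eval_every`` steps
    ``eval_fn`` is evaluated and the best-scoring parameter set is retained.
    """
    augmentation = augmentation or AugmentationConfig()
    rng = np.random.default_rng(seed)
    params = trainable if trainable is not None else model.parameters()
    opt = optimizer if optimizer is not None else Adam(params)
    state = TrainState()
    state.optimizer = opt
    samplers = {org: datasets[org] for org in sorted(datasets)}
    org_cycle = itertools.cycle(sorted(samplers))

    for step in range(schedule.total_steps):
        org = next(org_cycle)
        x, y = samplers[org](rng)
        x, y = augment_batch(x, y, augmentation, rng)
        model.train()
        pred = model(Tensor(x.astype(model.cfg.dtype)), org)
        loss = poisson_nll(pred, y.astype(model.cfg.dtype))
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training diverged at step {step}: loss={loss.data}")
        model.zero_grad()
        loss.backward()
        loss_value = float(loss.data)
        del pred, loss  # free the tape before the optimizer allocates
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in params]
        grads, _ = clip_global_norm(grads, schedule.clip_norm)
        lr = lr_override if lr_override is not None else lr_at_step(step, schedule)
        opt.step(grads, lr)
        state.step = step + 1

        val = np.nan
        if eval_fn is not None and (step + 1) % schedule.eval_every == 0:
            model.eval()
            val = float(eval_fn(model))
            if val > state.best_metric:
                state.best_metric = val
                state.best_step = step + 1
                state.best_state = model.state_dict()
        if (step + 1) % log_every == 0 or not np.isnan(val):
            state.log.append((step + 1, loss_value, lr, val))
            if verbose:
                print(f"step {step + 1} loss {loss_value:.4f} lr {lr:.2e} val {val}", flush=True)

    if eval_fn is not None and state.best_state is None:
        model.eval()
        state.best_metric = float(eval_fn(model))
        state.best_step = state.step
        state.best_state = model.state_dict()
    model.eval()
    return state


def fine_tune(
    model: SeqToTracksModel,
    dataset: Callable,
    organism: str,
    schedule: OptimizerSchedule,
    steps: int,
    freeze_other_heads: bool = True,
    **kwargs,
) -> TrainState:
    """Continue training on a single organism at the lower fine-tune rate.

    With ``freeze_other_heads`` only the shared trunk and the designated
    organism's head receive updates; other heads are left untouched.
    """
    sub = OptimizerSchedule(
        target_lr=schedule.fine_tune_lr,
        warmup_steps=0,
        clip_norm=schedule.clip_norm,
        total_steps=steps,
        fine_tune_lr=schedule.fine_tune_lr,
        eval_every=schedule.eval_every,
    )
    trainable = None
    if freeze_other_heads:
        frozen = {id(p) for org, head in model.heads.items() if org != organism for p in head.parameters()}
        trainable = [p for p in model.parameters() if id(p) not in frozen]
    return train(
        model,
        {organism: dataset},
        sub,
        trainable=trainable,
        lr_override=sub.fine_tune_lr,
        **kwargs,
    )


def write_training_log(state: TrainState, path):
    import pandas as pd

    pd.DataFrame(state.log, columns=["step", "loss", "lr", "val_metric"]).to_csv(path, sep="\t", index=False)
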