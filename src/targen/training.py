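"""Two-stage training: exponential-decay pre-training and alternating
adapter/main fine-tuning with a twice-repeated cosine learning rate.

Pre-training fits the unconditional model (target id 0 everywhere) with Adam
and a per-epoch multiplicative learning-rate decay.  Fine-tuning inserts
zero-initialised adapters into the last two decoder blocks and alternates
two phases with period 25 epochs:

* *adapter* phase (epochs 0–14 of each period): only the adapters, the
  token/positional embeddings, the target-embedding table and the output
  layer receive updates;
* *main* phase (epochs 15–24): everything is trained except the adapters.

The embedding and output layers are trained in every epoch.  The cosine
schedule ramps 0 → peak over the warm-up epochs and decays back to 0 by the
end of each cycle; early stopping fires once the validation loss has not
improved for ``patience`` epochs, and the best-validation checkpoint is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codec import PAD_INDEX, TokenVocabulary, tokenize
from .nn.model import ConditionalDecoder

__all__ = [
    "PretrainConfig", "FinetuneConfig", "TrainState", "Adam",
    "pretrain_lr", "finetune_lr", "phase_for_epoch", "apply_freeze_mask",
    "early_stop", "encode_dataset", "pretrain", "finetune",
]


@dataclass(frozen=True)
class PretrainConfig:
    """Pre-training schedule: lr decays multiplicatively by ``decay_factor``
    each epoch starting from ``lr0``."""

    epochs: int = 100
    lr0: float = 1e-4
    decay_factor: float = 0.95
    batch_size: int = 512

    def __post_init__(self):
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay_factor must be in (0, 1)")


@dataclass(frozen=True)
class FinetuneConfig:
    """Alternating fine-tuning schedule.

    Defaults are the reference values: 15-epoch adapter phases alternating
    with 10-epoch main phases, cosine learning rate warming 0 → 1e-3 over 20
    epochs then decaying to 0 by epoch 100, two cycles (200-epoch budget),
    early-stopping patience 5.
    """

    adapter_phase_len: int = 15
    main_phase_len: int = 10
    max_epochs: int = 200
    patience: int = 5
    peak_lr: float = 1e-3
    warmup_epochs: int = 20
    cycle_len: int = 100
    n_cycles: int = 2
    batch_size: int = 512

    def __post_init__(self):
        if self.adapter_phase_len < 1 or self.main_phase_len < 1:
            raise ValueError("phase lengths must be positive")
        if self.cycle_len * self.n_cycles != self.max_epochs:
            raise ValueError("cycle_len * n_cycles must equal max_epochs")
        if not 0 < self.warmup_epochs < self.cycle_len:
            raise ValueError("warmup must lie inside the cycle")


@dataclass
class TrainState:
    """Progress bookkeeping for the fine-tuning loop."""

    epoch: int = 0
    phase: str = "adapter"
    val_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = math.inf
    best_state: dict | None = None


def pretrain_lr(epoch: int, cfg: PretrainConfig) -> float:
    """Learning rate for 1-based pre-training ``epoch``:
    lr0 · decay_factor^(epoch-1)."""
    if epoch < 1:
        raise ValueError("pre-training epochs are 1-based")
    return cfg.lr0 * cfg.decay_factor ** (epoch - 1)


def finetune_lr(epoch: int, cfg: FinetuneConfig) -> float:
    """Cosine schedule for the 0-based fine-tuning ``epoch``.

    Half-cosine ramp 0 → peak over the warm-up, half-cosine decay peak → 0
    over the remainder of each cycle; periodic with period ``cycle_len``.
    """
    if not 0 <= epoch < cfg.cycle_len * cfg.n_cycles:
        raise ValueError(f"epoch {epoch} outside the {cfg.n_cycles}-cycle budget")
    e = epoch % cfg.cycle_len
    w = cfg.warmup_epochs
    if e <= w:
        return cfg.peak_lr * 0.5 * (1.0 - math.cos(math.pi * e / w))
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * (e - w) / (cfg.cycle_len - w)))


def phase_for_epoch(epoch: int, cfg: FinetuneConfig) -> str:
    """'adapter' for the first 15 epochs of each 25-epoch period, then
    'main' for 10, alternating."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    period = cfg.adapter_phase_len + cfg.main_phase_len
    return "adapter" if epoch % period < cfg.adapter_phase_len else "main"


def apply_freeze_mask(groups: dict[str, list[str]], phase: str) -> dict[str, bool]:
    """Trainability per parameter group for the given phase.

    Adapter phase: adapters + embeddings + target table + output layer.
    Main phase: everything except the adapters.  Decoder blocks that carry
    no adapter train only in the main phase (beyond the always-trained
    embedding/output groups).
    """
    if phase not in ("adapter", "main"):
        raise ValueError(f"unknown phase {phase!r}")
    always = {"embeddings", "target_table", "output_linear"}
    mask = {}
    for g in groups:
        if g in always:
            mask[g] = True
        elif g.endswith(".adapter"):
            mask[g] = phase == "adapter"
        else:
            mask[g] = phase == "main"
    return mask


def early_stop(history: list[float], patience: int = 5) -> bool:
    """Stop once the running-best validation loss is ``patience`` epochs old.

    The best epoch is the first attainment of the minimum (ties do not count
    as improvement).
    """
    if not history:
        raise ValueError("history must be nonempty")
    best = int(np.argmin(history))
    return (len(history) - 1 - best) >= patience


class Adam:
    """Adam with per-parameter state; frozen parameters are skipped entirely
    (no state update, no weight change)."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = {k: 0 for k in params}

    def register(self, params: dict) -> None:
        """Pick up parameters added after construction (e.g. adapters)."""
        for k, p in params.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(p.data)
                self.v[k] = np.zeros_like(p.data)
                self.t[k] = 0

    def step(self, params: dict, lr: float,
             trainable: dict[str, bool] | None = None) -> None:
        for name, p in params.items():
            if p.grad is None:
                continue
            if trainable is not None and not trainable.get(name, True):
                continue
            g = p.grad
            self.t[name] += 1
            t = self.t[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1 ** t)
            vhat = self.v[name] / (1 - self.beta2 ** t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def encode_dataset(df, vocab: TokenVocabulary, max_len: int,
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Tokenize a dataframe with ``selfies`` (+ optional ``target``) columns
    into a PAD-padded index matrix.

    Molecules longer than ``max_len`` tokens (including SOS/EOS) are dropped;
    the number dropped is returned so callers can log it.
    """
    rows, targets = [], []
    dropped = 0
    has_target = "target" in df.columns
    for _, rec in df.iterrows():
        seq = tokenize(rec["selfies"], vocab, add_specials=True)
        if len(seq) > max_len:
            dropped += 1
            continue
        rows.append(seq.indices)
        targets.append(int(rec["target"]) if has_target else 0)
    if not rows:
        raise ValueError("no sequences shorter than max_len")
    width = max(len(r) for r in rows)
    mat = np.full((len(rows), width), PAD_INDEX, dtype=np.int64)
    for i, r in enumerate(rows):
        mat[i, :len(r)] = r
    return mat, np.asarray(targets, dtype=np.int64), dropped


def _epoch_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _run_epoch(model: ConditionalDecoder, tokens, targets, batch_size, lr,
               optimizer: Adam, rng, trainable=None, zero_target_row=True,
               ) -> float:
    losses = []
    for idx in _epoch_minibatches(len(tokens), batch_size, rng):
        model.zero_grad()
        loss = model.loss(tokens[idx], targets[idx], training=True, rng=rng)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite training loss {float(loss.data)}; aborting")
        loss.backward()
        tt = model.params["target_table"]
        if tt.grad is not None:
            tt.grad[0] = 0.0  # row 0 is the pinned unconditional embedding
        optimizer.step(model.params, lr, trainable)
        if zero_target_row:
            tt.data[0] = 0.0
        losses.append(float(loss.data))
    return float(np.mean(losses))


def evaluate_loss(model: ConditionalDecoder, tokens, targets,
                  batch_size: int = 512) -> float:
    """Mean validation loss with dropout disabled, weighted by token count."""
    total, weight = 0.0, 0.0
    for start in range(0, len(tokens), batch_size):
        sl = slice(start, start + batch_size)
        loss = model.loss(tokens[sl], targets[sl], training=False)
        w = float((tokens[sl][:, 1:] != PAD_INDEX).sum())
        total += float(loss.data) * w
        weight += w
    return total / weight


def pretrain(model: ConditionalDecoder, train_df, vocab: TokenVocabulary,
             cfg: PretrainConfig, seed: int = 0,
             log=None) -> list[float]:
    """Pre-train the unconditional model; returns the per-epoch mean loss.

    All records are trained with target id 0 (the pinned zero embedding),
    regardless of any target column in the input.
    """
    tokens, _, dropped = encode_dataset(train_df, vocab, model.config.max_len)
    targets = np.zeros(len(tokens), dtype=np.int64)
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        lr = pretrain_lr(epoch, cfg)
        mean_loss = _run_epoch(model, tokens, targets, cfg.batch_size, lr,
                               optimizer, rng)
        history.append(mean_loss)
        if log is not None:
            log({"stage": "pretrain", "epoch": epoch, "lr": lr,
                 "loss": mean_loss, "dropped": dropped})
    return history


def finetune(model: ConditionalDecoder, train_df, valid_df,
             vocab: TokenVocabulary, cfg: FinetuneConfig, seed: int = 0,
             adapter_blocks: tuple[int, ...] | None = None,
             log=None) -> TrainState:
    """Alternating-phase fine-tuning on target-labelled data.

    Inserts zero-initialised adapters into ``adapter_blocks`` — by default
    every block except the first, which keeps its pre-training form — so the
    first fine-tuning forward pass reproduces the pre-trained model exactly.
    Then runs the phase/freeze/cosine/early-stop loop and restores the
    best-validation weights before returning.
    """
    if "target" not in train_df.columns:
        raise ValueError("fine-tuning data must carry a 'target' column")
    if adapter_blocks is None:
        adapter_blocks = tuple(range(1, model.config.n_blocks))
    missing = set(model.adapter_blocks) ^ set(adapter_blocks)
    if not model.adapter_blocks:
        model.add_adapters(adapter_blocks, seed=seed)
    elif missing:
        raise ValueError("model already has adapters in different blocks")
    max_len = model.config.max_len
    tr_tokens, tr_targets, _ = encode_dataset(train_df, vocab, max_len)
    va_tokens, va_targets, _ = encode_dataset(valid_df, vocab, max_len)
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.params)
    groups = model.parameter_groups()
    state = TrainState()
    for epoch in range(cfg.max_epochs):
        phase = phase_for_epoch(epoch, cfg)
        group_mask = apply_freeze_mask(groups, phase)
        trainable = {name: group_mask[g]
                     for g, names in groups.items() for name in names}
        lr = finetune_lr(epoch, cfg)
        mean_loss = _run_epoch(model, tr_tokens, tr_targets, cfg.batch_size,
                               lr, optimizer, rng, trainable)
        val_loss = evaluate_loss(model, va_tokens, va_targets, cfg.batch_size)
        state.epoch, state.phase = epoch, phase
        state.val_history.append(val_loss)
        if val_loss < state.best_val:
            state.best_val = val_loss
            state.best_epoch = epoch
            state.best_state = model.state_dict()
        if log is not None:
            log({"stage": "finetune", "epoch": epoch, "phase": phase,
                 "lr": lr, "train_loss": mean_loss, "val_loss": val_loss})
        if early_stop(state.val_history, cfg.patience):
            break
    if state.best_state is not None:
        model.load_state_dict(state.best_state)
    return state
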