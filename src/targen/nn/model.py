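"""Target-conditional decoder-only transformer for molecular strings.

Architecture: token + learned positional embeddings feed a stack of decoder
blocks, each consisting of (1) causally masked multi-head self-attention,
(2) a conditional multi-head attention whose key/value memory is a single
slot holding the target-protein embedding (token states are the queries),
and (3) a position-wise feed-forward network, each sub-layer wrapped in a
pre-normalised residual (x + Sublayer(LN(x))).  A final layer norm and a
linear map to vocabulary size produce next-token logits.

Conditioning: targets are encoded as integers 1..n_targets with 0 meaning
"no target".  Row 0 of the embedding table is pinned to zeros and, because
the attention projections carry no bias terms, a zero memory contributes
*exactly* zero through the conditional attention — the unconditional mode is
the conditional model with an all-zero target slot, not an approximation.

Adapters: residual bottlenecks x + W_up·act(W_down·x) inserted after the
feed-forward sub-layer of selected blocks at fine-tuning time.  The
up-projection is zero-initialised, so insertion changes no output logit.

Pre-normalisation is load-bearing for both exactness guarantees above: with
post-layer-norm residuals, a sub-layer returning zero would still perturb
the stream through the normalisation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import (Tensor, cross_entropy_logits, dropout, embedding,
                       layer_norm, relu, softmax)

__all__ = [
    "ModelConfig", "AttentionParams", "AdapterParams", "ConditionalDecoder",
    "scaled_dot_attention", "multi_head_attention", "adapter_forward",
    "save_checkpoint", "load_checkpoint",
]

_NEG = -1e30  # additive mask value; exp(_NEG - max) underflows to exact 0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults follow the reference configuration (d_model 512, 8 heads,
    3 blocks, per-head dims d_k = d_v = d_model/h = 64); desk-scale runs
    shrink d_model/h but keep the block structure.
    """

    vocab_size: int
    d_model: int = 512
    n_heads: int = 8
    n_blocks: int = 3
    ffn_dim: int | None = None       # default 4 * d_model
    adapter_dim: int = 64
    dropout: float = 0.1
    max_len: int = 72
    n_targets: int = 3

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.adapter_dim >= self.d_model:
            raise ValueError("adapter_dim must be smaller than d_model")
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.d_model)

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    d_v = d_k


@dataclass
class AttentionParams:
    """Per-head projection stacks: W_q/W_k (h, d_model, d_k), W_v
    (h, d_model, d_v), output projection W_o (h*d_v, d_model).  No biases."""

    W_q: Tensor
    W_k: Tensor
    W_v: Tensor
    W_o: Tensor


@dataclass
class AdapterParams:
    """Residual bottleneck weights; output shape equals input shape."""

    W_down: Tensor
    W_up: Tensor
    nonlinearity: str = "relu"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def scaled_dot_attention(Q, K, V, mask: np.ndarray | None = None) -> Tensor:
    """softmax(Q Kᵀ / √d_k) V for a single head.

    ``mask`` is boolean with True = blocked; blocked positions receive a
    -inf-equivalent score before the softmax.  A fully masked query row has
    an undefined softmax and raises ``ValueError``.
    """
    Q, K, V = _as_tensor(Q), _as_tensor(K), _as_tensor(V)
    d_k = Q.shape[-1]
    scores = (Q @ K.transpose(*range(K.data.ndim - 2), K.data.ndim - 1,
                              K.data.ndim - 2)) / np.sqrt(d_k)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.all(axis=-1).any():
            raise ValueError("fully masked attention row: softmax undefined")
        scores = scores + np.where(mask, _NEG, 0.0)
    return softmax(scores, axis=-1) @ V


def multi_head_attention(Q, K, V, params: AttentionParams,
                         mask: np.ndarray | None = None) -> Tensor:
    """Concat(Head_1..Head_h) W_o with Head_i = scaled_dot_attention of the
    per-head projections.  Inputs are (..., T, d_model) / (..., M, d_model)."""
    Q, K, V = _as_tensor(Q), _as_tensor(K), _as_tensor(V)
    single = Q.data.ndim == 2
    if single:
        Q, K, V = (x.reshape(1, *x.shape) for x in (Q, K, V))
    B, T, D = Q.shape
    M = K.shape[-2]
    h = params.W_q.shape[0]
    d_v = params.W_v.shape[-1]
    Qh = Q.reshape(B, 1, T, D) @ params.W_q            # (B, h, T, d_k)
    Kh = K.reshape(B, 1, M, D) @ params.W_k
    Vh = V.reshape(B, 1, M, D) @ params.W_v
    heads = scaled_dot_attention(Qh, Kh, Vh, mask)      # (B, h, T, d_v)
    concat = heads.transpose(0, 2, 1, 3).reshape(B, T, h * d_v)
    out = concat @ params.W_o
    return out.reshape(T, D) if single else out


def adapter_forward(x, params: AdapterParams) -> Tensor:
    """Residual bottleneck x + W_up · act(W_down · x), applied row-wise."""
    x = _as_tensor(x)
    act = {"relu": relu, "tanh": Tensor.tanh, "identity": lambda t: t}[
        params.nonlinearity]
    return x + act(x @ params.W_down) @ params.W_up


class ConditionalDecoder:
    """The stacked decoder with its parameter store.

    Parameters live in a flat name → Tensor dict and every tensor belongs to
    exactly one named group (the unit of the fine-tuning freeze schedule):
    ``embeddings``, ``target_table``, ``output_linear`` and per block
    ``block{i}.self_attn`` / ``block{i}.cond_attn`` / ``block{i}.ffn`` /
    ``block{i}.adapter``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0,
                 _init: bool = True):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self.adapter_blocks: tuple[int, ...] = ()
        if _init:
            self._initialise(np.random.default_rng(seed))

    # -- construction --------------------------------------------------
    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = Tensor(data, requires_grad=True, name=name)

    def _initialise(self, rng: np.random.Generator) -> None:
        c = self.config
        s = 0.02
        self._add("tok_emb", rng.normal(0, s, (c.vocab_size, c.d_model)))
        self._add("pos_emb", rng.normal(0, 0.01, (c.max_len, c.d_model)))
        # conditional embeddings start at zero (row 0 stays zero forever)
        self._add("target_table", np.zeros((c.n_targets + 1, c.d_model)))
        for i in range(c.n_blocks):
            for attn in ("self_attn", "cond_attn"):
                self._add(f"block{i}.{attn}.W_q",
                          rng.normal(0, s, (c.n_heads, c.d_model, c.d_k)))
                self._add(f"block{i}.{attn}.W_k",
                          rng.normal(0, s, (c.n_heads, c.d_model, c.d_k)))
                self._add(f"block{i}.{attn}.W_v",
                          rng.normal(0, s, (c.n_heads, c.d_model, c.d_v)))
                self._add(f"block{i}.{attn}.W_o",
                          rng.normal(0, s, (c.n_heads * c.d_v, c.d_model)))
                self._add(f"block{i}.{attn}.ln.gain", np.ones(c.d_model))
                self._add(f"block{i}.{attn}.ln.bias", np.zeros(c.d_model))
            self._add(f"block{i}.ffn.W1", rng.normal(0, s, (c.d_model, c.ffn_dim)))
            self._add(f"block{i}.ffn.b1", np.zeros(c.ffn_dim))
            self._add(f"block{i}.ffn.W2", rng.normal(0, s, (c.ffn_dim, c.d_model)))
            self._add(f"block{i}.ffn.b2", np.zeros(c.d_model))
            self._add(f"block{i}.ffn.ln.gain", np.ones(c.d_model))
            self._add(f"block{i}.ffn.ln.bias", np.zeros(c.d_model))
        self._add("final_ln.gain", np.ones(c.d_model))
        self._add("final_ln.bias", np.zeros(c.d_model))
        self._add("out.W", rng.normal(0, s, (c.d_model, c.vocab_size)))
        self._add("out.b", np.zeros(c.vocab_size))

    def add_adapters(self, blocks: tuple[int, ...] = (1, 2),
                     seed: int = 0) -> None:
        """Insert zero-initialised adapters; the forward pass is unchanged
        until the up-projections move away from zero."""
        rng = np.random.default_rng(seed)
        c = self.config
        for i in blocks:
            if not 0 <= i < c.n_blocks:
                raise ValueError(f"no block {i}")
            self._add(f"block{i}.adapter.W_down",
                      rng.normal(0, 0.02, (c.d_model, c.adapter_dim)))
            self._add(f"block{i}.adapter.W_up",
                      np.zeros((c.adapter_dim, c.d_model)))
        self.adapter_blocks = tuple(sorted(set(self.adapter_blocks) | set(blocks)))

    # -- parameter bookkeeping -----------------------------------------
    def parameter_groups(self) -> dict[str, list[str]]:
        """Partition of parameter names into freeze-schedule groups."""
        groups: dict[str, list[str]] = {
            "embeddings": [], "target_table": [], "output_linear": []}
        for i in range(self.config.n_blocks):
            for g in ("self_attn", "cond_attn", "ffn"):
                groups[f"block{i}.{g}"] = []
        for i in self.adapter_blocks:
            groups[f"block{i}.adapter"] = []
        for name in self.params:
            if name in ("tok_emb", "pos_emb"):
                groups["embeddings"].append(name)
            elif name == "target_table":
                groups["target_table"].append(name)
            elif name.startswith(("final_ln", "out.")):
                groups["output_linear"].append(name)
            elif name.startswith("block"):
                block, sub = name.split(".")[:2]
                key = f"{block}.{sub}"
                if key not in groups:
                    raise ValueError(f"orphan parameter {name!r}")
                groups[key].append(name)
            else:
                raise ValueError(f"orphan parameter {name!r}")
        assigned = sum(len(v) for v in groups.values())
        if assigned != len(self.params):
            raise ValueError("parameter group partition is not exhaustive")
        return groups

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("state dict does not match parameter census")
        for k, v in state.items():
            self.params[k].data = np.array(v, dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- forward pass ---------------------------------------------------
    def _attn_params(self, block: int, which: str) -> AttentionParams:
        p = self.params
        return AttentionParams(
            W_q=p[f"block{block}.{which}.W_q"], W_k=p[f"block{block}.{which}.W_k"],
            W_v=p[f"block{block}.{which}.W_v"], W_o=p[f"block{block}.{which}.W_o"])

    def _adapter_params(self, block: int) -> AdapterParams:
        return AdapterParams(W_down=self.params[f"block{block}.adapter.W_down"],
                             W_up=self.params[f"block{block}.adapter.W_up"])

    def _ln(self, x: Tensor, prefix: str) -> Tensor:
        return layer_norm(x, self.params[f"{prefix}.gain"],
                          self.params[f"{prefix}.bias"])

    def block_forward(self, block: int, x: Tensor, memory: Tensor,
                      causal_mask: np.ndarray,
                      use_adapter: bool = True, use_conditioning: bool = True,
                      training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """One decoder block on a (B, T, d_model) stream."""
        c = self.config

        def drop(t: Tensor) -> Tensor:
            return dropout(t, c.dropout, rng, training)

        h = self._ln(x, f"block{block}.self_attn.ln")
        x = x + drop(multi_head_attention(
            h, h, h, self._attn_params(block, "self_attn"), causal_mask))
        if use_conditioning:
            q = self._ln(x, f"block{block}.cond_attn.ln")
            x = x + drop(multi_head_attention(
                q, memory, memory, self._attn_params(block, "cond_attn")))
        h = self._ln(x, f"block{block}.ffn.ln")
        p = self.params
        inner = relu(h @ p[f"block{block}.ffn.W1"] + p[f"block{block}.ffn.b1"])
        x = x + drop(inner @ p[f"block{block}.ffn.W2"] + p[f"block{block}.ffn.b2"])
        if use_adapter and block in self.adapter_blocks:
            x = adapter_forward(x, self._adapter_params(block))
        return x

    def forward(self, tokens: np.ndarray, target_ids: np.ndarray | int,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Next-token logits (B, T, vocab_size) for int tokens (B, T)."""
        c = self.config
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.int64))
        B, T = tokens.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        if tokens.min() < 0 or tokens.max() >= c.vocab_size:
            raise ValueError("token index out of vocabulary range")
        target_ids = np.broadcast_to(np.asarray(target_ids, dtype=np.int64), (B,))
        if target_ids.min() < 0 or target_ids.max() > c.n_targets:
            raise ValueError("target id out of range")
        x = embedding(self.params["tok_emb"], tokens) \
            + embedding(self.params["pos_emb"], np.arange(T))
        x = dropout(x, c.dropout, rng, training)
        memory = embedding(self.params["target_table"],
                           target_ids[:, None])        # (B, 1, d_model)
        causal = np.triu(np.ones((T, T), dtype=bool), k=1)
        for i in range(c.n_blocks):
            x = self.block_forward(i, x, memory, causal,
                                   training=training, rng=rng)
        x = self._ln(x, "final_ln")
        return x @ self.params["out.W"] + self.params["out.b"]

    def loss(self, tokens: np.ndarray, target_ids, pad_index: int = 0,
             training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
        """Teacher-forced next-token cross-entropy with PAD masked out."""
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.int64))
        inputs, targets = tokens[:, :-1], tokens[:, 1:]
        logits = self.forward(inputs, target_ids, training=training, rng=rng)
        mask = (targets != pad_index).astype(np.float64)
        return cross_entropy_logits(logits, targets, mask)


def save_checkpoint(model: ConditionalDecoder, path: str | Path,
                    vocab_hash: str = "", extra: dict | None = None) -> None:
    """Weight archive (.npz) plus a JSON sidecar with config and vocab hash."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {
        "config": asdict(model.config),
        "adapter_blocks": list(model.adapter_blocks),
        "vocab_hash": vocab_hash,
        **(extra or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path,
                    expect_vocab_hash: str | None = None
                    ) -> tuple[ConditionalDecoder, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if expect_vocab_hash is not None and sidecar["vocab_hash"] != expect_vocab_hash:
        raise ValueError("vocabulary hash mismatch between checkpoint and vocab")
    model = ConditionalDecoder(ModelConfig(**sidecar["config"]))
    if sidecar["adapter_blocks"]:
        model.add_adapters(tuple(sidecar["adapter_blocks"]))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, sidecar
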