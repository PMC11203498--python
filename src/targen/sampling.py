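"""Autoregressive molecule sampling with temperature-scaled categorical
draws, conditional on a target id.

Each generated sequence owns an independent counter-based random stream
derived from (seed, sequence index), so the sampled set is invariant to how
sequences are batched.  Decoding goes through the robust string grammar, so
every emitted sequence yields a valid molecule regardless of how well the
model is trained — validity is a property of the representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import EOS_INDEX, SOS_INDEX, TokenVocabulary, detokenize, selfies_to_smiles
from .nn.model import ConditionalDecoder

__all__ = ["GenerationConfig", "sample_next_token", "generate"]

#: temperatures below this are treated as the greedy (argmax) limit
_GREEDY_EPS = 1e-8


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling protocol: temperature 1.5 by default; top-k filtering is an
    optional comparison mode (k = 30 when enabled), off by default."""

    n_samples: int = 1000
    temperature: float = 1.5
    max_len: int = 72
    target_id: int = 0
    seed: int = 42
    top_k: int | None = None
    batch_size: int = 512

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 when set")


def sample_next_token(logits: np.ndarray, temperature: float,
                      rng: np.random.Generator,
                      top_k: int | None = None) -> int:
    """Draw a token index from softmax(logits / temperature).

    As temperature → 0+ this reduces to argmax.  With ``top_k`` set, mass is
    restricted to the k highest-scoring tokens before sampling.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if top_k is not None and top_k < logits.size:
        cutoff = np.partition(logits, -top_k)[-top_k]
        logits = np.where(logits >= cutoff, logits, -np.inf)
    if temperature < _GREEDY_EPS:
        return int(np.argmax(logits))
    scaled = logits / temperature
    scaled = scaled - scaled[np.isfinite(scaled)].max()
    p = np.exp(scaled)
    p /= p.sum()
    return int(rng.choice(logits.size, p=p))


def generate(model: ConditionalDecoder, vocab: TokenVocabulary,
             cfg: GenerationConfig) -> pd.DataFrame:
    """Sample ``n_samples`` molecules; returns columns selfies/smiles/target.

    Sequences start from SOS and terminate at EOS or ``max_len`` tokens
    (truncated sequences are decoded as-is).  SOS/EOS/PAD are stripped
    before grammar decoding.
    """
    if len(vocab) != model.config.vocab_size:
        raise ValueError("vocabulary size does not match model checkpoint")
    max_len = min(cfg.max_len, model.config.max_len)
    sequences: list[list[int]] = []
    for chunk_start in range(0, cfg.n_samples, cfg.batch_size):
        chunk = min(cfg.batch_size, cfg.n_samples - chunk_start)
        rngs = [np.random.default_rng([cfg.seed, chunk_start + i])
                for i in range(chunk)]
        seqs = [[SOS_INDEX] for _ in range(chunk)]
        alive = list(range(chunk))
        while alive and len(seqs[alive[0]]) < max_len:
            ctx = np.array([seqs[i] for i in alive], dtype=np.int64)
            logits = model.forward(ctx, cfg.target_id).data[:, -1, :]
            still = []
            for row, i in enumerate(alive):
                tok = sample_next_token(logits[row], cfg.temperature,
                                        rngs[i], cfg.top_k)
                seqs[i].append(tok)
                if tok != EOS_INDEX:
                    still.append(i)
            alive = still
        sequences.extend(seqs)
    rows = []
    for seq in sequences:
        selfies = detokenize(seq, vocab)
        rows.append({"selfies": selfies,
                     "smiles": selfies_to_smiles(selfies),
                     "target": cfg.target_id})
    return pd.DataFrame(rows)
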