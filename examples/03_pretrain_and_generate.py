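"""Pre-train a small unconditional model and sample molecules from it.

Uses a reduced configuration (d_model 64, 4 heads, 3 decoder blocks) so the
whole script runs in about a minute on a laptop CPU.  Every sampled
molecule is valid by construction; uniqueness and novelty depend on the
model and are reported by the metric functions.
"""

from targen import (ConditionalDecoder, GenerationConfig, ModelConfig,
                    build_vocabulary, generate, generate_corpus,
                    novel_fraction, pretrain, unique_fraction, valid_fraction)
from targen.training import PretrainConfig

corpus = generate_corpus(n=2000, seed=7)
vocab = build_vocabulary(list(corpus.records["selfies"]))
print(f"vocabulary: {len(vocab)} tokens (3 specials + "
      f"{len(vocab.tokens)} chemical symbols)")

model = ConditionalDecoder(
    ModelConfig(vocab_size=len(vocab), d_model=64, n_heads=4, n_blocks=3,
                adapter_dim=16, max_len=72), seed=0)
history = pretrain(model, corpus.records[corpus.records["split"] == "train"],
                   vocab, PretrainConfig(epochs=3, batch_size=256), seed=1)
print("pre-training loss per epoch:", [round(h, 3) for h in history])

out = generate(model, vocab, GenerationConfig(n_samples=500, temperature=1.5,
                                              max_len=72, seed=42))
valid, P = valid_fraction(list(out["smiles"]))
print(f"valid fraction: {valid:.3f} over {len(out)} samples")
print(f"unique@{len(P)}: {unique_fraction(P, c=len(P), seed=0):.3f}")
print(f"novel vs training corpus: "
      f"{novel_fraction(P, list(corpus.records['smiles'].fillna(''))):.3f}")
print("example molecules:", list(out['smiles'].head(5)))
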