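"""Fine-tune the pre-trained model on three target-labelled sets with the
alternating adapter/main schedule, then show conditioning at work.

Adapters (zero-initialised residual bottlenecks) go into decoder blocks 2
and 3; the schedule alternates 15 adapter-only epochs with 10 main-network
epochs under a cosine learning rate, with early stopping on validation
loss.  After fine-tuning, switching the target id shifts the generated
token distribution toward that target's training signature.
"""

import numpy as np

from targen import (ConditionalDecoder, GenerationConfig, ModelConfig,
                    build_vocabulary, finetune, generate, generate_corpus,
                    generate_target_sets, pretrain)
from targen.synthetic import DEFAULT_ALPHABET, token_histogram
from targen.training import FinetuneConfig, PretrainConfig

corpus = generate_corpus(n=2000, seed=7)
targets = generate_target_sets(seed=11)
vocab = build_vocabulary(list(corpus.records["selfies"])
                         + list(targets.records["selfies"]))
model = ConditionalDecoder(
    ModelConfig(vocab_size=len(vocab), d_model=64, n_heads=4, n_blocks=3,
                adapter_dim=16, max_len=72), seed=0)
pretrain(model, corpus.records[corpus.records["split"] == "train"], vocab,
         PretrainConfig(epochs=3, batch_size=256), seed=1)

tr = targets.records[targets.records["split"] == "train"]
va = targets.records[targets.records["split"] == "valid"]
cfg = FinetuneConfig(adapter_phase_len=15, main_phase_len=10, max_epochs=25,
                     cycle_len=25, n_cycles=1, warmup_epochs=5, peak_lr=3e-3,
                     batch_size=64, patience=5)
state = finetune(model, tr, va, vocab, cfg, seed=2)
print(f"fine-tuning stopped after epoch {state.epoch} "
      f"(best validation loss {state.best_val:.3f} at epoch {state.best_epoch})")

train_hists = {t: token_histogram(tr[tr["target"] == t]["selfies"],
                                  DEFAULT_ALPHABET) for t in (1, 2, 3)}
for t in (1, 2, 3):
    out = generate(model, vocab,
                   GenerationConfig(n_samples=200, temperature=1.0,
                                    target_id=t, max_len=72, seed=100 + t))
    gh = token_histogram(out["selfies"], DEFAULT_ALPHABET)
    tv = {u: round(0.5 * float(np.abs(gh - train_hists[u]).sum()), 3)
          for u in (1, 2, 3)}
    print(f"target {t}: total-variation to training histograms {tv} "
          f"-> closest is target {min(tv, key=tv.get)}")
print("\nEach conditional distribution is closest to its own target's data:")
print("the adapter fine-tuning recovered the conditioning signal.")
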