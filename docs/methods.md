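# Methods

`targen` implements a target-conditional autoregressive molecular generator
with an adapter-based alternating fine-tuning strategy, together with the
evaluation stack used to judge de-novo design models (validity, uniqueness,
novelty, property distributions, QSAR activity scoring).  This note records
the model, the choices made where the design was genuinely open, what the
synthetic data emulates, and what the tests do and do not establish.

## Molecular representation

Molecules are written in a robust derivation-rule string grammar in the
SELFIES family, implemented in `targen.grammar`.  Symbols are bracketed
atoms with a bond-order prefix (`[C]`, `[=O]`, `[#N]`), branch openers with
base-16 length operands (`[Branch1] <digit>`), and ring closers with
distance operands (`[Ring1]`, `[=Ring1]`, …).  During decoding, bond orders
are capped by the remaining valence of both partners, unrealisable branch
and ring instructions are consumed and skipped, and a fragment stops
growing when its attachment atom is saturated.  As a consequence *every*
sequence of alphabet symbols decodes to a chemically valid molecule; the
only decoding error is an out-of-alphabet symbol.  This is the entire
mechanism behind the pipeline's Valid = 1.0 guarantee — it is a property of
the representation, not of the trained model, and holds for random-weight
checkpoints.

The grammar covers neutral molecules over B, C, N, O, S, P, F, Cl, Br, I
with bond orders 1–3.  Sulfur and phosphorus are capped at their lowest
common valences (2 and 3) so every decoded atom maps onto a standard
neutral valence state; charged, radical, isotopic or hypervalent inputs
raise an explicit encoding error.  Stereochemistry is dropped on encoding
(the alphabet carries no stereo markers).  Round-trip equality is judged on
the toolkit's canonical SMILES.  An empty derivation returns the empty
string; the toolkit parses it as the empty molecule, so zero-token samples
count as valid — after even brief training they essentially disappear.

The vocabulary fixes PAD/SOS/EOS at indices 0–2 and sorts chemical tokens
lexicographically, so identical corpora always yield identical vocabularies
(reproducible checkpoints).  The default maximum sequence length is 72
tokens including specials; longer training molecules are dropped with a
reported count.

## Model

A decoder-only transformer (default: d_model = 512, h = 8 heads,
d_k = d_v = d_model/h = 64, 3 blocks, FFN width 4·d_model, dropout 0.1;
desk-scale runs use d_model = 64, h = 4).  Each block applies

1. causally masked multi-head self-attention,
2. conditional multi-head attention whose key/value memory is a single
   slot holding the target embedding (token states are queries),
3. a position-wise feed-forward network,

each as a pre-normalised residual `x + Sublayer(LN(x))`, followed by a
final layer norm and a linear map to vocabulary logits.  Positions are
learned embeddings added to token embeddings.

Two exactness guarantees shaped the numerics:

* **Zero-target transparency.**  Target id 0 selects a row of the embedding
  table that is pinned to zeros and never updated.  Attention projections
  carry no bias terms, so a zero memory yields exactly zero through the
  conditional attention: the unconditional model is the conditional model
  at target 0, bit for bit.
* **Identity at insertion.**  Adapters are residual bottlenecks
  `x + W_up·relu(W_down·x)` (default width d_model/8 at reference scale,
  16 at desk scale) placed after the FFN sub-layer inside the residual
  stream, with `W_up` zero-initialised and `W_down` small random.
  Inserting them into a pre-trained model changes no logit.

Pre-normalisation is load-bearing for both: with post-layer-norm residuals
a sub-layer returning zero would still perturb the stream through the
normalisation, and neither guarantee would hold exactly.  That is why this
package uses pre-LN rather than the post-LN arrangement of the original
transformer.

The conditioning memory is used raw (not layer-normalised): normalising a
zero vector would inject the norm's bias and break transparency.

## Training

**Pre-training** (unconditional, target 0 everywhere): Adam, batch 512 at
reference scale, 100 epochs, learning rate 1e-4 multiplied by 0.95 each
epoch.  The loss is teacher-forced next-token cross-entropy with PAD
positions masked.  Desk-scale runs use 3–5 epochs on a 5,000-molecule
synthetic corpus with batch 256.

**Fine-tuning** inserts adapters into every block except the first (the
first block keeps its pre-training form) and alternates two phases with
period 25 epochs: 15 *adapter* epochs in which only the adapters, the
token/positional embeddings, the target table and the output layer are
trainable, then 10 *main* epochs in which everything except the adapters
trains.  The embedding and output layers train in every epoch.  The
learning rate follows a half-cosine ramp 0 → 1e-3 over 20 epochs and a
half-cosine decay back to 0 by epoch 100, repeated for two cycles
(200-epoch budget).  Early stopping fires once the validation loss —
computed on the concatenated per-target 10% splits — has not improved for
5 epochs, and the best-validation checkpoint is restored.  `patience` is
defined as the maximum number of epochs allowed since the first attainment
of the best loss; ties do not count as improvement.  Frozen parameters are
skipped entirely by the optimizer (no moment updates), so freeze
correctness is exact weight equality, asserted in the tests.

The global fine-tuning epoch index drives both the cosine schedule and the
phase alternation; early stopping simply truncates it.

Desk-scale fine-tuning uses a shape-preserving shrink of the schedule
(peak 3e-3, warm-up 5, one 25-epoch cycle, batch 64) chosen once for the
study conditions; the 15/10 alternation and patience 5 are kept.

## Generation

Sampling starts from SOS and draws each next token from
softmax(logits/T) with T = 1.5 by default (top-k with k = 30 is available
as a comparison mode, off by default), stopping at EOS or 72 tokens;
truncated sequences are decoded as-is.  Each sequence owns a counter-based
random stream derived from (seed, sequence index), so the sampled set is
invariant to batching.  Temperatures below 1e-8 are treated as the greedy
argmax limit.

## Synthetic data

The generators stand in for a drug-like pre-training corpus and small
target-labelled fine-tuning sets at desk scale:

* **Corpus**: 5,000 molecules, token lengths uniform on [8, 36], tokens
  i.i.d. uniform over a 12-symbol alphabet (C/N/O with double-bond
  variants, F, S, Cl, Br, branch and ring symbols).  Robust decoding makes
  every record valid.
* **Target sets**: 300/600/150 molecules for targets 1/2/3, preserving the
  relative ordering of the real fine-tuning sets (1381/3585/795 for
  EGFR/HTR1A/S1PR1) and the small-fine-tuning-set regime (~0.3% of
  pre-training data in the reference setting).  Each target multiplies the
  probability mass of two preferred tokens by 5 (nitrogen, oxygen, and
  sulfur/chlorine tokens respectively), giving pairwise total-variation
  distances ≈ 0.4 between target token distributions — distinguishable by
  a token-frequency classifier with accuracy > 0.8, the precondition for
  the conditioning-recovery tests.  Splits are 9:1 train/validation per
  target before concatenation.
* **Activity labels** emulate pXC50: 4 + 6·(preferred-token fraction) +
  N(0, 0.3), clipped to [4, 10], so the anchors are 4 (no preferred
  tokens), 10 (all preferred) and 7 — the 'high' class boundary — at
  fraction 0.5.  The fraction is computed on the *canonical re-encoding*
  of the decoded molecule, not the raw sampled string: derivation can
  discard tokens (a saturated chain stops growing), and a label defined on
  discarded tokens would not be a function of the structure a QSAR model
  sees.  Defining it on the canonical encoding makes structure → activity
  well-defined and recoverable.

What the synthetic data does *not* emulate: realistic chemistry (the
molecules are small and combinatorial rather than drug-like), scaffold
structure, assay noise heteroscedasticity, or inter-target correlation.
Passing tests therefore demonstrate that the machinery — conditioning,
freeze schedules, metrics, activity regression — works and is calibrated,
not that the model would reach the reference benchmark numbers on real
corpora at full scale.

## Evaluation metrics

Valid = n(P)/n(G) with validity = toolkit parseability; Unique@k =
n(U)/n(S) on a seeded size-k subsample of P without replacement; Novel =
n(P\X)/n(P), the *generated-set perspective* (fraction of valid molecules
never seen in training), with all comparisons keyed on canonical SMILES.
Property distributions are compared by the empirical 1-Wasserstein
distance.  Profiles report MW, TPSA, LogP, HBD, HBA, QED and SA (the last
two delegated to the toolkit's published implementations), with good-range
percentages over the closed intervals MW [200, 500], TPSA [20, 130],
LogP [−1, 6], HBD [0, 5], HBA [0, 10], QED [0.4, 1], SA [1, 5].  pXC50
classes use left-closed boundaries: low < 6 ≤ middle < 7 ≤ high < 8 ≤
ultra-high.

## QSAR

Features are a fixed 2533-long concatenation: 2048-bit FCFP6
(functional-class Morgan fingerprint, radius 3), MACCS keys 1–166, and 319
descriptors pinned by a frozen manifest (the toolkit's 210-entry descriptor
list, the 42 molecular quantum numbers, and the first 67 2-D
autocorrelation components).  Non-finite descriptor values become 0.0.
The regressor is LightGBM with library defaults, a fixed seed and one
thread (deterministic).  Rankings sort by descending predicted pXC50 with
ties broken by ascending canonical SMILES.

## Numerical choices and degenerate inputs

* Float64 throughout the network; gradient correctness is pinned by
  central-difference tests at 1e-5 tolerance.
* Masked attention adds −1e30 before the softmax; after the stability
  shift this underflows to an exact zero weight.  A fully masked query row
  is an error (undefined softmax).
* Non-finite training loss aborts with a diagnostic rather than training
  on garbage.
* Empty corpus, empty generation set, out-of-vocabulary symbols,
  vocabulary/checkpoint hash mismatches, and sub-50-molecule QSAR training
  sets are all explicit errors.

## Problem sizes

Test-suite and acceptance runs use: 5,000-molecule corpus with a reduced
model (d_model 64, 4 heads, 3 blocks, 5 epochs, batch 256) and 1,000
samples for the validity protocol; a 2,000-molecule corpus (3 epochs) for
the conditioning-recovery sweep over 3 fine-tuning seeds; n = 500 for the
QSAR signal-recovery fixture.  These sizes keep the full workflow at
minutes on a single CPU while leaving every mechanism exercised at its
reference shape.

## Known limitations

* The grammar's element and valence coverage excludes charged species,
  hypervalent S/P (sulfones, phosphates) and stereochemistry; encoding
  such molecules raises an error rather than approximating them.
* The desk-scale model is far below the capacity regime of the reference
  configuration; uniqueness/novelty of its samples are reported, not
  asserted, since they are properties of training scale.
* LightGBM determinism is guaranteed only for a fixed seed, thread count
  and library version.
* Checkpoints are a weight archive plus JSON sidecar; no cross-version
  migration is attempted.
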