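# Methods

## Problem and model

The package classifies free-text documents — the motivating application is
assigning ICD-O-3 primary-site topography codes (C00–C90) to cancer
pathology reports — with a word-level convolutional neural network, and
trains that network under asynchronous data-parallel ("downpour") stochastic
gradient descent with a parameter server.

A document is tokenized, truncated/right-padded to *n* tokens, and mapped
through a trainable embedding matrix to a document matrix **A** ∈ ℝ^{n×k}.
For each filter width *h* ∈ {3, 4, 5}, a bank of *F* linear filters
**w** ∈ ℝ^{h·k} slides over every window of *h* consecutive word vectors,

    o_i = w · A[i : i+h−1],      c_i = f(o_i + b),   i = 1 … n−h+1,

and global max pooling keeps each filter's single largest response,
recording its position so the backward pass routes gradient only to the
argmax window. The pooled responses of all widths (3·*F* values) pass
through a fully-connected hidden layer with inverted dropout and a softmax
output trained under mean cross-entropy. All gradients are derived by hand
in numpy (no autodiff) and are verified against central finite differences.

At full scale the defaults follow the reference architecture: *n* = 1500,
*k* = 300, *F* = 300 per width, dropout 0.5, embeddings initialized
uniformly in (−0.025, 0.025) with the PAD row frozen at zero.

Choices the architecture description leaves open, fixed here as package
defaults:

- **Activation**: rectifier (configurable to tanh). A window of width *h*
  over *n* positions yields *n−h+1* valid starts; that count is used.
- **Hidden layer size**: 300 at full scale (unstated upstream; standard).
- **"l2-normalization"** is implemented as a max-norm constraint in the
  word-CNN lineage's sense: after every optimizer application, any word
  vector, filter weight vector, or dense column whose l2 norm exceeds the
  cap *s* (default 3) is rescaled onto the sphere of radius *s*.
- **Biases**: one scalar per filter; bias vectors on the dense layers.
- **Dropout** is inverted (masks scaled by 1/keep at train time), so
  evaluation needs no rescaling.
- Cross-entropy clamps p at 1e−12 to keep the loss finite under underflow.
- Prediction ties resolve to the lowest class index (numpy argmax).

## Preprocessing

Text is lowercased and split on whitespace and non-alphanumeric symbols;
decimal numbers collapse to a FLOAT token and integers of three or more
digits to a LARGEINT token (1–2 digit integers such as grades stay
literal). Tokens appearing in fewer than five documents (document
frequency, configurable) map to a shared RARE token. The exact token
pattern is `<rare>|<float>|<largeint>|\d+\.\d+|[a-z0-9]+`, which makes the
tokenizer idempotent on its own rendered output. Cross-validation splits
are class-stratified by per-class seeded shuffle plus round-robin (remainder
records to the lowest-index folds); 25% of each training portion, stratified,
is held out for validation. Vocabularies are built from the training portion
of a fold only.

## Asynchronous training protocol

The training set is partitioned into N near-equal shards after a seeded
shuffle. Each worker draws mini-batches without replacement within its
local epoch, computes mean gradients on its current local weights, and
sends them with the server version those weights derive from. The server
applies each packet with the configured optimizer (w ← w + delta), enforces
the norm constraints server-side, increments its version, and replies to
the sender with fresh weights. Workers block between send and reply (at
most one update in flight each), which bounds staleness; weights arriving
mid-batch would be applied only after that batch's gradients are computed
(deferred local application), and the worker-level API honors that rule.

Asynchrony is executed by a deterministic discrete-event scheduler. Batch
compute cost is modeled as constant per batch divided by a per-worker speed
multiplier; with equal speeds workers advance in lockstep rounds and logged
staleness is at most N−1. Heterogeneous speed multipliers are supported,
with the weaker guarantee that staleness stays finite (a much faster worker
can interleave several updates during a slower worker's batch). One epoch
is the aggregate consumption of M training cases across workers; validation
loss — computed on the parameter server's current weights — is logged every
quarter epoch, giving exactly 4·(epochs) checkpoints. A run stops when
every worker has completed its local epochs, so applied updates per epoch
equal Σ_n ⌈|shard_n|/batch⌉ exactly. With N = 1 the scheduler collapses,
bit-for-bit, to a serial training loop; the test suite asserts this for all
four optimizers. Only the simulated transport is implemented; the protocol
is factored so a message-passing transport could be added behind the same
worker/server operations.

Randomness is compartmentalized: worker *i*'s epoch shuffles and dropout
masks come from `default_rng([seed, 7919, i])`; partitioning and splitting
use their own tagged streams. Every run is a pure function of (config,
seeds).

## Optimizers

SGD, RMSProp, Adadelta and Adam in their canonical published forms, with
the original papers' hyperparameter defaults (SGD η=0.01; RMSProp η=0.001,
ρ=0.9, ε=1e−8; Adadelta ρ=0.95, ε=1e−6; Adam η=0.001, β₁=0.9, β₂=0.999,
ε=1e−8). Adam includes bias correction (its canonical form, even though
prose descriptions of the rule sometimes omit it). Adadelta's window of
past gradients is the standard exponential moving average, and it takes no
learning rate by construction. A 1-D quadratic sanity harness checks each
rule reaches |w−a| < 1e−3 within a budget frozen from running the scalar
recursions (SGD 397, RMSProp 3053, Adadelta 985, Adam 6473 iterations
observed; budgets 2000/10000/5000/20000).

## Synthetic corpora

Real registry pathology reports are IRB-restricted, so experiments run on
synthetic corpora that reproduce the dataset's token-level statistics, not
its prose. The default per-class case-count profile is the registry's own
64-class long tail (4415 cases for breast C50 down to 10 for adrenal gland
C74; 22,976 total), scalable by a factor. Each document is an i.i.d. token
mixture: a class-informative keyword with probability 0.3 (20 keywords per
class, disjoint across classes unless an overlap fraction is set to emulate
confusable sites), a numeric literal (decimals and ≥3-digit integers, rate
0.05) to exercise the substitution rules, a never-repeated rare token (rate
0.02) to exercise the RARE mapping, otherwise a background token drawn from
a 1/rank (Zipf-like) law over 500 types. Document lengths are negative
binomial with mean 600 and dispersion 0.2 (variance = μ + 0.2μ²), which
puts ≈99.5% of documents under 1500 tokens, matching the observation that
over 98% of real reports fall under the truncation length.

What the generator does *not* emulate: word order and syntax (tokens are
exchangeable within a document), topical correlation between background
tokens, section structure, and label noise. Passing tests therefore show
that the pipeline, model, gradients and protocol behave correctly on
corpora whose difficulty is controlled by the keyword signal rate — not
that the model reaches any particular accuracy on real clinical text.

## Desk-scale study conditions

Tests and the acceptance script run two named configurations, both small
enough for seconds-to-minutes runtimes on one CPU:

- **Learnable corpus**: the 8 largest registry classes scaled into 50–400
  cases (profile 400/210/177/163/142/104/87/86), mean document length 60,
  default mixture rates. Desk model: 100-token documents, 48-dim
  embeddings, 24 filters per width, 96 hidden units. Trained with 4
  simulated workers, batch 32, 10 epochs.
- **Overfit regime**: 8 balanced classes × 30 documents with keyword signal
  rate 0.05 (high irreducible error), desk model with dropout 0.25, 4
  workers, batch 32, 40 epochs — a small corpus against a comparatively
  large model, trained well past convergence.

A desk run sees roughly an order of magnitude fewer parameter-server
updates than a full-scale training course (hundreds rather than thousands),
so the desk recipe scales the rate-bearing optimizers' learning rate to
3e−3. Adadelta has no learning rate to rescale — its step size is
self-determined — which is precisely why, at this update budget, it
converges in far more updates than Adam or RMSProp. Under these conditions
the package reproduces the qualitative training phenomenology of the
full-scale study: RMSProp and Adam reach their validation-loss minima in
fewer updates than Adadelta, then overfit (validation loss rises while
worker training loss approaches zero), while Adadelta's post-minimum rise
is smaller over the same horizon. These orderings are asserted at fixed
seeds: validation curves at this scale are noisy, and on a minority of
seeds checkpoint noise produces argmin ties or early spurious minima that
break the strict ordering even though the underlying pattern is visible in
the curves.

## Evaluation

Per-class precision, recall and F1 with the zero-division convention
(0 when a denominator vanishes, matching the 0.00 rows reported for classes
that are never predicted correctly); micro-F1 pools decisions (equal to
accuracy for single-label multiclass data) and macro-F1 averages per-class
F1 without weights. Macro averaging includes zero-support classes by
default (equal weight to each class in the class set), with an option to
restrict to supported classes. The confusion matrix is actual × predicted
and can be support-normalized row-wise. Implementations are cross-checked
against scikit-learn in the test suite but do not depend on it.

## Known limitations

- The simulated scheduler models compute cost, not network transport; no
  wall-clock or message-throughput conclusions can be drawn from it.
- Staleness ≤ N−1 holds for equal-speed workers; heterogeneous multipliers
  weaken the bound.
- The gradient check excludes the frozen PAD embedding row (a constant, not
  a parameter) and is run at parameter points with nonzero biases, away
  from rectifier kinks where finite differences are undefined.
- Single-document forward/backward passes are looped, not batched, in
  numpy; the desk scale is sized accordingly.
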