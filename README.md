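# downpourtext

Word-level CNN document classification trained with asynchronous
data-parallel ("downpour") stochastic gradient descent — as a desk-scale,
fully deterministic, testable library.

## The problem

Cancer registries extract structured facts — above all the ICD-O-3 primary
site code (C50 = breast, C61 = prostate, …) — from free-text pathology
reports, historically by hand. A word-level convolutional neural network
can learn this mapping directly from text, but training it on
registry-scale corpora requires distributing the work: workers compute
mini-batch gradients on their shard of the data while a parameter server
applies them with an adaptive optimizer and hands back refreshed weights.
Because workers act on possibly stale weights, the training dynamics — and
how they interact with the choice of optimizer and batch size — become an
object of study in themselves.

This package implements the whole system in plain numpy, with the
asynchrony executed by a deterministic discrete-event scheduler, so that
every protocol property (staleness bounds, update conservation, serial
equivalence) is exactly testable on one CPU. Registry text is
IRB-restricted, so a synthetic-corpus generator reproduces its token-level
statistics: a 64-class long-tail case profile (4415 cases down to 10),
documents almost all under 1500 tokens, class-informative keywords, numeric
literals and rare tokens.

## The model

A document is tokenized (decimals → FLOAT, ≥3-digit integers → LARGEINT,
sub-threshold document-frequency tokens → RARE), truncated/padded to
*n* = 1500 positions and embedded into a document matrix **A** ∈ ℝ^{n×k},
*k* = 300. For each filter width *h* ∈ {3,4,5}, 300 filters compute

    o_i = w · A[i : i+h−1],   c_i = f(o_i + b),   pooled = max_i c_i,

and the 900 pooled features feed a 300-unit hidden layer with dropout 0.5
and a softmax over classes, trained under cross-entropy with max-norm
weight constraints. Gradients are hand-derived (max pooling routes
gradient to the argmax window only; the PAD embedding row is frozen at
zero) and verified against central finite differences. The parameter
server applies updates as w ← w − opt(Δw, θ) with opt one of SGD, RMSProp,
Adadelta, Adam in canonical form.

## Worked example

Generate a learnable 8-class imbalanced corpus and train with 4 simulated
workers:

```
$ downpourtext generate --out corpus.jsonl --n-classes 8 --seed 1
wrote 1369 records over 8 classes to corpus.jsonl

$ downpourtext train --corpus corpus.jsonl --optimizer adadelta \
    --batch-size 32 --workers 4 --epochs 10 --seed 1 --outdir run \
    --embed-dim 48 --filters 24 --hidden 96 --max-len 100
min validation loss 0.6461 at epoch 10.00 (320 updates); max staleness 3
```

The run directory contains a CSV training log (one row per applied update
and per quarter-epoch validation checkpoint) and a JSON manifest of every
configuration value and seed:

```
event_type,version,worker,staleness,loss,epoch_fraction
update,1,0,0,2.0765983761714115,0.03470715835140998
update,2,1,1,2.0782285357413905,0.06941431670281996
...
```

Staleness never exceeds workers−1 (here 3): each worker blocks between
sending gradients and receiving refreshed weights, so at most one update
per other worker can intervene. The same run with `--workers 1` is
bit-identical to a serial training loop.

The same pipeline is available as a library:

```python
from downpourtext import corpus, harness

log, report, best_macro = harness.learnability_run(seed=1, epochs=10)
print(best_macro)            # 0.9936 — validation macro-F1, 8-class corpus
print(report.micro_f1)       # 0.9967
```

Sweeps over optimizers × batch sizes (`downpourtext sweep-optimizers`),
worker counts × batch sizes (`sweep-workers`) and class-stratified k-fold
cross-validation (`crossval`) mirror the three experiment designs of the
full-scale study; each writes per-cell logs, a summary CSV and a manifest.

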