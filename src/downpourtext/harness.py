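"""Experiment harness: optimizer/batch sweeps, worker sweeps, cross-validation.

Reproduces the study's three experiment designs at desk scale on synthetic
corpora: (1) an optimizer x mini-batch-size sweep logging validation loss
every quarter epoch, (2) a worker-count x batch-size sweep recording
applied-update counts and staleness, (3) a class-stratified k-fold
cross-validated evaluation with per-fold and pooled classification reports.
Every run is a pure function of its configuration and seeds; sweep
summaries are pure functions of their training logs.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from downpourtext import downpour, metrics, model, optim, preprocess
from downpourtext.corpus import LabeledCorpus
from downpourtext.downpour import TrainingLog
from downpourtext.model import ModelConfig
from downpourtext.optim import OptimizerSpec

__all__ = [
    "prepare_fold", "sweep_optimizers", "sweep_workers", "crossval", "CrossValResult",
    "desk_optimizer_spec", "learnability_run", "overfit_regime_run",
]


def _as_spec(opt) -> OptimizerSpec:
    return opt if isinstance(opt, OptimizerSpec) else OptimizerSpec(name=opt)


# Desk-scale learning rate for the rate-bearing optimizers.  A desk run has
# roughly an order of magnitude fewer parameter-server updates per training
# course than the full-scale study (hundreds rather than thousands), so the
# canonical 1e-3 rates barely move the weights within the epoch budget; 3e-3
# compensates.  Adadelta has no learning rate to rescale — its update
# magnitude is self-determined — which is exactly why it converges in far
# more updates than the others at this scale.
DESK_LEARNING_RATE = 0.003


def desk_optimizer_spec(name: str) -> OptimizerSpec:
    """Optimizer spec under the desk-scale training recipe."""
    if name in ("adam", "rmsprop", "sgd"):
        return OptimizerSpec(name=name, learning_rate=DESK_LEARNING_RATE)
    return OptimizerSpec(name=name)


def learnability_run(seed: int = 1, epochs: int = 10):
    """End-to-end learnability check on the default learnable synthetic corpus.

    Generates the 8-class imbalanced demo corpus, trains with 4 simulated
    workers under Adam (desk recipe) at batch size 32, and returns the
    training result plus the validation classification report at the final
    checkpoint.  Returns (log, report, best_macro_f1_over_checkpoints).
    """
    from downpourtext.corpus import demo_corpus_config, generate_corpus

    corpus = generate_corpus(demo_corpus_config(seed=seed))
    model_config = model.desk_model_config()
    plan = preprocess.make_splits(corpus, k=10, seed=seed)
    train_docs, val_docs, _, vocab = prepare_fold(corpus, plan, 0, model_config)
    result = downpour.run_training(
        train_docs, val_docs, model_config, desk_optimizer_spec("adam"),
        n_workers=4, batch_size=32, epochs=epochs, seed=seed,
        vocab_size=vocab.size, n_classes=len(corpus.class_set), record_val_f1=True,
    )
    y_true = [d.label_index for d in val_docs]
    y_pred = model.predict_batch(val_docs, result.params, model_config)
    cm = metrics.confusion(y_true, y_pred, list(range(len(corpus.class_set))))
    rep = metrics.report(cm)
    best_macro = max(c.val_macro_f1 for c in result.log.checkpoints)
    return result.log, rep, best_macro


def overfit_regime_run(seed: int = 5, epochs: int = 40):
    """The synthetic overfit regime: a small weak-signal corpus against a
    relatively large model, trained past convergence.

    8 balanced classes of 30 documents, keyword signal rate 0.05 (high
    irreducible error), desk model with dropout 0.25, 4 workers, batch 32.
    Returns {optimizer_name: TrainingLog} for rmsprop, adam and adadelta
    under the desk recipe, from which convergence speed (updates to the
    validation-loss minimum) and post-minimum rise are read off.
    """
    from downpourtext.corpus import CorpusConfig, generate_corpus

    corpus = generate_corpus(CorpusConfig(
        n_classes=8, class_profile=[30] * 8, keyword_signal_rate=0.05,
        rare_token_rate=0.05, mean_doc_length=60.0, seed=seed,
    ))
    model_config = model.desk_model_config(dropout_rate=0.25)
    plan = preprocess.make_splits(corpus, k=10, seed=seed)
    train_docs, val_docs, _, vocab = prepare_fold(corpus, plan, 0, model_config)
    logs: dict[str, TrainingLog] = {}
    for name in ("rmsprop", "adam", "adadelta"):
        result = downpour.run_training(
            train_docs, val_docs, model_config, desk_optimizer_spec(name),
            n_workers=4, batch_size=32, epochs=epochs, seed=seed,
            vocab_size=vocab.size, n_classes=len(corpus.class_set),
        )
        logs[name] = result.log
    return logs


def prepare_fold(
    corpus: LabeledCorpus,
    plan: preprocess.SplitPlan,
    test_fold: int,
    model_config: ModelConfig,
    min_doc_freq: int = 5,
):
    """Encode one cross-validation fold.

    The vocabulary is built from the training portion only (validation and
    test tokens outside it resolve to RARE), so no information from held-out
    records enters preprocessing.  Returns (train, val, test) encoded
    document lists plus the vocabulary.
    """
    train_idx, val_idx = plan.train_val_indices(test_fold)
    test_idx = plan.test_indices(test_fold)
    label_index = {label: i for i, label in enumerate(corpus.class_set)}
    train_corpus = LabeledCorpus(
        records=[corpus.records[i] for i in train_idx], class_set=list(corpus.class_set)
    )
    vocab = preprocess.build_vocabulary(train_corpus, min_doc_freq=min_doc_freq)

    def enc(idx):
        out = []
        for i in idx:
            text, label = corpus.records[i]
            out.append(
                preprocess.encode(
                    preprocess.tokenize(text), vocab, model_config.max_len,
                    label_index=label_index[label],
                )
            )
        return out

    return enc(train_idx), enc(val_idx), enc(test_idx), vocab


def _summarize(log: TrainingLog) -> dict:
    best = log.argmin_checkpoint()
    return {
        "n_updates": log.n_updates(),
        "min_val_loss": log.min_val_loss(),
        "argmin_epoch_fraction": best.epoch_fraction,
        "argmin_updates": best.version,
        "max_staleness": log.max_staleness(),
    }


def sweep_optimizers(
    corpus: LabeledCorpus,
    model_config: ModelConfig,
    optimizers=("adadelta", "adam", "rmsprop", "sgd"),
    batch_sizes=(16, 32, 64, 128, 256),
    n_workers: int = 16,
    epochs: int = 25,
    k: int = 10,
    seed: int = 0,
    min_doc_freq: int = 5,
    outdir=None,
) -> tuple[pd.DataFrame, dict]:
    """Train one fold per (optimizer, batch size) cell and summarize each
    cell's validation-loss curve.  Cell failures are recorded and the sweep
    continues.  Returns the summary table and the per-cell training logs."""
    plan = preprocess.make_splits(corpus, k=k, seed=seed)
    train_docs, val_docs, _, vocab = prepare_fold(corpus, plan, 0, model_config, min_doc_freq)
    rows = []
    logs: dict[tuple[str, int], TrainingLog] = {}
    for opt in optimizers:
        spec = _as_spec(opt)
        for batch in batch_sizes:
            row = {"optimizer": spec.name, "batch_size": batch, "error": ""}
            try:
                result = downpour.run_training(
                    train_docs, val_docs, model_config, spec,
                    n_workers=n_workers, batch_size=batch, epochs=epochs,
                    seed=seed, vocab_size=vocab.size, n_classes=len(corpus.class_set),
                )
                row.update(_summarize(result.log))
                logs[(spec.name, batch)] = result.log
            except Exception as exc:  # cell failure must not abort the sweep
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if outdir is not None:
        _write_outputs(outdir, "sweep_optimizers", table, logs, {
            "optimizers": [_as_spec(o).name for o in optimizers],
            "thetas": {_as_spec(o).name: _as_spec(o).theta() for o in optimizers},
            "batch_sizes": list(batch_sizes), "n_workers": n_workers,
            "epochs": epochs, "k": k, "seed": seed, "min_doc_freq": min_doc_freq,
        })
    return table, logs


def sweep_workers(
    corpus: LabeledCorpus,
    model_config: ModelConfig,
    optimizer="adam",
    worker_counts=(4, 8, 16, 32),
    batch_sizes=(16, 32, 64, 128, 256),
    epochs: int = 10,
    k: int = 10,
    seed: int = 0,
    min_doc_freq: int = 5,
    outdir=None,
) -> tuple[pd.DataFrame, dict]:
    """Train one fold per (worker count, batch size) cell, recording update
    counts, staleness histograms and the minimum validation loss."""
    spec = _as_spec(optimizer)
    plan = preprocess.make_splits(corpus, k=k, seed=seed)
    train_docs, val_docs, _, vocab = prepare_fold(corpus, plan, 0, model_config, min_doc_freq)
    rows = []
    logs: dict[tuple[int, int], TrainingLog] = {}
    for n_workers in worker_counts:
        for batch in batch_sizes:
            row = {"n_workers": n_workers, "batch_size": batch, "error": ""}
            try:
                result = downpour.run_training(
                    train_docs, val_docs, model_config, spec,
                    n_workers=n_workers, batch_size=batch, epochs=epochs,
                    seed=seed, vocab_size=vocab.size, n_classes=len(corpus.class_set),
                )
                row.update(_summarize(result.log))
                row["staleness_histogram"] = json.dumps(result.log.staleness_histogram())
                logs[(n_workers, batch)] = result.log
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if outdir is not None:
        _write_outputs(outdir, "sweep_workers", table, logs, {
            "optimizer": spec.name, "theta": spec.theta(),
            "worker_counts": list(worker_counts), "batch_sizes": list(batch_sizes),
            "epochs": epochs, "k": k, "seed": seed, "min_doc_freq": min_doc_freq,
        })
    return table, logs


@dataclass
class CrossValResult:
    fold_reports: list[metrics.ClassReport]
    fold_matrices: list[metrics.ConfusionMatrix]
    pooled_matrix: metrics.ConfusionMatrix
    pooled_report: metrics.ClassReport
    manifest: dict = field(default_factory=dict)


def crossval(
    corpus: LabeledCorpus,
    model_config: ModelConfig,
    optimizer="adadelta",
    k: int = 10,
    n_workers: int = 16,
    batch_size: int = 64,
    epochs: int = 10,
    seed: int = 0,
    min_cases: int = 10,
    min_doc_freq: int = 5,
    outdir=None,
) -> CrossValResult:
    """Class-stratified k-fold cross-validation of the full pipeline.

    Classes below ``min_cases`` are removed before splitting (the error for
    a class smaller than k therefore fires before any training).  Each fold
    trains on the remaining k-1 folds (minus the 25% validation portion)
    and is scored on its held-out test fold; the pooled confusion matrix is
    the sum of fold matrices.
    """
    spec = _as_spec(optimizer)
    filtered = preprocess.filter_classes(corpus, min_cases=min_cases)
    plan = preprocess.make_splits(filtered, k=k, seed=seed)
    class_set = list(filtered.class_set)
    fold_reports: list[metrics.ClassReport] = []
    fold_matrices: list[metrics.ConfusionMatrix] = []
    for fold in range(k):
        train_docs, val_docs, test_docs, vocab = prepare_fold(
            filtered, plan, fold, model_config, min_doc_freq
        )
        result = downpour.run_training(
            train_docs, val_docs, model_config, spec,
            n_workers=n_workers, batch_size=batch_size, epochs=epochs,
            seed=seed + fold, vocab_size=vocab.size, n_classes=len(class_set),
        )
        y_true = [d.label_index for d in test_docs]
        y_pred = model.predict_batch(test_docs, result.params, model_config)
        cm = metrics.confusion(y_true, y_pred, list(range(len(class_set))))
        cm.class_set = class_set
        fold_matrices.append(cm)
        fold_reports.append(metrics.report(cm))
    pooled = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled = pooled + cm
    pooled_report = metrics.report(pooled)
    manifest = {
        "optimizer": spec.name, "theta": spec.theta(), "k": k,
        "n_workers": n_workers, "batch_size": batch_size, "epochs": epochs,
        "seed": seed, "min_cases": min_cases, "min_doc_freq": min_doc_freq,
        "classes": class_set,
    }
    result_obj = CrossValResult(
        fold_reports=fold_reports, fold_matrices=fold_matrices,
        pooled_matrix=pooled, pooled_report=pooled_report, manifest=manifest,
    )
    if outdir is not None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pooled_report.write_csv(outdir / "crossval_pooled_report.csv")
        pd.DataFrame(pooled.counts, index=class_set, columns=class_set).to_csv(
            outdir / "crossval_pooled_confusion.csv"
        )
        with open(outdir / "crossval_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result_obj


def _write_outputs(outdir, stem: str, table: pd.DataFrame, logs: dict, manifest: dict) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / f"{stem}_summary.csv", index=False)
    for key, log in logs.items():
        tag = "_".join(str(part) for part in key)
        log.write_csv(outdir / f"{stem}_{tag}_log.csv")
    with open(outdir / f"{stem}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
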