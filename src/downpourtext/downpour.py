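"""Asynchronous data-parallel (downpour) training with a parameter server.

The training set is partitioned into N worker shards of near-equal size.
Each worker repeatedly draws a mini-batch (without replacement within its
local epoch), computes mean cross-entropy gradients on its *current* local
weights, and sends them to the parameter server together with the server
version those weights derive from.  The server applies each incoming
gradient packet with the configured optimizer rule, w <- w + opt_delta,
enforces the max-norm constraints, bumps its version, and replies to the
sending worker with the refreshed weights.  A worker blocks between send
and reply — at most one update in flight per worker — which bounds gradient
staleness by N-1 when workers progress at comparable speeds.  Weights that
arrive while a mini-batch is in progress are applied only after that
batch's gradients are computed (deferred local application).

Asynchrony is executed by a deterministic discrete-event scheduler: each
batch costs event-time proportional to its case count divided by the
worker's speed multiplier, and simultaneous completions break ties by
worker id.  The same protocol could run over real message passing; only
the simulated transport is provided here.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from downpourtext import metrics as metrics_mod
from downpourtext import model as model_mod
from downpourtext import optim as optim_mod
from downpourtext.model import ModelConfig, ModelParams
from downpourtext.preprocess import EncodedDocument

__all__ = [
    "partition", "WorkerState", "UpdateMessage", "ParameterServerState",
    "worker_compute", "server_apply", "UpdateEvent", "Checkpoint",
    "TrainingLog", "TrainingResult", "run_training", "worker_rng",
]

# Worker-local RNG streams (epoch shuffles and dropout masks) are spawned
# from (seed, _WORKER_STREAM, worker_id); the constant keeps them disjoint
# from other seeded streams in the package.
_WORKER_STREAM = 7919


def worker_rng(seed: int, worker_id: int) -> np.random.Generator:
    return np.random.default_rng([seed, _WORKER_STREAM, worker_id])


def partition(M: int, N: int, seed: int = 0) -> list[np.ndarray]:
    """Split indices 0..M-1 into N disjoint shards whose sizes differ by <= 1,
    after a seeded shuffle.  Larger shards land on the lowest worker ids."""
    if N < 1:
        raise ValueError("need at least one worker")
    if M < N:
        raise ValueError(f"cannot partition {M} cases over {N} workers")
    perm = np.random.default_rng([seed, 31337]).permutation(M)
    base, extra = divmod(M, N)
    shards = []
    start = 0
    for n in range(N):
        size = base + (1 if n < extra else 0)
        shards.append(np.sort(perm[start: start + size]))
        start += size
    return shards


@dataclass
class UpdateMessage:
    """A worker's gradient packet and the server version it was computed against."""

    worker_id: int
    gradients: dict[str, np.ndarray]
    basis_version: int
    batch_size: int
    batch_loss: float = float("nan")


@dataclass
class WorkerState:
    """A worker's shard, local weights, batch cursor and deferred-refresh slot."""

    worker_id: int
    shard: np.ndarray
    local_params: ModelParams
    basis_version: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    speed: float = 1.0
    epoch_order: np.ndarray | None = None
    cursor: int = 0
    epochs_done: int = 0
    pending_params: ModelParams | None = None
    pending_version: int = -1

    def next_batch_size(self, batch_size: int) -> int:
        remaining = len(self.shard) - self.cursor
        if remaining == 0:
            remaining = len(self.shard)
        return min(batch_size, remaining)

    def batch_cost(self) -> float:
        """Event-time cost of one mini-batch: constant per batch, scaled by
        the worker's speed multiplier.  Constant cost keeps equal-speed
        workers in lockstep rounds, which is what bounds staleness by N-1;
        heterogeneous hardware is modeled through ``speed``, at the price of
        a weaker (but still finite) staleness bound."""
        return 1.0 / self.speed

    def receive_weights(self, params: ModelParams, version: int, defer: bool = False) -> None:
        """Install refreshed server weights; ``defer=True`` queues them to be
        applied only after the in-progress mini-batch (mid-batch arrival)."""
        if defer:
            self.pending_params = params.copy()
            self.pending_version = version
        else:
            self.local_params = params.copy()
            self.basis_version = version


def worker_compute(
    worker: WorkerState,
    train_docs: list[EncodedDocument],
    config: ModelConfig,
    batch_size: int,
) -> UpdateMessage:
    """Compute mean gradients for the worker's next mini-batch.

    The batch is drawn without replacement within the worker's local epoch
    (shard reshuffled per epoch from the worker's own rng; a final short
    batch is allowed).  Gradients use the worker's CURRENT local weights;
    any pending server refresh is applied only afterwards.
    """
    if len(worker.shard) == 0:
        raise ValueError(f"worker {worker.worker_id} has an empty shard")
    if worker.cursor == 0:
        worker.epoch_order = worker.rng.permutation(worker.shard)
    assert worker.epoch_order is not None
    batch_idx = worker.epoch_order[worker.cursor: worker.cursor + batch_size]
    worker.cursor += len(batch_idx)
    docs = [train_docs[i] for i in batch_idx]
    loss, grads = model_mod.batch_gradients(
        docs, worker.local_params, config, rng=worker.rng, train=True
    )
    msg = UpdateMessage(
        worker_id=worker.worker_id,
        gradients=grads,
        basis_version=worker.basis_version,
        batch_size=len(docs),
        batch_loss=loss,
    )
    if worker.pending_params is not None:  # deferred local application
        worker.local_params = worker.pending_params
        worker.basis_version = worker.pending_version
        worker.pending_params = None
        worker.pending_version = -1
    if worker.cursor >= len(worker.shard):
        worker.cursor = 0
        worker.epochs_done += 1
    return msg


@dataclass
class ParameterServerState:
    """Authoritative versioned weights plus the optimizer accumulators."""

    params: ModelParams
    spec: optim_mod.OptimizerSpec
    opt_state: optim_mod.OptimizerState
    version: int = 0
    norm_cap: float | None = None
    last_applied: dict[int, int] = field(default_factory=dict)

    @classmethod
    def create(
        cls,
        params: ModelParams,
        spec: optim_mod.OptimizerSpec,
        norm_cap: float | None = None,
    ) -> "ParameterServerState":
        return cls(
            params=params.copy(),
            spec=spec,
            opt_state=optim_mod.init_state(spec, params.tensors),
            norm_cap=norm_cap,
        )


def server_apply(
    server: ParameterServerState, msg: UpdateMessage
) -> tuple[ModelParams, int]:
    """Apply one gradient packet: optimizer step, norm constraints, version bump.

    Returns the refreshed weights (a copy, for dispatch to the sending
    worker) and the packet's staleness, current version minus basis version.
    """
    for key, g in msg.gradients.items():
        if g.shape != server.params.tensors[key].shape:
            raise ValueError(f"gradient shape mismatch for tensor {key!r}")
    staleness = server.version - msg.basis_version
    if staleness < 0:
        raise ValueError("message basis_version exceeds server version")
    deltas = optim_mod.step(server.spec, server.opt_state, msg.gradients)
    for key, d in deltas.items():
        server.params.tensors[key] += d
    if server.norm_cap is not None:
        model_mod.apply_norm_constraints(server.params, server.norm_cap)
    server.version += 1
    server.last_applied[msg.worker_id] = server.version
    return server.params.copy(), staleness


@dataclass
class UpdateEvent:
    version: int
    worker_id: int
    staleness: int
    batch_loss: float
    epoch_fraction: float


@dataclass
class Checkpoint:
    epoch_fraction: float
    version: int
    val_loss: float
    val_macro_f1: float = float("nan")


@dataclass
class TrainingLog:
    """Applied-update events and quarter-epoch validation checkpoints."""

    updates: list[UpdateEvent] = field(default_factory=list)
    checkpoints: list[Checkpoint] = field(default_factory=list)

    def max_staleness(self) -> int:
        return max((u.staleness for u in self.updates), default=0)

    def staleness_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for u in self.updates:
            hist[u.staleness] = hist.get(u.staleness, 0) + 1
        return dict(sorted(hist.items()))

    def n_updates(self) -> int:
        return len(self.updates)

    def min_val_loss(self) -> float:
        return min(c.val_loss for c in self.checkpoints)

    def argmin_checkpoint(self) -> Checkpoint:
        """The checkpoint attaining the minimum validation loss (first on ties)."""
        best = min(range(len(self.checkpoints)), key=lambda i: self.checkpoints[i].val_loss)
        return self.checkpoints[best]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "event_type": "update", "version": u.version, "worker": u.worker_id,
                "staleness": u.staleness, "loss": u.batch_loss,
                "epoch_fraction": u.epoch_fraction,
            }
            for u in self.updates
        ] + [
            {
                "event_type": "validation", "version": c.version, "worker": -1,
                "staleness": -1, "loss": c.val_loss, "epoch_fraction": c.epoch_fraction,
            }
            for c in self.checkpoints
        ]
        return pd.DataFrame(rows).sort_values(["version", "event_type"]).reset_index(drop=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class TrainingResult:
    log: TrainingLog
    params: ModelParams


def _validation_metrics(
    val_docs: list[EncodedDocument],
    params: ModelParams,
    config: ModelConfig,
    n_classes: int,
    with_f1: bool,
) -> tuple[float, float]:
    total = 0.0
    preds = np.empty(len(val_docs), dtype=np.int64)
    for i, doc in enumerate(val_docs):
        cache = model_mod.forward(doc, params, config)
        total += model_mod.loss(cache.probs, doc.label_index)
        preds[i] = int(np.argmax(cache.probs))
    val_loss = total / len(val_docs)
    if not with_f1:
        return val_loss, float("nan")
    y_true = np.array([d.label_index for d in val_docs])
    cm = metrics_mod.confusion(y_true, preds, list(range(n_classes)))
    return val_loss, metrics_mod.report(cm).macro_f1


def run_training(
    train_docs: list[EncodedDocument],
    val_docs: list[EncodedDocument],
    model_config: ModelConfig,
    optimizer_spec: optim_mod.OptimizerSpec,
    n_workers: int,
    batch_size: int,
    epochs: int,
    seed: int = 0,
    *,
    params: ModelParams | None = None,
    vocab_size: int | None = None,
    n_classes: int | None = None,
    speed_multipliers: list[float] | None = None,
    transport: str = "simulated",
    record_val_f1: bool = False,
) -> TrainingResult:
    """Run asynchronous downpour training under the simulated scheduler.

    One epoch is the aggregate consumption of ``len(train_docs)`` cases
    across workers; validation loss (and optionally macro-F1) is evaluated
    on the server's current weights every quarter epoch, giving exactly
    ``4 * epochs`` checkpoints.  The run stops once every worker has
    completed ``epochs`` local epochs over its shard.  Fully deterministic
    in (seed, configuration).
    """
    if transport != "simulated":
        raise NotImplementedError(
            f"transport {transport!r} not available; only 'simulated' is implemented"
        )
    if batch_size < 1 or epochs < 1:
        raise ValueError("batch_size and epochs must be positive")
    if not train_docs or not val_docs:
        raise ValueError("need non-empty training and validation sets")
    if n_classes is None:
        n_classes = max(d.label_index for d in [*train_docs, *val_docs]) + 1
    if params is None:
        if vocab_size is None:
            raise ValueError("pass initial params or a vocab_size to initialize from")
        params = model_mod.init_params(model_config, vocab_size, n_classes, seed=seed)
    speeds = speed_multipliers if speed_multipliers is not None else [1.0] * n_workers
    if len(speeds) != n_workers or any(s <= 0 for s in speeds):
        raise ValueError("speed_multipliers must give one positive factor per worker")

    M = len(train_docs)
    shards = partition(M, n_workers, seed)
    server = ParameterServerState.create(params, optimizer_spec, model_config.norm_cap)
    workers = [
        WorkerState(
            worker_id=n,
            shard=shards[n],
            local_params=server.params.copy(),
            basis_version=0,
            rng=worker_rng(seed, n),
            speed=speeds[n],
        )
        for n in range(n_workers)
    ]

    log = TrainingLog()
    heap: list[tuple[float, int]] = []
    for w in workers:
        heapq.heappush(heap, (w.batch_cost(), w.worker_id))

    consumed = 0
    n_checkpoints = 4 * epochs
    checkpoints_done = 0
    while heap:
        t, wid = heapq.heappop(heap)
        worker = workers[wid]
        msg = worker_compute(worker, train_docs, model_config, batch_size)
        fresh, staleness = server_apply(server, msg)
        consumed += msg.batch_size
        log.updates.append(
            UpdateEvent(
                version=server.version, worker_id=wid, staleness=staleness,
                batch_loss=msg.batch_loss, epoch_fraction=consumed / M,
            )
        )
        worker.receive_weights(fresh, server.version)
        while (
            checkpoints_done < n_checkpoints
            and consumed >= M * (checkpoints_done + 1) / 4 - 1e-9
        ):
            val_loss, macro = _validation_metrics(
                val_docs, server.params, model_config, n_classes, record_val_f1
            )
            checkpoints_done += 1
            log.checkpoints.append(
                Checkpoint(
                    epoch_fraction=checkpoints_done / 4,
                    version=server.version,
                    val_loss=val_loss,
                    val_macro_f1=macro,
                )
            )
        if worker.epochs_done < epochs:
            heapq.heappush(heap, (t + worker.batch_cost(), wid))
    return TrainingResult(log=log, params=server.params)
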