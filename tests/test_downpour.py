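"""Asynchronous training protocol: partitioning, staleness, serial equivalence."""

import numpy as np
import pytest

from downpourtext import downpour, model, optim
from downpourtext.model import ModelParams


class TestPartition:
    def test_sizes_differ_by_at_most_one(self):
        shards = downpour.partition(10, 3, seed=0)
        assert sorted(len(s) for s in shards) == [3, 3, 4]

    def test_single_worker_gets_everything(self):
        shards = downpour.partition(7, 1, seed=0)
        assert (np.sort(shards[0]) == np.arange(7)).all()

    def test_disjoint_and_exhaustive(self):
        shards = downpour.partition(53, 4, seed=9)
        merged = np.sort(np.concatenate(shards))
        assert (merged == np.arange(53)).all()

    def test_more_workers_than_cases_rejected(self):
        with pytest.raises(ValueError):
            downpour.partition(2, 3)

    def test_seed_changes_assignment(self):
        a = downpour.partition(20, 2, seed=0)
        b = downpour.partition(20, 2, seed=1)
        assert not all((x == y).all() for x, y in zip(a, b))


class TestWorkerCompute:
    def _worker(self, setup, shard_size=10, seed=0):
        config, params, docs, _, _ = setup
        shard = np.arange(shard_size)
        return downpour.WorkerState(
            worker_id=0, shard=shard, local_params=params.copy(),
            rng=downpour.worker_rng(seed, 0),
        ), config, docs

    def test_epoch_batch_sizes(self, tiny_model_setup):
        worker, config, docs = self._worker(tiny_model_setup, shard_size=10)
        sizes = [downpour.worker_compute(worker, docs, config, 4).batch_size for _ in range(3)]
        assert sizes == [4, 4, 2]
        assert worker.epochs_done == 1

    def test_gradients_match_direct_recomputation(self, tiny_model_setup):
        worker, config, docs = self._worker(tiny_model_setup, shard_size=8)
        # replicate the worker's batch draw with the same rng stream
        rng = downpour.worker_rng(0, 0)
        order = rng.permutation(np.arange(8))
        expected_docs = [docs[i] for i in order[:4]]
        msg = downpour.worker_compute(worker, docs, config, 4)
        _, expected = model.batch_gradients(expected_docs, worker.local_params, config,
                                            rng=rng, train=True)
        for key in expected:
            assert np.allclose(msg.gradients[key], expected[key])

    def test_pending_weights_applied_only_after_batch(self, tiny_model_setup):
        config, params, docs, vocab_size, n_classes = tiny_model_setup
        worker, config, docs = self._worker(tiny_model_setup, shard_size=6)
        old_weights = worker.local_params.copy()
        refreshed = params.copy()
        for key in refreshed.tensors:
            refreshed.tensors[key] = refreshed.tensors[key] + 0.1
        worker.receive_weights(refreshed, version=5, defer=True)
        msg = downpour.worker_compute(worker, docs, config, 3)
        # gradients reflect the PRE-refresh weights
        rng = downpour.worker_rng(0, 0)
        order = rng.permutation(np.arange(6))
        _, expected = model.batch_gradients([docs[i] for i in order[:3]], old_weights,
                                            config, rng=rng, train=True)
        for key in expected:
            assert np.allclose(msg.gradients[key], expected[key])
        assert msg.basis_version == 0
        # and the refresh has now been installed for the next batch
        assert worker.basis_version == 5
        assert (worker.local_params["out_b"] == refreshed["out_b"]).all()

    def test_empty_shard_rejected(self, tiny_model_setup):
        config, params, docs, _, _ = tiny_model_setup
        worker = downpour.WorkerState(worker_id=0, shard=np.array([], dtype=int),
                                      local_params=params.copy())
        with pytest.raises(ValueError):
            downpour.worker_compute(worker, docs, config, 4)


class TestServerApply:
    def _scalar_server(self, spec):
        params = ModelParams(tensors={"w": np.array([1.0])}, vocab_size=1, n_classes=2)
        return downpour.ParameterServerState.create(params, spec, norm_cap=None)

    def test_sgd_scalar_closed_form_and_version(self):
        server = self._scalar_server(optim.OptimizerSpec("sgd", learning_rate=0.1))
        msg = downpour.UpdateMessage(worker_id=0, gradients={"w": np.array([2.0])},
                                     basis_version=0, batch_size=4)
        fresh, staleness = downpour.server_apply(server, msg)
        assert np.isclose(fresh["w"][0], 0.8)
        assert server.version == 1 and staleness == 0

    def test_staleness_is_version_minus_basis(self):
        server = self._scalar_server(optim.OptimizerSpec("sgd"))
        for expected_staleness in (0, 1, 2):
            msg = downpour.UpdateMessage(worker_id=0, gradients={"w": np.array([0.5])},
                                         basis_version=0, batch_size=1)
            _, staleness = downpour.server_apply(server, msg)
            assert staleness == expected_staleness

    def test_two_workers_bump_version_twice(self):
        server = self._scalar_server(optim.OptimizerSpec("sgd"))
        for wid in (0, 1):
            msg = downpour.UpdateMessage(worker_id=wid, gradients={"w": np.array([1.0])},
                                         basis_version=0, batch_size=1)
            downpour.server_apply(server, msg)
        assert server.version == 2
        assert server.last_applied == {0: 1, 1: 2}

    def test_shape_mismatch_rejected(self):
        server = self._scalar_server(optim.OptimizerSpec("sgd"))
        msg = downpour.UpdateMessage(worker_id=0, gradients={"w": np.zeros(3)},
                                     basis_version=0, batch_size=1)
        with pytest.raises(ValueError):
            downpour.server_apply(server, msg)


def _serial_reference(train_docs, config, spec, batch_size, epochs, seed, vocab_size, n_classes):
    """Independent serial loop: same seeding contract, no scheduler/server."""
    params = model.init_params(config, vocab_size, n_classes, seed=seed)
    shard = downpour.partition(len(train_docs), 1, seed)[0]
    rng = downpour.worker_rng(seed, 0)
    state = optim.init_state(spec, params.tensors)
    for _ in range(epochs):
        order = rng.permutation(shard)
        for start in range(0, len(order), batch_size):
            batch = [train_docs[i] for i in order[start: start + batch_size]]
            _, grads = model.batch_gradients(batch, params, config, rng=rng, train=True)
            for key, d in optim.step(spec, state, grads).items():
                params.tensors[key] += d
            model.apply_norm_constraints(params, config.norm_cap)
    return params


class TestRunTraining:
    @pytest.mark.parametrize("name", optim.OPTIMIZER_NAMES)
    def test_single_worker_bit_identical_to_serial_loop(self, tiny_model_setup, name):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        spec = optim.OptimizerSpec(name)
        result = downpour.run_training(
            docs[:8], docs[8:], config, spec, n_workers=1, batch_size=3,
            epochs=2, seed=13, vocab_size=vocab_size, n_classes=n_classes,
        )
        serial = _serial_reference(docs[:8], config, spec, 3, 2, 13, vocab_size, n_classes)
        for key in serial.tensors:
            assert (result.params[key] == serial[key]).all(), key

    def test_staleness_bounded_by_worker_count(self, tiny_model_setup):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        result = downpour.run_training(
            docs[:10], docs[10:], config, optim.OptimizerSpec("sgd"), n_workers=3,
            batch_size=2, epochs=3, seed=0, vocab_size=vocab_size, n_classes=n_classes,
        )
        assert result.log.max_staleness() <= 2
        assert result.log.n_updates() > 0

    def test_update_count_conservation(self, tiny_model_setup):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        n_workers, batch, epochs = 3, 4, 2
        result = downpour.run_training(
            docs[:10], docs[10:], config, optim.OptimizerSpec("sgd"),
            n_workers=n_workers, batch_size=batch, epochs=epochs, seed=1,
            vocab_size=vocab_size, n_classes=n_classes,
        )
        shards = downpour.partition(10, n_workers, seed=1)
        expected = epochs * sum(-(-len(s) // batch) for s in shards)
        assert result.log.n_updates() == expected

    def test_quarter_epoch_checkpoints(self, tiny_model_setup):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        result = downpour.run_training(
            docs[:8], docs[8:], config, optim.OptimizerSpec("sgd"), n_workers=2,
            batch_size=2, epochs=2, seed=0, vocab_size=vocab_size, n_classes=n_classes,
        )
        assert len(result.log.checkpoints) == 8
        assert [c.epoch_fraction for c in result.log.checkpoints] == [
            0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0
        ]
        versions = [c.version for c in result.log.checkpoints]
        assert versions == sorted(versions)

    def test_reproducible_under_seed(self, tiny_model_setup):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        kwargs = dict(n_workers=2, batch_size=3, epochs=1, seed=21,
                      vocab_size=vocab_size, n_classes=n_classes)
        a = downpour.run_training(docs[:9], docs[9:], config,
                                  optim.OptimizerSpec("adam"), **kwargs)
        b = downpour.run_training(docs[:9], docs[9:], config,
                                  optim.OptimizerSpec("adam"), **kwargs)
        for key in a.params.tensors:
            assert (a.params[key] == b.params[key]).all()
        assert [u.staleness for u in a.log.updates] == [u.staleness for u in b.log.updates]

    def test_unimplemented_transport_rejected(self, tiny_model_setup):
        config, _, docs, vocab_size, n_classes = tiny_model_setup
        with pytest.raises(NotImplementedError):
            downpour.run_training(
                docs[:8], docs[8:], config, optim.OptimizerSpec("sgd"), n_workers=1,
                batch_size=2, epochs=1, vocab_size=vocab_size, n_classes=n_classes,
                transport="mpi",
            )

    def test_log_csv_round_trip(self, tiny_model_setup, tmp_path):
        import pandas as pd

        config, _, docs, vocab_size, n_classes = tiny_model_setup
        result = downpour.run_training(
            docs[:8], docs[8:], config, optim.OptimizerSpec("sgd"), n_workers=2,
            batch_size=4, epochs=1, seed=0, vocab_size=vocab_size, n_classes=n_classes,
        )
        path = tmp_path / "log.csv"
        result.log.write_csv(path)
        frame = pd.read_csv(path)
        assert set(frame["event_type"]) == {"update", "validation"}
        assert (frame["version"].diff().dropna() >= 0).all()
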