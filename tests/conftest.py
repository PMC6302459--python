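import numpy as np
import pytest

from downpourtext import corpus, harness, model, preprocess


@pytest.fixture(scope="session")
def tiny_corpus() -> corpus.LabeledCorpus:
    """Two balanced, cleanly separable classes; small enough for exact oracles."""
    config = corpus.CorpusConfig(
        n_classes=2,
        class_profile=[50, 50],
        vocab_size_informative=10,
        background_vocab_size=60,
        mean_doc_length=30.0,
        keyword_signal_rate=0.3,
        seed=11,
    )
    return corpus.generate_corpus(config)


@pytest.fixture(scope="session")
def tiny_model_setup():
    """A deliberately small architecture for gradient and protocol tests."""
    config = model.ModelConfig(
        embed_dim=4,
        filter_widths=(2, 3),
        filters_per_width=2,
        hidden_units=5,
        dropout_rate=0.0,
        max_len=12,
        norm_cap=3.0,
    )
    vocab_size, n_classes = 20, 3
    params = model.init_params(config, vocab_size, n_classes, seed=3)
    # generic nonzero biases keep preactivations away from the rectifier kink,
    # where finite-difference checks are undefined
    rng = np.random.default_rng(7)
    for key in ("conv2_b", "conv3_b", "hidden_b", "out_b"):
        params.tensors[key] = rng.uniform(-0.3, 0.3, size=params.tensors[key].shape)
    docs = []
    for _ in range(12):
        true_len = int(rng.integers(3, config.max_len + 1))
        idx = np.zeros(config.max_len, dtype=np.int64)
        idx[:true_len] = rng.integers(1, vocab_size, size=true_len)
        docs.append(
            preprocess.EncodedDocument(
                indices=idx, true_length=true_len,
                label_index=int(rng.integers(n_classes)),
            )
        )
    return config, params, docs, vocab_size, n_classes


@pytest.fixture(scope="session")
def learnable_dataset(tiny_corpus):
    """Encoded train/validation docs from the separable two-class corpus."""
    config = model.ModelConfig(
        embed_dim=8, filter_widths=(2, 3), filters_per_width=4,
        hidden_units=12, dropout_rate=0.5, max_len=40,
    )
    plan = preprocess.make_splits(tiny_corpus, k=5, seed=11)
    train, val, test, vocab = harness.prepare_fold(tiny_corpus, plan, 0, config, min_doc_freq=2)
    return config, train, val, test, vocab
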