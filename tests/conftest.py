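"""Shared fixtures.

The two session-scoped benchmark runs (full signal, zero signal) each train
the default convolutional model once on the default synthetic benchmark;
several evaluation and acceptance tests reuse them so the suite trains the
expensive model exactly twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from poreformer import (
    EncodingConfig,
    ModelConfig,
    SplitSpec,
    SyntheticConfig,
    build_model,
    encode_batch,
    make_benchmark,
    split_dataset,
    stack_tensors,
    train,
)

BENCHMARK_SEED = 0
BENCH_PAD_LENGTH = 400


@dataclass
class BenchmarkRun:
    """One end-to-end run: data, split, trained model, held-out scores."""

    signal_strength: float
    dataset: object
    holdout: list
    train_records: list
    test_records: list
    encoding: EncodingConfig
    model_config: ModelConfig
    classifier: object
    history: object
    test_labels: np.ndarray
    test_scores: np.ndarray


def _run_benchmark(signal_strength: float) -> BenchmarkRun:
    config = SyntheticConfig(seed=BENCHMARK_SEED, signal_strength=signal_strength)
    dataset, holdout, _ = make_benchmark(config)
    records = dataset.positives + dataset.negatives
    encoding = EncodingConfig(scheme="combined", pad_length=BENCH_PAD_LENGTH)
    train_recs, test_recs = split_dataset(records, SplitSpec(seed=BENCHMARK_SEED))
    train_t, train_y = encode_batch(train_recs, encoding)
    test_t, test_y = encode_batch(test_recs, encoding)
    x_train, x_test = stack_tensors(train_t), stack_tensors(test_t)
    model_config = ModelConfig(seed=BENCHMARK_SEED)
    classifier = build_model(model_config, x_train.shape[1:], scheme="combined")
    classifier, history = train(classifier, x_train, train_y, x_test, test_y,
                                model_config)
    return BenchmarkRun(
        signal_strength=signal_strength,
        dataset=dataset,
        holdout=holdout,
        train_records=train_recs,
        test_records=test_recs,
        encoding=encoding,
        model_config=model_config,
        classifier=classifier,
        history=history,
        test_labels=test_y,
        test_scores=classifier.predict(x_test),
    )


@pytest.fixture(scope="session")
def full_signal_run() -> BenchmarkRun:
    """Default benchmark at signal_strength = 1, trained once per session."""
    return _run_benchmark(1.0)


@pytest.fixture(scope="session")
def null_signal_run() -> BenchmarkRun:
    """Default benchmark at signal_strength = 0 (no learnable signal)."""
    return _run_benchmark(0.0)
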