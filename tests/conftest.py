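"""Shared fixtures: one ensemble trained on the default synthetic benchmark.

Training the three-classifier ensemble takes tens of seconds, so the
benchmark model (100 windows per gesture, fixed seed) is session-scoped and
shared by the classifier, closed-loop and acceptance tests.
"""

import pytest

from emglove import generate_dataset, train_ensemble

BENCH_TRAIN_SEED = 11
BENCH_EVAL_SEED = 1234
BENCH_N_PER_GESTURE = 100


@pytest.fixture(scope="session")
def bench_data():
    return generate_dataset(BENCH_N_PER_GESTURE, seed=BENCH_TRAIN_SEED)


@pytest.fixture(scope="session")
def bench_model(bench_data):
    X, y = bench_data
    return train_ensemble(X, y, seed=BENCH_TRAIN_SEED)


@pytest.fixture(scope="session")
def bench_eval_data():
    return generate_dataset(BENCH_N_PER_GESTURE, seed=BENCH_EVAL_SEED)
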