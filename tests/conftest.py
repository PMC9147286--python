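"""Shared fixtures: the seeded desk-scale benchmark and trained models.

Training the three counters dominates suite runtime, so the seed-0
benchmark models are session-scoped and shared between the unit tests
and the acceptance-style end-to-end checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from weakcount.benchmark import (
    BenchmarkData,
    make_benchmark,
    train_benchmark_countseg,
    train_benchmark_scount,
    train_benchmark_wscount,
)

logging.getLogger("weakcount").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bench() -> BenchmarkData:
    return make_benchmark(seed=0)


@pytest.fixture(scope="session")
def scount_model(bench):
    return train_benchmark_scount(bench, seed=0)


@pytest.fixture(scope="session")
def countseg_model(bench):
    return train_benchmark_countseg(bench, seed=0)


@pytest.fixture(scope="session")
def wscount_model(bench):
    return train_benchmark_wscount(bench, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
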