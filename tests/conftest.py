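"""Shared fixtures: deterministic RNGs and synthetic communities.

The small community keeps unit tests fast; the default community (the
generator's stock conditions, seed 42) backs the end-to-end planted-truth
checks and is built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from crisprmge import (CommunityConfig, PipelineResult, generate_community,
                       run_pipeline)
from crisprmge.simulate import Community


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def small_community() -> Community:
    cfg = CommunityConfig(seed=7, n_phages=4, phage_len_range=(3000, 8000),
                          n_hosts=3, host_len=15_000, coverage=12.0)
    return generate_community(cfg)


@pytest.fixture(scope="session")
def small_result(small_community: Community) -> PipelineResult:
    return run_pipeline(small_community.contigs, small_community.reads)


@pytest.fixture(scope="session")
def default_community() -> Community:
    return generate_community(CommunityConfig(seed=42))


@pytest.fixture(scope="session")
def default_result(default_community: Community) -> PipelineResult:
    return run_pipeline(default_community.contigs, default_community.reads)
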