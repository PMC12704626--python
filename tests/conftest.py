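"""Shared fixtures: a small simulation config and a reduced-size pipeline
workspace generated once per session (all fixture data is synthesized at
test time; nothing is loaded from disk)."""

from pathlib import Path

import numpy as np
import pytest

from stratwas.simulate import SimulationConfig, make_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale config: enough signal for bookkeeping tests, fast to run."""
    return SimulationConfig(n_per_stratum=8000, n_ref=200, n_loci=4, n_variants=12,
                            n_genes=3, n_causal=2, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config)


@pytest.fixture(scope="session")
def small_workspace(small_config, tmp_path_factory) -> Path:
    """Bundle + TWAS + filter outputs for the small config, shared read-only."""
    from stratwas import pipeline

    out = tmp_path_factory.mktemp("ws")
    pipeline.stage_bundle(small_config, out)
    pipeline.stage_ctwas(out)
    pipeline.stage_filter(out)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
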