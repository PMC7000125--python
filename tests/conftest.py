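"""Shared fixtures: toy germline database and a small simulated run.

The expensive fixtures are session-scoped; the small error-free dataset is
the ground-truth substrate for read-processing and annotation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bcrseq import (SimulationConfig, build_toy_germline, load_manifest,
                    load_truth, run_pipeline, simulate_dataset)


@pytest.fixture(scope="session")
def toy_db():
    return build_toy_germline(seed=0)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=1, n_timepoints=2,
        subsets={"immature": 50, "naive": 60, "memory": 40, "plasmacyte": 12},
        clones_per_subset={"immature": 80, "naive": 110, "memory": 40,
                           "plasmacyte": 8},
        seq_error_rate=0.0, shm_rate=0.0)


@pytest.fixture(scope="session")
def small_dataset(toy_db, small_cfg, tmp_path_factory):
    """Error-free simulated paired-end run with truth table."""
    out = tmp_path_factory.mktemp("smallsim")
    paths = simulate_dataset(toy_db, small_cfg, out)
    return {
        "paths": paths,
        "manifest": load_manifest(paths["manifest"]),
        "truth": load_truth(paths["truth"]),
    }


@pytest.fixture(scope="session")
def small_result(toy_db, small_dataset):
    """Full pipeline output on the error-free small run."""
    p = small_dataset["paths"]
    return run_pipeline(p["r1"], p["r2"], toy_db, small_dataset["manifest"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
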