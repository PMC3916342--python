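"""Shared fixtures.

The expensive end-to-end fixtures (trained detector, whole-volume and
blockwise runs on the default phantom) are session-scoped so the
acceptance-level tests share one pipeline execution.
"""

from __future__ import annotations

import numpy as np
import pytest

import emsynapse as es
from emsynapse.pipeline import PipelineConfig, blockwise_process, run_pipeline, train_pipeline

#: training conditions: a separate, smaller annotated phantom
TRAIN_SPEC = es.PhantomSpec(shape=(24, 448, 448), n_synapses=12, seed=101)
#: the default 20-synapse evaluation phantom, fixed seed
TEST_SPEC = es.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def pipeline_cfg() -> PipelineConfig:
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def trained_detector(pipeline_cfg):
    vol, truth = es.generate_phantom(TRAIN_SPEC)
    return train_pipeline(vol, truth, pipeline_cfg)


@pytest.fixture(scope="session")
def default_phantom():
    return es.generate_phantom(TEST_SPEC)


@pytest.fixture(scope="session")
def global_run(trained_detector, default_phantom, pipeline_cfg):
    vol, _ = default_phantom
    return run_pipeline(vol, trained_detector, pipeline_cfg)


@pytest.fixture(scope="session")
def blockwise_run(trained_detector, default_phantom, pipeline_cfg):
    vol, _ = default_phantom
    return blockwise_process(vol, trained_detector, pipeline_cfg, (256, 256))


# ---- small, fast pipeline fixtures for unit-level end-to-end checks ----

SMALL_TRAIN_SPEC = es.PhantomSpec(
    shape=(18, 256, 256),
    n_synapses=5,
    synapse_extent_nm=(200.0, 420.0),
    n_membranes=4,
    membrane_extent_nm=(250.0, 400.0),
    n_blobs=2,
    blob_axis_nm=(150.0, 250.0),
    seed=7,
)


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    return PipelineConfig(seed=3)


@pytest.fixture(scope="session")
def small_detector(small_cfg):
    vol, truth = es.generate_phantom(SMALL_TRAIN_SPEC)
    return train_pipeline(vol, truth, small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
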