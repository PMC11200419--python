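import dataclasses

import numpy as np
import pytest

from bmelseg.anomaly import anomaly_map_for_study
from bmelseg.backends import OracleBackend
from bmelseg.phantom import PhantomConfig, generate_dataset, generate_study
from bmelseg.preprocess import preprocess_study
from bmelseg.tasks import TaskKind


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Reduced grid for fast unit tests."""
    return dataclasses.replace(PhantomConfig(), grid_shape=(8, 32, 32))


@pytest.fixture(scope="session")
def lesioned_study(default_config):
    return generate_study(default_config, seed=42)


@pytest.fixture(scope="session")
def healthy_study(default_config):
    return generate_study(default_config, seed=43, with_lesions=False)


@pytest.fixture(scope="session")
def oracle_cv_setup():
    """Six low-noise lesioned phantom volumes with oracle anomaly maps.

    Shared by the threshold-CV equivalence and end-to-end recovery tests:
    the oracle backend makes the maps a clean function of the known lesion
    signal, isolating the postprocessing pipeline.
    """
    config = dataclasses.replace(
        PhantomConfig(), noise_sd=0.01, target_lesion_contrast=0.5
    )
    studies = generate_dataset(config, n_healthy=0, n_lesioned=6, seed=314)
    pp = [preprocess_study(s) for s in studies]
    task = TaskKind.SEQUENCE_TRANSLATION
    backend = OracleBackend.from_studies(pp, task)
    maps = [anomaly_map_for_study(s, backend, task) for s in pp]
    return pp, maps
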