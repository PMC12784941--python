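import dataclasses

import numpy as np
import pytest

from corticothal import pipeline
from corticothal.synth import HistoSpec, PETSpec, SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_config(seed: int = 11, **overrides) -> SynthConfig:
    """A reduced study: fewer animals, shorter scans, full modality coverage."""
    base = SynthConfig(
        seed=seed,
        n_tbi=6,
        n_sham=4,
        n_volumes=700,
        pet=PETSpec(n_scanned=(6, 4), n_faulty=(1, 0)),
        histo=HistoSpec(n_subset=(4, 3)),
    )
    return dataclasses.replace(base, **overrides) if overrides else base


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return pipeline.run_pipeline(small_cohort)
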