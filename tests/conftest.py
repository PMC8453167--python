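import numpy as np
import pandas as pd
import pytest

from epichain.io_formats import OmicsMatrix, StudyDesign
from epichain.synthetic import SimConfig, make_design, simulate


@pytest.fixture(scope="session")
def design_2x2() -> StudyDesign:
    """Minimal valid design: 2 AA + 2 EA patients, paired."""
    return make_design(2, 2)


@pytest.fixture(scope="session")
def design_8x8() -> StudyDesign:
    """The cohort layout: 8 AA + 8 EA patients, paired."""
    return make_design(8, 8)


@pytest.fixture(scope="session")
def small_cohort():
    """One small fully linked synthetic cohort shared across tests."""
    config = SimConfig(
        n_cpg=600, n_mirna=120, n_mrna=400,
        n_dmde=4, n_chains=2, n_switch=2,
        seed=42,
    )
    return config, simulate(config)


def random_matrix(design: StudyDesign, n_features: int, seed: int,
                  kind: str = "mvalue") -> OmicsMatrix:
    rng = np.random.default_rng(seed)
    vals = rng.normal(0.0, 1.0, size=(n_features, len(design.sample_ids)))
    return OmicsMatrix(
        [f"f{i}" for i in range(n_features)], design.sample_ids, vals, kind
    )
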