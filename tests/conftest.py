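import numpy as np
import pytest

from canthyro.expression import log2_layer
from canthyro.synthetic import CohortConfig, generate_cohort


def small_config(seed: int = 3, **overrides) -> CohortConfig:
    """A desk-sized cohort: 10 + 10 tumors, 5 normals, compact gene and
    variant counts so the full pipeline runs in seconds."""
    base = dict(
        seed=seed,
        n_tumors_subtype1=10,
        n_tumors_subtype2=10,
        n_normals=5,
        n_genes=250,
        n_marker_genes_per_subtype=30,
        n_somatic_per_sample=40,
        n_germline_per_sample=60,
        reference_length=30000,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_log_expr(small_cohort):
    return log2_layer(small_cohort.expression)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
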