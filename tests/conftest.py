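import logging

import numpy as np
import pytest

from irscore import (
    CohortConfig,
    PlantedPatternSpec,
    generate_cohort,
    generate_null_cohort,
)

logging.getLogger("irscore").setLevel(logging.ERROR)


PLANTED = PlantedPatternSpec(
    items=((0, 5), (1, 12), (2, 8)),
    target_class="case",
    enrichment_target=0.30,
    enrichment_other=0.05,
)


def small_cohort_config(seed: int = 0, n_pairs: int = 12, planted: bool = True,
                        **kw) -> CohortConfig:
    """Desk-scale cohort: few pairs, small cores, few metrics."""
    defaults = dict(
        n_pairs=n_pairs,
        pixels_per_core=(60, 120),
        n_metrics=6,
        planted_patterns=(PLANTED,) if planted else (),
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def planted_cohort():
    return generate_cohort(small_cohort_config(seed=11, n_pairs=15))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_null_cohort(small_cohort_config(seed=11, n_pairs=15, planted=False))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
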