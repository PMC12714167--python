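import warnings

import numpy as np
import pytest

from ctrlcircuit.synthetic import (
    CohortSpec,
    ExpressionSpec,
    generate_connectome_cohort,
    generate_expression_atlas,
)

# scipy Shapiro-Wilk and the soft-power fallback warn on purpose in several
# fixtures; keep test output readable
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def planted_cohort():
    """20/20 cohort with a planted 10-edge path attenuated in MDDSI."""
    spec = CohortSpec(
        n_per_group={"MDDNSI": 20, "MDDSI": 20},
        n_regions=90,
        planted_edges=[(i, i + 1) for i in range(10)],
        edge_effect=2.0,
        affected_group="MDDSI",
        seed=7,
    )
    return generate_connectome_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    spec = CohortSpec(
        n_per_group={"MDDNSI": 15, "MDDSI": 15}, n_regions=60, seed=13
    )
    return generate_connectome_cohort(spec)


@pytest.fixture(scope="session")
def planted_atlas():
    """Four 150-gene modules at within-r 0.7; module 0 tracks the trait at 0.5."""
    spec = ExpressionSpec(
        n_genes=700,
        n_regions=120,
        modules=[(150, 0.7, 0.5), (150, 0.7, 0.0), (150, 0.7, 0.0), (150, 0.7, 0.0)],
        seed=21,
    )
    return generate_expression_atlas(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
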