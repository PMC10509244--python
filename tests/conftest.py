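import numpy as np
import pytest

from hicdiffkit.matrix import ContactMatrix, NormTag
from hicdiffkit.pipeline import boundary_typing, drf_differential_analysis
from hicdiffkit.synthetic import (
    default_study_design,
    default_study_spec,
    make_cohort,
)

COHORT_SEED = 11


def toeplitz_matrix(n: int = 60, resolution: int = 25_000) -> ContactMatrix:
    """Pure distance-decay matrix: value depends only on |i - j|."""
    idx = np.arange(n)
    vals = 100.0 / (np.abs(idx[:, None] - idx[None, :]) + 1.0)
    return ContactMatrix("chrT", resolution, vals, np.ones(n, bool), NormTag.CHROM_TOTAL)


@pytest.fixture(scope="session")
def study_cohort():
    """The default synthetic study cohort (8 conditions x 2 replicates)."""
    return make_cohort(
        default_study_spec(), default_study_design(), n_replicates=2, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def typed_boundaries(study_cohort):
    return boundary_typing(study_cohort)


@pytest.fixture(scope="session")
def drf_analysis(study_cohort):
    return drf_differential_analysis(study_cohort)
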