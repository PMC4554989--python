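import numpy as np
import pytest

from springdamp import CohortSpec, ModelParams, standard_grid
from springdamp.synthetic import DEFAULT_LINE_MEDIANS, PHYSIO_SAMPLING


@pytest.fixture
def grid():
    """Standard 0–100 grid at step 0.1 (1001 points)."""
    return standard_grid()


@pytest.fixture
def sweep_base_params():
    """Held-fixed configuration of the canonical sensitivity sweeps."""
    return ModelParams(K=0.1, C=2.0, F_pert=1.0, perc=1.0)


@pytest.fixture
def cortisol_params():
    """The mean-pattern cortisol fit (fitting defaults F_pert=0.1, perc=1)."""
    return ModelParams(K=0.028, C=0.384)


@pytest.fixture
def physio_times():
    return PHYSIO_SAMPLING.copy()


@pytest.fixture
def single_line_degenerate_spec():
    """One line, 8 individuals, no between-individual spread, no noise.

    The canonical fixture for deterministic outlier-rule checks: every
    individual of a measure yields an identical series, so Tukey fences
    collapse to a point and only planted outliers can be flagged.
    """
    return CohortSpec(
        line_medians={"A": DEFAULT_LINE_MEDIANS["A"]},
        dispersion=0.0,
        noise_sigma=0.0,
        seed=0,
    )
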