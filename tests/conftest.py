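import warnings

import numpy as np
import pytest

from hetgeo.ihs import FeatureITHModel
from hetgeo.synthio import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Compact multi-region cohort reused across module tests."""
    cfg = SimConfig(
        n_patients=8,
        regions_per_patient=4,
        n_genes=80,
        sigma_between=1.0,
        sigma_within=0.5,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Cohort whose genes span the full range of true within-ratios r_g.

    Total per-gene variance is held at 1 so r_g = sigma_w^2 directly;
    10 patients x 5 regions matches a realistic multi-region design.
    """
    r = np.linspace(0.05, 0.95, 300)
    cfg = SimConfig(
        n_patients=10,
        regions_per_patient=5,
        n_genes=300,
        sigma_within=np.sqrt(r),
        sigma_between=np.sqrt(1.0 - r),
        baseline_log_mean=6.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_ihs(recovery_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FeatureITHModel(
            recovery_cohort.expression, recovery_cohort.patients, log2_transform=True
        ).fit()
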