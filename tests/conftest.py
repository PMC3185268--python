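import numpy as np
import pandas as pd
import pytest

from triageiv.cohort import Cohort


def make_cohort(treatment, outcome, covariates=None, instruments=None, cluster=None):
    """Build a validated Cohort from plain arrays (test helper)."""
    treatment = np.asarray(treatment)
    n = len(treatment)
    data = {"patient_id": np.arange(n), "treatment": treatment, "outcome": np.asarray(outcome)}
    covariates = covariates or {}
    instruments = instruments or {}
    for name, vals in {**covariates, **instruments}.items():
        data[name] = np.asarray(vals)
    cluster_name = None
    if cluster is not None:
        cluster_name = "cluster_id"
        data[cluster_name] = np.asarray(cluster)
    return Cohort(
        data=pd.DataFrame(data),
        covariate_names=tuple(covariates),
        instrument_names=tuple(instruments),
        cluster_name=cluster_name,
    ).validate()


def two_by_two_cohort(z_counts):
    """Cohort from counts keyed by (z, x, y) -> n."""
    z, x, y = [], [], []
    for (zi, xi, yi), cnt in z_counts.items():
        z += [zi] * cnt
        x += [xi] * cnt
        y += [yi] * cnt
    return make_cohort(x, y, instruments={"z": z})


def random_iv_cohort(rng, n=200):
    """Small random cohort with a binary instrument and no covariates,
    resampled until the instrument moves treatment (nonzero Wald denominator)."""
    while True:
        z = rng.binomial(1, rng.uniform(0.3, 0.7), n)
        p_x = 1 / (1 + np.exp(-(rng.normal(0, 0.5) + rng.uniform(0.8, 2.0) * z)))
        x = (rng.random(n) < p_x).astype(int)
        p_y = 1 / (1 + np.exp(-(rng.normal(-0.5, 0.3) + rng.normal(0, 0.5) * x)))
        y = (rng.random(n) < p_y).astype(int)
        if len(np.unique(x)) == 2 and len(np.unique(y)) == 2:
            if abs(x[z == 1].mean() - x[z == 0].mean()) > 1e-9:
                return make_cohort(x, y, instruments={"z": z})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
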