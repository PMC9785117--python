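import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metaboaging as m
from metaboaging.synthdata import CohortTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-structured cohort draw (n=138, ~2% missing)."""
    return m.generate_cohort(m.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without missing values, split 105/33."""
    cohort = m.generate_cohort(m.GeneratorConfig(seed=12, missing_rate=0.0))
    return m.split_cohort(cohort, 105 / 138, seed=13)


@pytest.fixture(scope="session")
def transformed_cohort(clean_cohort):
    table, specs, report = m.fit_transform_cohort(clean_cohort)
    return table, specs, report


@pytest.fixture()
def qc_fixture():
    """12-feature table: 3 fail the blank rule, 2 the CV rule, 1 missingness."""
    return m.generate_feature_table(
        12, n_samples=20, n_blanks=3, n_qc=3, drift_amplitude=0.1, seed=21,
        n_fail_blank=3, n_fail_cv=2, n_fail_missing=1,
    )


def make_cohort_table(columns: dict, roles: dict) -> CohortTable:
    """Assemble a CohortTable directly from arrays (test helper)."""
    df = pd.DataFrame(columns)
    df.index = pd.Index([f"S{i:03d}" for i in range(len(df))], name="subject_id")
    return CohortTable(data=df, roles=roles, mask=df.notna())


def linear_drift_table(n_samples=24, n_qc=6, slope=0.02, base=1e5, seed=3):
    """Feature table with exactly linear multiplicative drift and noiseless QCs."""
    rng = np.random.default_rng(seed)
    ft = m.generate_feature_table(
        4, n_samples=n_samples, n_blanks=2, n_qc=n_qc, drift_amplitude=0.0,
        seed=seed, qc_cv=0.0,
    )
    order = ft.injection_order.to_numpy(dtype=float)
    drift = 1.0 + slope * (order - order.mean())
    vals = ft.intensities.to_numpy()
    ft.intensities.iloc[:, :] = vals * drift[None, :]
    return ft
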