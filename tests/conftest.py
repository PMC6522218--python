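"""Shared fixtures: phantom cohorts and derived feature tables.

The expensive fixtures (full cohort extraction) are session-scoped so the
end-to-end checks and the classifier tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import liverlesion as ll


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_config():
    return ll.PhantomConfig(n_patients=1, noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten patients, uniform class mix, default noise."""
    return ll.generate_cohort(ll.PhantomConfig(n_patients=10, seed=11))


@pytest.fixture(scope="session")
def strong_cohort_table() -> pd.DataFrame:
    """Feature table of the 50-patient, well-separated evaluation cohort."""
    records = ll.generate_cohort(ll.PhantomConfig(n_patients=50, seed=0))
    return ll.extract_cohort(records)


@pytest.fixture(scope="session")
def strong_cohort_folds(strong_cohort_table):
    """LOPO fold results on the 50-patient cohort (700 trees, 50 features)."""
    return ll.lopo_crossval(strong_cohort_table, ll.ModelConfig(seed=0))


def synthetic_feature_table(
    n_patients: int = 12,
    n_features: int = 8,
    n_informative: int = 3,
    lesions_per_patient: int = 2,
    separation: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A feature table with class structure but no imaging: fast classifier tests."""
    rng = np.random.default_rng(seed)
    classes = list(ll.CLASS_ORDER)
    rows = []
    for p in range(n_patients):
        for j in range(lesions_per_patient):
            label = classes[(p * lesions_per_patient + j) % len(classes)]
            center = separation * classes.index(label)
            x = rng.normal(0.0, 1.0, size=n_features)
            x[:n_informative] += center
            row = {
                "patient_id": f"P{p:03d}",
                "lesion_id": f"P{p:03d}_L{j}",
                "label": label,
            }
            row.update({f"f{k}": x[k] for k in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)
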