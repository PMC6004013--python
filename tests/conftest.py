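import numpy as np
import pandas as pd
import pytest

from uromet import SyntheticConfig, generate_cohort
from uromet.core_io import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """Modest two-batch cohort with drift, batch offsets and noise."""
    cfg = SyntheticConfig(
        n_features=40, n_discriminant=8, n_background=4,
        n_patients_bc=14, n_patients_monitor=3, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with every perturbation switched off."""
    cfg = SyntheticConfig(
        n_features=25, n_discriminant=0, n_background=3,
        n_patients_bc=10, n_patients_monitor=2,
        drift_amplitude=0.0, between_batch_log2_range=0.0,
        noise_rsd=0.0, effect_log2fc=0.0, seed=5,
    )
    return generate_cohort(cfg)


def tiny_table() -> FeatureTable:
    """Hand-built 6-sample, 3-feature table exercising every role."""
    samples = pd.DataFrame(
        {
            "patient_id": [None, None, "P1", "P1", "P2", None],
            "batch": [1, 1, 1, 1, 1, 1],
            "injection_order": [1, 2, 3, 4, 5, 6],
            "role": ["CONDITIONING_QC", "QC", "STUDY", "STUDY", "STUDY", "BLANK"],
            "class_label": [None, None, "BC", "CTRL", "BC", None],
            "visit_index": pd.array([None, None, 0, 1, 0, None], dtype="Int64"),
        },
        index=pd.Index([f"S{i}" for i in range(1, 7)], name="sample_id"),
    )
    features = pd.DataFrame(
        {"mz": [100.05, 250.1, 399.9], "rt": [1.2, 3.4, 7.8]},
        index=pd.Index(["F1", "F2", "F3"], name="feature_id"),
    )
    rng = np.random.default_rng(0)
    intensities = pd.DataFrame(
        rng.uniform(50, 500, size=(6, 3)), index=samples.index, columns=features.index
    )
    intensities.iloc[2, 1] = np.nan  # one missing value survives I/O
    return FeatureTable(intensities, samples, features).validate()


@pytest.fixture()
def hand_table():
    return tiny_table()
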