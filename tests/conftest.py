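import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort with the default strong signatures (2 SD, 14 h)."""
    from sepsishorizon import CohortParams, generate_cohort
    params = CohortParams(n_patients=60, seed=42)
    patients, events = generate_cohort(params)
    return params, patients, events


@pytest.fixture(scope="session")
def small_records(small_cohort):
    from sepsishorizon import records_from_tables
    _, patients, events = small_cohort
    return records_from_tables(patients, events)


@pytest.fixture(scope="session")
def small_dataset(small_records):
    """Standardized 4 h-horizon windows for the small cohort, capped at 48 rows."""
    from sepsishorizon import assemble_dataset, standardize_dataset
    ds = assemble_dataset(small_records, 4, max_timepoints=48)
    return standardize_dataset(ds)


@pytest.fixture(scope="session")
def tiny_fitted(small_dataset):
    """A small lstm_transformer fitted on the small cohort (for explain/models tests)."""
    from sepsishorizon import SequenceClassifier
    ds = small_dataset
    clf = SequenceClassifier(architecture="lstm_transformer", d_model=8, n_heads=2,
                             n_encoder_layers=1, ff_dim=16, dropout=0.0,
                             learning_rate=3e-3, batch_size=16, max_epochs=6,
                             random_state=0)
    clf.fit(ds.X, ds.y, ds.valid)
    return clf
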