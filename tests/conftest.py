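import pytest
from hypothesis import HealthCheck, settings

from centrokit import SyntheticSpec, sample_protein_set, sample_template_hits

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_spec():
    return SyntheticSpec(n_proteins=500, seed=1)


@pytest.fixture(scope="session")
def study_cohort(study_spec):
    """A 500-protein study-like cohort with ground-truth tracks."""
    records, track_set, ledger = sample_protein_set(study_spec)
    return records, track_set, ledger


@pytest.fixture(scope="session")
def study_hits(study_spec, study_cohort):
    records, track_set, _ = study_cohort
    return sample_template_hits(study_spec, records, track_set)


@pytest.fixture(scope="session")
def small_cohort():
    spec = SyntheticSpec(n_proteins=30, length_mean=400.0, seed=7)
    records, track_set, ledger = sample_protein_set(spec)
    return spec, records, track_set, ledger
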