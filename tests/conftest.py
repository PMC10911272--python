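import pytest
from hypothesis import HealthCheck, settings

import ribomethdiff as rmd

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def catalog():
    return rmd.default_catalog()


@pytest.fixture(scope="session")
def design():
    return rmd.default_design()


@pytest.fixture(scope="session")
def preset_data(catalog, design):
    """Planted-truth dataset under the default growth-arrest scenario, seed 1."""
    truth = rmd.build_truth(catalog, design, seed=1, **rmd.growth_arrest_preset())
    profiles = rmd.simulate_end_counts(truth, rmd.FragmentationParams(seed=1), catalog)
    merged = rmd.merge_technical_replicates(profiles, design)
    scores = rmd.compute_rms_scores(merged, catalog)
    return truth, merged, scores


@pytest.fixture(scope="session")
def donor_dominant_data(catalog, design):
    """Same planted truth with dominant donor batch effects, seed 1."""
    truth = rmd.build_truth(catalog, design, seed=1, **rmd.donor_dominant_preset())
    profiles = rmd.simulate_end_counts(truth, rmd.FragmentationParams(seed=1), catalog)
    merged = rmd.merge_technical_replicates(profiles, design)
    scores = rmd.compute_rms_scores(merged, catalog)
    return truth, scores
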