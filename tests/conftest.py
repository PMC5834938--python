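import pytest

from estubenthos.core_data import SurveyDesign
from estubenthos.simulate import field_survey_preset, simulate_survey


@pytest.fixture(scope="session")
def design():
    return SurveyDesign()


@pytest.fixture(scope="session")
def small_design():
    """2 estuaries x 2 sites x 2 habitats x 2 plots x 2 replicates = 32 cores."""
    return SurveyDesign(
        estuaries=("A", "B"),
        sites_per_estuary=2,
        plots_per_site_habitat=2,
        replicates_per_plot=2,
    )


@pytest.fixture(scope="session")
def preset_survey():
    """The documented survey preset generated at seed 1."""
    config = field_survey_preset(seed=1)
    faunal, sediment, truth = simulate_survey(config)
    return config, faunal, sediment, truth
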