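import numpy as np
import pytest

from surveysub.population import ScenarioSpec, build_population
from surveysub.synthetic import SyntheticSurveyConfig, generate_synthetic_survey


@pytest.fixture(scope="session")
def small_survey():
    """Compact synthetic survey: 120 sites, 6 years (fast but structured)."""
    cfg = SyntheticSurveyConfig(n_sites=120, n_years=6, mean_catch=12.0, seed=11)
    return generate_synthetic_survey(cfg)


@pytest.fixture(scope="session")
def warm_population(small_survey):
    hauls, lengths, otoliths = small_survey
    return build_population(hauls, lengths, ScenarioSpec("warm"), seed=5, otoliths=otoliths)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
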