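import numpy as np
import pandas as pd
import pytest

from oysterhsm import GeneratorConfig, generate_survey
from oysterhsm.field_summary import first_quadrat_table, site_abundance_table


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def survey(default_config):
    return generate_survey(default_config)


@pytest.fixture(scope="session")
def sites(survey):
    return survey[0]


@pytest.fixture(scope="session")
def quadrats(survey):
    return survey[1]


@pytest.fixture(scope="session")
def first_quadrats(sites, quadrats):
    return first_quadrat_table(sites, quadrats)


@pytest.fixture(scope="session")
def presence_sites(sites, quadrats, default_config):
    table = site_abundance_table(sites, quadrats, default_config.quadrat_area)
    out = table[table["observed_presence"]].copy()
    out["substrate_cover"] = out["mean_substrate"]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def toy_covariates(rng):
    """Three near-independent covariate columns."""
    n = 200
    return pd.DataFrame({
        "a": rng.normal(size=n),
        "b": rng.normal(size=n),
        "c": rng.normal(size=n),
    })
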