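import pathlib
import sys

import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from cohortstore import EtlOptions, run_etl, scenario_obesity_asthma

KEY = bytes(range(32))


@pytest.fixture(scope="session")
def key():
    return KEY


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The obesity/asthma narrative fixture, generated once per session."""
    d = tmp_path_factory.mktemp("scenario")
    return scenario_obesity_asthma(11, d)


@pytest.fixture(scope="session")
def scenario_bundle(scenario, tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario_store")
    return run_etl(
        scenario.csv_path,
        scenario.vcf_path,
        KEY,
        out,
        EtlOptions(include_nocall=True),
    )
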