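import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from sfcurate.calibrate import calibrate_hierarchy
from sfcurate.network import build_network
from sfcurate.scoring import ScoringParams
from sfcurate.synth import SynthConfig, generate_queries, generate_superfamily


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture(scope="session")
def default_cfg():
    """The study conditions: default synthetic superfamily, seed 1."""
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def superfamily(default_cfg):
    return generate_superfamily(default_cfg)


@pytest.fixture(scope="session")
def small_superfamily():
    """A light superfamily for unit tests (6 members per family)."""
    return generate_superfamily(SynthConfig(seed=7, members_per_family=6))


@pytest.fixture(scope="session")
def calibrated_superfamily(default_cfg, params):
    """Default superfamily with profiles built and cutoffs calibrated."""
    sf = generate_superfamily(default_cfg)
    calibrate_hierarchy(sf.root, sf.records, params)
    return sf


@pytest.fixture(scope="session")
def query_set(default_cfg, calibrated_superfamily):
    return generate_queries(default_cfg, calibrated_superfamily)


@pytest.fixture(scope="session")
def full_ssn(superfamily, params):
    """All-vs-all similarity network of the default superfamily."""
    return build_network(superfamily.records, params, max_evalue=10.0)
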