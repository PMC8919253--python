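import numpy as np
import pytest

from cexfrag.chem import cystine_topology
from cexfrag.forcefield import build_forcefield
from cexfrag.geometry import reference_geometry
from cexfrag.integrity import baselines_from_thermal
from cexfrag.simulate import SimulationConfig, sample_starting_configs, thermalize


@pytest.fixture(scope="session")
def cystine():
    return cystine_topology()


@pytest.fixture(scope="session")
def ff_neutral(cystine):
    return build_forcefield(cystine, 0.0)


@pytest.fixture(scope="session")
def ff_charged(cystine):
    return build_forcefield(cystine, 3.0)


@pytest.fixture(scope="session")
def refgeom(cystine, ff_neutral):
    return reference_geometry(cystine, ff_neutral)


@pytest.fixture(scope="session")
def thermal_cfg():
    # 16 ps thermal run: long enough for 12 starting configs 1 ps apart and
    # converged baseline moments, short enough for the test suite.
    return SimulationConfig(
        seed=5, ensemble_size=12, thermal_duration_ps=16.0, save_stride=4
    )


@pytest.fixture(scope="session")
def thermal(cystine, ff_neutral, thermal_cfg, refgeom):
    return thermalize(cystine, ff_neutral, thermal_cfg, start_positions=refgeom)


@pytest.fixture(scope="session")
def start_frames(thermal, thermal_cfg):
    return sample_starting_configs(thermal, thermal_cfg)


@pytest.fixture(scope="session")
def baselines(thermal, cystine):
    return baselines_from_thermal(thermal, cystine.bonds)
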