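import numpy as np
import pytest

from sdpgap import BilayerSDP, Contrast, default_pc_scheme, scenario_library


@pytest.fixture(scope="session")
def popc_truth():
    """POPC-like ground truth (SAXS MLV preset)."""
    return scenario_library()["popc_saxs_mlv"]


@pytest.fixture(scope="session")
def pc_scheme():
    return default_pc_scheme(n_CH2=28, n_CH=2, n_CH3=2)


@pytest.fixture
def popc_sdp(popc_truth):
    return popc_truth.sdp


@pytest.fixture
def xray():
    return Contrast(radiation="xray")


@pytest.fixture
def neutron_d2o():
    return Contrast(radiation="neutron", solvent_d2o_fraction=1.0)


@pytest.fixture
def z_grid():
    return np.linspace(-40.0, 40.0, 1601)


def make_sdp(scheme, **overrides):
    """Feasible bilayer state with optional field overrides."""
    volumes = {c.name: c.volume_ref for c in scheme.components}
    kw = dict(
        z_CholCH3=20.2,
        z_PCN=18.6,
        z_CG=15.2,
        sigma_PCN=2.6,
        sigma_CG=2.2,
        sigma_CH3=2.9,
        D_C=14.32,
        sigma_HC=2.3,
        volumes=volumes,
        V_L=sum(volumes.values()),
    )
    kw.update(overrides)
    return BilayerSDP(**kw)
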