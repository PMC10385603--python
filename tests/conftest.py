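import pytest

from theradose import cu64, default_config
from theradose.nuclide import RadionuclideData


@pytest.fixture(scope="session")
def nuclide():
    return cu64()


@pytest.fixture(scope="session")
def config():
    return default_config(seed=0)


@pytest.fixture(scope="session")
def beta_only_nuclide():
    """Cu-64 record with the electron term restricted to the beta branches
    (no Auger/conversion component) — handy for closed-form unit checks."""
    return RadionuclideData(
        name="Cu-64-beta-only",
        half_life_h=12.7004,
        branch_beta_plus=0.174,
        branch_beta_minus=0.390,
        branch_ec=0.44,
        mean_energy_np_mev=0.390 * 0.1902 + 0.174 * 0.2782,
        mean_energy_photon_mev=0.0,
        source_citation="test fixture",
    )
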