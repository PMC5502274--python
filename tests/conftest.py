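import warnings

import pytest

from berrynet.simulate import default_config, simulate_study


@pytest.fixture(scope="session")
def demo_study():
    """The bundled demo scenario, simulated once per session (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(default_config(0))


@pytest.fixture()
def small_config():
    """A small, fast configuration for targeted generator tests."""
    from berrynet.simulate import ModuleSpec, SimulationConfig

    return SimulationConfig(
        n_genes=120,
        n_metabolites=5,
        module_spec=[
            ModuleSpec("M1", 40, (-0.4, 0.2, 1.0, 1.7, 2.3), 0.2),
            ModuleSpec("M2", 40, (-0.5, 1.3, 2.2, 0.8, 0.1), 0.2),
        ],
        seed=11,
    )
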