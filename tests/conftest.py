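import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture
def small_spec():
    from bmrepurpose.simulate import SimulationSpec

    return SimulationSpec(
        n_genes=300,
        frac_de=0.1,
        n_drugs=80,
        n_compounds=8,
        n_cell_lines=30,
        n_frames=60,
        n_particles=12,
        seed=7,
    )
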