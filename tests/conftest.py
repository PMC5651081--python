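import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from panelforge.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        seed=11,
        n_chromosomes=2,
        chromosome_length=200_000,
        genes_per_chromosome=20,
        n_candidates=2000,
        n_legacy=50,
        n_samples=20,
    )


@pytest.fixture(scope="session")
def sim_bundle(small_spec):
    return simulate(small_spec)
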