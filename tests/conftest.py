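import numpy as np
import pytest

from frailtyflow.engine import EntrySpec, FlowSpec, ModelParameters, zero_parameters
from frailtyflow.synthetic import SyntheticConfig, example_parameters, generate


@pytest.fixture(scope="session")
def example_params():
    return example_parameters()


@pytest.fixture(scope="session")
def synthetic_observations(example_params):
    """A medium-sized seeded cohort shared across tests (12 years)."""
    initial = np.full((4, 4), 50_000.0)
    config = SyntheticConfig(
        years=12,
        initial_counts=initial,
        true_params=example_params,
        seed=2006,
    )
    observations, truth = generate(config)
    return observations, truth


def constant_params(
    p_death=0.0, p_dereg=0.0, p_prog=0.0, p_age=0.0, entry_rate=0.0,
    n_bands=4, n_states=4,
) -> ModelParameters:
    """Uniform constant-rate parameter grid for hand-calculable scenarios."""
    params = zero_parameters(n_bands, n_states)
    for key in params.death:
        params.death[key] = FlowSpec(kind="constant", p=p_death)
    for key in params.dereg:
        params.dereg[key] = FlowSpec(kind="constant", p=p_dereg)
    for key in params.entry:
        params.entry[key] = EntrySpec(kind="constant", rate=entry_rate)
    for key in params.ageing:
        params.ageing[key] = FlowSpec(kind="constant", p=p_age)
    for key in params.progression:
        params.progression[key] = FlowSpec(kind="constant", p=p_prog)
    return params
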