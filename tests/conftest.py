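import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated experiment shared by read-only tests."""
    from mutacc.ma_simulator import SimParams, simulate_experiment

    params = SimParams(
        seed=11, n_lines=2, n_sublines=6, n_pseudolines=4, n_replicates=3
    )
    table, truth = simulate_experiment(params)
    return params, table, truth


@pytest.fixture(scope="session")
def small_fitness(small_sim):
    """Fitness records for the small simulated experiment."""
    from mutacc.demographic_fitness import (
        compute_relative_fitness,
        mean_control_schedule,
        solve_r0,
    )

    _, table, _ = small_sim
    rate = solve_r0(mean_control_schedule(table))
    return table, rate, compute_relative_fitness(table, rate)


def simulate_fitness(params):
    """simulate -> w records, the standard front half of the pipeline."""
    from mutacc.demographic_fitness import (
        compute_relative_fitness,
        mean_control_schedule,
        solve_r0,
    )
    from mutacc.ma_simulator import simulate_experiment

    table, truth = simulate_experiment(params)
    rate = solve_r0(mean_control_schedule(table))
    return table, truth, compute_relative_fitness(table, rate)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
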