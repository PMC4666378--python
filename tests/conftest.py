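import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A seeded 8,000-site two-group simulation with 8 spiked regions."""
    from methsingle.simulate import simulate_counts, spike_in_dmrs, synth_template

    template = synth_template(8000, seed=11)
    truth = spike_in_dmrs(template, n_dmr=8, seed=11)
    sim = simulate_counts(truth, depth=10.0, seed=11)
    return sim


@pytest.fixture(scope="session")
def null_sim():
    """A seeded 8,000-site null simulation (no spiked regions)."""
    from methsingle.simulate import simulate_counts, spike_in_dmrs, synth_template

    template = synth_template(8000, seed=23)
    truth = spike_in_dmrs(template, n_dmr=0, seed=23)
    return simulate_counts(truth, depth=10.0, seed=23, n_reps=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
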