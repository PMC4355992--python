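import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mcombat as mc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    probes = probes or tuple(f"g{i + 1}" for i in range(g))
    samples = samples or tuple(f"s{j + 1}" for j in range(n))
    return mc.ExpressionMatrix(values, tuple(probes), tuple(samples))


@pytest.fixture
def toy():
    """Two batches of three samples; probe g1 is the hand-derived example
    ({1,2,3} vs {5,6,7}), probe g2 just provides a second gene."""
    Y = make_matrix([[1, 2, 3, 5, 6, 7], [2, 4, 6, 1, 3, 5]])
    design = mc.BatchDesign(
        Y.sample_ids, ("A", "A", "A", "B", "B", "B"), reference="A"
    )
    return Y, design


@pytest.fixture
def strong_sim():
    """Three batches with strong injected additive and scale effects."""
    cfg = mc.SimulationConfig(n_genes=400, batch_sizes=(30, 30, 30), seed=42)
    return mc.simulate_dataset(cfg)
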