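import numpy as np
import pytest

from eqtlnet.model import NetworkModel
from eqtlnet.simulate import SimulationConfig, sample_effects, sample_topology


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_model(
    rng: np.random.Generator,
    p: int,
    expected_degree: float = 1.5,
    allow_cycles: bool = False,
) -> NetworkModel:
    """Random faithful, stable model with unique cis perturbations."""
    cfg = SimulationConfig(
        p=p, expected_degree=min(expected_degree, p - 1), allow_cycles=allow_cycles
    )
    support = sample_topology(p, cfg.expected_degree, allow_cycles, rng)
    return sample_effects(support, cfg, rng)


def chain_model(p: int, effect: float = 0.8, sigma: float = 0.25) -> NetworkModel:
    """Deterministic linear pathway y0 -> y1 -> ... -> y_{p-1}."""
    b = np.zeros((p, p))
    for i in range(p - 1):
        b[i + 1, i] = effect
    return NetworkModel(
        b=b,
        w=np.eye(p),
        sigma=np.full(p, sigma),
        assignment=np.arange(p),
    )
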