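import numpy as np
import pytest

from triageq import WorkflowConfig


@pytest.fixture
def fig10_config() -> WorkflowConfig:
    """Busy single-radiologist clinic at the reference operating point:
    10-min reads, 10% prevalence, Se=0.95 / Sp=0.89, traffic intensity 0.8."""
    return WorkflowConfig(f=0.0, prevalence_pi=0.1, se=0.95, sp=0.89,
                          n_rad=1, read_time_diseased=10.0,
                          read_time_nondiseased=10.0, rho=0.8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240921)


def random_stable_config(rng: np.random.Generator) -> WorkflowConfig:
    """Sample a random stable clinical scenario across both workflow models."""
    n_rad = int(rng.integers(1, 3))
    equal_rates = n_rad == 2 or rng.random() < 0.5
    read_d = float(rng.uniform(5.0, 15.0))
    read_nd = read_d if equal_rates else float(rng.uniform(5.0, 15.0))
    return WorkflowConfig(
        f=float(rng.uniform(0.0, 0.5)),
        prevalence_pi=float(rng.uniform(0.05, 0.4)),
        se=float(rng.uniform(0.6, 1.0)),
        sp=float(rng.uniform(0.6, 1.0)),
        n_rad=n_rad,
        read_time_interrupting=float(rng.uniform(3.0, 8.0)),
        read_time_diseased=read_d,
        read_time_nondiseased=read_nd,
        rho=float(rng.uniform(0.3, 0.85)),
    )
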