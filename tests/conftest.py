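import numpy as np
import pytest

from ahrcore import SimulationConfig, StudyDesign, generate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast five-study configuration with a strong, easily recovered signal."""
    return SimulationConfig(
        n_genes=400,
        battery_size=8,
        effect_size_log2=2.5,
        noise_sd_log2=0.4,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_all(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def bh_oracle(p):
    """Independent Benjamini-Hochberg step-up (plain loop implementation)."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def hypergeom_tail_oracle(n, size_a, size_b, observed):
    """Exact upper-tail overlap probability by direct combinatorial sum."""
    from math import comb

    total = comb(n, size_b)
    acc = 0
    for k in range(observed, min(size_a, size_b) + 1):
        if size_b - k > n - size_a:
            continue
        acc += comb(size_a, k) * comb(n - size_a, size_b - k)
    return acc / total
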