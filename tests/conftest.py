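import numpy as np
import pytest

import ctskit as ck


def random_sequence(rng, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pwm():
    """Random-count width-6 PWM with a near-uniform background."""
    r = np.random.default_rng(7)
    return ck.build_pwm(r.integers(0, 40, size=(4, 6)), pseudocount=0.5)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small synthetic data set shared by simulator/pipeline tests."""
    cfg = ck.SimConfig(
        genome_length=500_000,
        n_single_sites=25,
        n_paired_sites=25,
        tag_depth=200_000,
        n_genes=200,
        seed=11,
    )
    genome, truth = ck.simulate_genome(cfg)
    return cfg, genome, truth
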