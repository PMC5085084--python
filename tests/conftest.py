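import numpy as np
import pytest

from msapseq.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact error-free study used by several suites."""
    return SimulationConfig(
        seed=11,
        genome_length=12_000,
        target_gaattc_sites=24,
        target_ccgg_sites=24,
        n_changes_per_pair=4,
        n_shared=2,
        read_error_rate=0.0,
        coverage=10,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genome_with_methylome(rng, length):
    """Random sequence + random states on its CCGG sites (oracle food)."""
    from msapseq.digest import MethylationState, Methylome, find_sites

    seq = "".join(rng.choice(list("ACGT"), size=length))
    _eco, ccgg = find_sites(seq)
    states = list(MethylationState)
    meth = Methylome(
        {q: states[int(rng.integers(len(states)))] for q in ccgg if rng.random() < 0.7}
    )
    return seq, meth
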