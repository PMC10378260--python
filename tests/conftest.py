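import numpy as np
import pytest

from sleephht import DEFAULT_STAGE_SPECS, EMDConfig, decompose, generate_epoch

STAGE_CYCLE = list(DEFAULT_STAGE_SPECS)


@pytest.fixture(scope="session")
def emd_config():
    return EMDConfig()


@pytest.fixture(scope="session")
def hundred_decompositions(emd_config):
    """EMD of 100 synthetic 30-s epochs cycling through all six stages."""
    seeds = np.random.SeedSequence(42).generate_state(100)
    out = []
    for k in range(100):
        spec = DEFAULT_STAGE_SPECS[STAGE_CYCLE[k % len(STAGE_CYCLE)]]
        ep = generate_epoch(spec, seed=int(seeds[k]))
        out.append((ep, decompose(ep.samples, emd_config)))
    return out


@pytest.fixture(scope="session")
def fs():
    return 100.0


@pytest.fixture(scope="session")
def t_epoch(fs):
    return np.arange(3000) / fs
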