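import numpy as np
import pytest
from hypothesis import settings

from mirspot.energy import load_default_parameters
from mirspot.sequences import BASES, RnaSequence

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, length, name="seq"):
    return RnaSequence(name, "".join(BASES[k] for k in rng.integers(0, 4, length)))


@pytest.fixture(scope="session")
def zero_params(params):
    """All-zero parameter table (init, stacks, penalties and terminals 0)."""
    from dataclasses import replace

    import numpy as np

    return replace(
        params,
        stack_energy={k: 0.0 for k in params.stack_energy},
        bulge_penalty=np.zeros_like(params.bulge_penalty),
        interior_penalty=np.zeros_like(params.interior_penalty),
        init_energy=0.0,
        terminal_penalty=0.0,
    )
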