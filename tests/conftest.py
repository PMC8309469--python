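import numpy as np
import pytest

from boxscan import CompositionModel, compile_motif, default_registry


@pytest.fixture(scope="session")
def registry():
    return {m.name: m for m in default_registry()}


@pytest.fixture
def rng():
    return np.random.default_rng(20210706)


def random_composition_model(rng: np.random.Generator) -> CompositionModel:
    """Random valid CompositionModel via Dirichlet draws."""
    mono = rng.dirichlet(np.ones(4))
    trans = np.vstack([rng.dirichlet(np.ones(4)) for _ in range(4)])
    return CompositionModel(mono=mono, trans=trans, source="random")


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
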