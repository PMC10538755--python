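import numpy as np
import pytest

from tortflow import founders as fnd
from tortflow import landscape as lsc
from tortflow import simulate as sim


@pytest.fixture(scope="session")
def freqs20():
    return fnd.generate_frequencies(seed=11)


@pytest.fixture(scope="session")
def small_panel(freqs20):
    return fnd.sample_founders(freqs20, n=60, seed=12)


@pytest.fixture()
def open_surface():
    """Uniform zero-resistance 25x25 surface at low density (K=3)."""
    return lsc.build_scenario_surface("no_barrier", density="low")


@pytest.fixture()
def flat_k24_surface():
    """Small uniform surface with a high per-cell capacity for mating tests."""
    return lsc.ResistanceSurface(
        resistance=np.zeros((5, 5)), carrying=np.full((5, 5), 24, dtype=int)
    )


def make_state(rows, cols, sexes, genotypes, loci):
    return sim.PopulationState(
        row=np.asarray(rows, dtype=np.int16),
        col=np.asarray(cols, dtype=np.int16),
        sex=np.asarray(sexes, dtype=np.int8),
        genotypes=np.asarray(genotypes, dtype=np.int16),
        loci=loci,
    )


@pytest.fixture()
def state_factory():
    return make_state
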