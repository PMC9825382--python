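import numpy as np
import pandas as pd
import pytest

from panmethyl import (
    MethylState,
    SelectivityProfile,
    SimConfig,
    TruthAntibody,
    enumerate_library,
    gen_proteome,
)
from panmethyl.kopl_design import AA19, FLANK_OFFSETS


@pytest.fixture(scope="session")
def me2_library():
    return enumerate_library(MethylState.me2)


@pytest.fixture
def uniform_profile():
    """Complete 6x19 profile with every cell at 1.0."""
    matrix = pd.DataFrame(1.0, index=list(AA19), columns=list(FLANK_OFFSETS))
    return SelectivityProfile(antibody_id="abU", state=MethylState.me2, matrix=matrix)


def make_profile(value=1.0, antibody_id="ab", state=MethylState.me2, cells=None):
    """Profile filled with ``value``; ``cells`` overrides {(offset, aa): v}."""
    matrix = pd.DataFrame(float(value), index=list(AA19), columns=list(FLANK_OFFSETS))
    for (off, aa), v in (cells or {}).items():
        matrix.at[aa, off] = v
    return SelectivityProfile(antibody_id=antibody_id, state=state, matrix=matrix)


@pytest.fixture(scope="session")
def small_proteome():
    cfg = SimConfig(seed=11, n_proteins=20, mean_length=200)
    return gen_proteome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
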