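import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from gutaa.endmembers import (
    DEFAULT_CASEIN_PROFILE,
    DEFAULT_CORNMEAL_PROFILE,
    DEFAULT_DIETS,
    DEFAULT_FRACTIONATION,
    EndmemberSet,
    build_endmember_set,
)


@pytest.fixture(scope="session")
def default_endmembers() -> EndmemberSet:
    return build_endmember_set(
        DEFAULT_DIETS, DEFAULT_CASEIN_PROFILE, DEFAULT_CORNMEAL_PROFILE, DEFAULT_FRACTIONATION
    )


@pytest.fixture()
def single_cell_endmembers() -> EndmemberSet:
    """One treatment, one AA, with the canonical C3/C4 separation of 14.4‰."""
    return EndmemberSet(
        delta_dietary={("T", "Val"): -26.5},
        delta_microbial={("T", "Val"): -12.1},
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200304)


def make_isotope_frame(deltas, treatment="T", aa="Val") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [f"{treatment}_m{i}" for i in range(len(deltas))],
            "treatment": treatment,
            "aa": aa,
            "delta_muscle": deltas,
        }
    )
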