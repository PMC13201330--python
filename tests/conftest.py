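import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pedigree():
    """Hand-built pedigree: 2 families, known offspring counts and sexes."""
    rows = [
        # family 0: sibling 1 has 2 offspring, sibling 2 has 3
        (0, 0, 1, 1, 0, 1),
        (0, 0, 1, 1, 1, 0),
        (0, 1, 2, 0, 2, 1),
        (0, 1, 2, 0, 3, 1),
        (0, 1, 2, 0, 4, 0),
        # family 1: one offspring each
        (1, 2, 1, 2, 5, 0),
        (1, 3, 2, 1, 6, 1),
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "parent_id",
            "sibling_index",
            "parent_genotype",
            "offspring_id",
            "offspring_sex",
        ],
    )
    frame["parent_genotype"] = frame["parent_genotype"].astype("Int64")
    frame["offspring_sex"] = frame["offspring_sex"].astype("Int64")
    return frame
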