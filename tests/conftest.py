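import numpy as np
import pandas as pd
import pytest

from hydroscreen.profiles import RANKS, AsvCountTable, TaxonomyTable
from hydroscreen.simulate import (
    ActivityProfileSpec,
    CommunitySimSpec,
    generate_activity_profile,
    generate_community,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_table():
    """Six samples × five ASVs with reactor/day/replicate metadata."""
    counts = pd.DataFrame(
        [
            [12000, 300, 40, 0, 5],
            [8000, 1500, 600, 2, 0],
            [15000, 200, 80, 10, 1],
            [9000, 900, 99, 0, 0],
            [20000, 50, 5, 3, 7],
            [11000, 400, 60, 1, 2],
        ],
        index=[f"S{i}" for i in range(6)],
        columns=[f"ASV{i}" for i in range(5)],
    )
    metadata = pd.DataFrame(
        {
            "reactor": ["R1"] * 3 + ["R2"] * 3,
            "day": [13, 20, 27, 13, 20, 27],
            "replicate": ["a"] * 6,
        },
        index=counts.index,
    )
    return AsvCountTable(counts=counts, metadata=metadata)


@pytest.fixture
def toy_taxonomy():
    rows = {
        "ASV0": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "s1"],
        "ASV1": ["Bacteria", "P1", "C1", "O1", "F1", "G1", "s2"],
        "ASV2": ["Bacteria", "P1", "C1", "O1", "F2", "G2", ""],
        "ASV3": ["Bacteria", "P2", "C2", "O2", "", "", ""],
        "ASV4": ["Bacteria", "P2", "C2", "O2", "F3", "G3", ""],
    }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One reactor's community with 10 planted responders, shared per session."""
    activity = generate_activity_profile(ActivityProfileSpec(), seed=11, reactor="R2")
    spec = CommunitySimSpec(n_asvs=400, n_responders=10, seed=11)
    table, taxonomy, truth = generate_community(spec, activity)
    return activity, table, taxonomy, truth
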