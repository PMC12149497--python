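import numpy as np
import pandas as pd
import pytest

from feedpattern.pedigree import Pedigree
from feedpattern.sim import EfficiencySimConfig, assign_design, simulate_efficiency_records


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return Pedigree.from_frame(
        pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
    )


@pytest.fixture
def fullsib_mating_pedigree() -> Pedigree:
    """Founders, two full sibs, and the full-sib mating's offspring."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {"animal": [1, 2, 3, 4, 5], "sire": [0, 0, 1, 1, 3], "dam": [0, 0, 2, 2, 4]}
        )
    )


def random_pedigree(n: int, seed: int) -> Pedigree:
    """Random topological pedigree where later animals draw earlier parents."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(2, n):
        if rng.random() < 0.8:
            sire[i], dam[i] = sorted(rng.choice(i, size=2, replace=False))
    return Pedigree(sire=sire, dam=dam, ids=np.arange(1, n + 1))


@pytest.fixture(scope="session")
def herd_records():
    """A 6000-cow trait-record simulation shared by the slower RFI checks."""
    n = 6000
    cows = assign_design(n, n_cohorts=60, seed=11)
    cows.insert(0, "cow_id", [f"c{i:05d}" for i in range(n)])
    recs = simulate_efficiency_records(cows, EfficiencySimConfig(), seed=12)
    return cows, recs
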