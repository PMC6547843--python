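import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phenorep.cohort import (
    TIME_GROUPS,
    AnimalRecord,
    MeasureSpec,
    default_catalogue,
    default_params,
    generate_cohort,
    reference_study_params,
    simulate_measures,
)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def params():
    return default_params(seed=7)


@pytest.fixture(scope="session")
def cohort(params):
    return generate_cohort(params)


@pytest.fixture(scope="session")
def table(cohort, params, catalogue):
    return simulate_measures(cohort, params, catalogue)


@pytest.fixture(scope="session")
def dropout_params():
    return reference_study_params(seed=7)


@pytest.fixture(scope="session")
def dropout_cohort(dropout_params):
    return generate_cohort(dropout_params)


@pytest.fixture(scope="session")
def dropout_table(dropout_cohort, dropout_params, catalogue):
    return simulate_measures(dropout_cohort, dropout_params, catalogue)


def make_balanced_design(n_cages_per_strain: int, rng: np.random.Generator):
    """A hand-built balanced split-plot cohort plus random values for one
    measure — used against the brute-force sums-of-squares oracle."""
    records = []
    for pair in range(1, n_cages_per_strain + 1):
        for strain in ("B6", "D2"):
            cage = f"{strain}_c{pair}"
            for slot, tg in enumerate(TIME_GROUPS, start=1):
                records.append(
                    AnimalRecord(
                        animal_id=f"{cage}_m{slot}", strain=strain, cage_id=cage,
                        pair_id=pair, time_group=tg, batch=1,
                    )
                )
    values = rng.normal(size=len(records))
    spec = MeasureSpec("toy", "OF")
    table = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "measure_id": "toy",
            "trial": np.nan,
            "value": values,
            "raw_value": values,
        }
    )
    return records, table, spec
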