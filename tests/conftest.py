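import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from iscn.cohort import CohortConfig, PlantedEffect, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 regions in 3 communities, 6 subjects: big enough to exercise every stage."""
    config = CohortConfig(
        n_subjects=6,
        n_regions=12,
        voxels_per_region=80,
        n_communities=3,
        planted_effects=(PlantedEffect(2, "affective_dysregulation", 0.5),),
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_screening_roster():
    """Roster encoding the published screening flow.

    37 biomarker-AD-compatible records, of which 2 have CDR 2 and 2 have the
    logopenic (lvPPA) phenotype; applying the exclusion rules retains 33.
    """
    rows = []
    for i in range(37):
        cdr = 2.0 if i in (10, 20) else (1.0 if i % 2 else 0.5)
        phenotype = "lvPPA" if i in (25, 30) else "typical"
        rows.append(
            {
                "subject_id": f"P{i + 1:03d}",
                "abeta42": 520.0,
                "ttau": 700.0,
                "ptau181": 120.0,
                "amyloid_pet_positive": pd.NA,
                "cdr_global": cdr,
                "phenotype": phenotype,
            }
        )
    return pd.DataFrame(rows)
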