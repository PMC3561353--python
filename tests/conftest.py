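import numpy as np
import pandas as pd
import pytest

import domestigrow as dg


@pytest.fixture(scope="session")
def study_dataset():
    """One full simulated data set at the study's default design and parameters."""
    return dg.simulate_dataset(seed=7)


@pytest.fixture(scope="session")
def small_design():
    return dg.BreedingDesign(offspring_per_family_per_tank=5)


def make_phenotypes(weights: dict) -> pd.DataFrame:
    """Phenotype frame from {(family, group, treatment, tank): [weights...]}."""
    rows = []
    i = 0
    for (family, group, treatment, tank), ws in weights.items():
        for w in ws:
            i += 1
            rows.append(
                dict(id=f"x{i}", family=family, group=group, treatment=treatment,
                     tank=tank, weight_g=float(w),
                     length_cm=float(np.cbrt(100 * w / 1.28)))
            )
    return pd.DataFrame(rows)
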