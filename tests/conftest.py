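import numpy as np
import pandas as pd
import pytest

from oxcpk.io import PKDataset
from oxcpk.model import PopulationParameters, reference_parameters
from oxcpk.simulate import CohortConfig, generate


@pytest.fixture(scope="session")
def ref_pop() -> PopulationParameters:
    return reference_parameters()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-arm cohort reused by estimation and evaluation tests."""
    return generate(CohortConfig(n_sparse=60, n_rich=10, seed=11))


def make_dataset(subjects: list[dict]) -> PKDataset:
    """Build an event-record table from per-subject specs.

    Each spec: {id, wt, dose, (tau for steady state | None for single dose),
    times: [...], dvs: [...]} plus optional covariates.
    """
    rows = []
    for s in subjects:
        tau = s.get("tau")
        common = dict(
            ID=s["id"], WT=s.get("wt", 66.0), AGE=s.get("age", 40.0),
            SEX=s.get("sex", 1), GFR=s.get("gfr", 100.0),
            EIASM=s.get("eiasm", 0), STUDY=1 if tau else 2,
        )
        for k, v in s.items():
            if k.isupper():
                common[k] = v
        rows.append(dict(common, TIME=0.0, AMT=s["dose"], DV=np.nan, EVID=1,
                         MDV=1, SS=1 if tau else 0, II=tau or 0.0))
        for t, dv in zip(s["times"], s["dvs"]):
            rows.append(dict(common, TIME=t, AMT=np.nan, DV=dv, EVID=0,
                             MDV=0, SS=0, II=0.0))
    return PKDataset(pd.DataFrame(rows))
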