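import numpy as np
import pandas as pd
import pytest

from datsbr import synth
from datsbr.normative import NormativeAgeModel


@pytest.fixture(scope="session")
def reference_cohort():
    """Calibrated cohort (40 HC / 36 MCI-LB / 51 DLB), fixed seed."""
    cfg = synth.reference_cohort_config(seed=7)
    subjects, sbr = synth.simulate_cohort(cfg)
    return cfg, subjects, sbr


@pytest.fixture(scope="session")
def reference_ztable(reference_cohort):
    _, _, sbr = reference_cohort
    norm = NormativeAgeModel.from_dataframe(sbr).fit()
    return norm, norm.zscore_table(sbr, include_sides=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
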