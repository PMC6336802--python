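import numpy as np
import pandas as pd
import pytest

from fepstrat.panss import ITEM_NAMES
from fepstrat.simulate import (
    DEFAULT_INFORMATIVE_ITEMS,
    SUBTYPES,
    SyntheticCohortConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (n=325) under the default calibration."""
    return generate_cohort(SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for moment-recovery checks."""
    return generate_cohort(SyntheticCohortConfig(n_patients=2000, seed=2))


def strong_separation_signature() -> pd.DataFrame:
    """Noise-robust 4-subtype item signature on the 30-item instrument.

    Level-1 items separate the branches by 4 points, split items separate
    A from B within each branch by 4 points; everything else is flat.
    """
    sig = pd.DataFrame(4.0, index=list(SUBTYPES), columns=list(ITEM_NAMES))
    lvl1 = list(DEFAULT_INFORMATIVE_ITEMS["level1"])
    c1 = list(DEFAULT_INFORMATIVE_ITEMS["C1"])
    c2 = list(DEFAULT_INFORMATIVE_ITEMS["C2"])
    sig.loc[["C1A", "C1B"], lvl1] = 6.0
    sig.loc[["C2A", "C2B"], lvl1] = 2.0
    sig.loc["C1A", c1] = 6.0
    sig.loc["C1B", c1] = 2.0
    sig.loc["C2A", c2] = 6.0
    sig.loc["C2B", c2] = 2.0
    return sig


@pytest.fixture(scope="session")
def separable_cohort():
    """Cleanly separable cohort: strong signature, low noise."""
    cfg = SyntheticCohortConfig(
        n_patients=160,
        item_signature=strong_separation_signature(),
        severity_sd=0.2,
        item_noise_sd=0.4,
        seed=5,
    )
    return generate_cohort(cfg)


def all_c1a_config(n: int, seed: int, **kwargs) -> SyntheticCohortConfig:
    """Config drawing every patient from the high-severity risk subtype."""
    return SyntheticCohortConfig(
        n_patients=n,
        subtype_proportions={"C1A": 1.0, "C1B": 0.0, "C2A": 0.0, "C2B": 0.0},
        seed=seed,
        **kwargs,
    )
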