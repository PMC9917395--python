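import numpy as np
import pandas as pd
import pytest

from dditraj.gbtm import Panel
from dditraj.preprocess import block_daily_max
from dditraj.synthetic import SimConfig, generate_cohort


def two_group_config(n=300, sigma=1.5, seed=0):
    """Well-separated two-class world: flat means 2 vs 12 mg/L."""
    return SimConfig(
        n_patients=n,
        group_props=(0.6, 0.4),
        group_polys=((2.0,), (12.0,)),
        sigma=sigma,
        followup_mean=(12.0, 12.0),
        mortality_logit=(-3.0, -1.0),
        seed=seed,
    )


def included_panel(bundle, min_days=3):
    """Daily-max blocking + minimum-days rule; returns (panel, true labels)."""
    blocked = block_daily_max(bundle.measurements)
    counts = blocked.groupby("patient_id")["day"].nunique()
    keep = counts[counts >= min_days].index
    blocked = blocked[blocked["patient_id"].isin(keep)]
    panel = Panel.from_long(blocked)
    mask = bundle.covariates["patient_id"].isin(panel.ids).to_numpy()
    return panel, np.asarray(bundle.true_labels)[mask]


@pytest.fixture(scope="session")
def default_bundle():
    return generate_cohort(SimConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def default_panel(default_bundle):
    return included_panel(default_bundle)


@pytest.fixture(scope="session")
def two_group_bundle():
    return generate_cohort(two_group_config(seed=11))


@pytest.fixture(scope="session")
def two_group_panel(two_group_bundle):
    return included_panel(two_group_bundle)


@pytest.fixture()
def tiny_panel():
    """3 patients x 4 days, values chosen to include a censored-high point."""
    df = pd.DataFrame({
        "patient_id": np.repeat([1, 2, 3], 4),
        "day": np.tile([0, 1, 2, 3], 3),
        "value": [1.0, 2.0, 1.5, 2.5,
                  12.0, 10.0, 11.0, 9.0,
                  40.0, 38.0, 35.0, 30.0],
    })
    return Panel.from_long(df)
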