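import datetime as dt

import numpy as np
import pandas as pd
import pytest

from lysiphen import simulate as sim
from lysiphen.simulate import IrrigationSchedule, PotParams, variety_preset


@pytest.fixture(scope="session")
def noiseless_pot() -> PotParams:
    return PotParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def xiangye_drydown(noiseless_pot):
    """Noiseless progressive drydown of a Xiangye-parameterised pot (26 days)."""
    return sim.simulate_drydown(
        variety_preset("Xiangye"),
        pot=noiseless_pot,
        schedule=IrrigationSchedule(policy="none", well_days=1),
        days=26,
        seed=11,
    )


@pytest.fixture(scope="session")
def ck_week(noiseless_pot):
    """Noiseless well-watered control pot for one week."""
    return sim.simulate_drydown(
        variety_preset("Xiangye"),
        pot=noiseless_pot,
        schedule=IrrigationSchedule(policy="ck"),
        days=7,
        seed=5,
    )


def hinge(vwc, a, k, theta):
    v = np.asarray(vwc, dtype=float)
    return a + k * np.minimum(v - theta, 0.0)


@pytest.fixture(scope="session")
def exact_hinge_points():
    """Noiseless two-segment data: a=1, k=3, theta=0.15, VWC 0.30 -> 0.05."""
    v = np.linspace(0.30, 0.05, 26)
    return np.column_stack([v, hinge(v, 1.0, 3.0, 0.15)])


def make_weight_frame(start, weights, step_minutes=3, flags=None):
    idx = pd.date_range(start, periods=len(weights), freq=f"{step_minutes}min")
    return pd.DataFrame(
        {"weight_g": np.asarray(weights, dtype=float),
         "irrigation_flag": flags if flags is not None else False},
        index=idx,
    )
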