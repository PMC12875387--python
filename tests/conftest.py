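import datetime as dt

import numpy as np
import pytest

from chamberflux.campaign import GASES, FluxRecord, QCFlag
from chamberflux.simulate import SimulationParams, simulate_campaign

BASE_TIME = dt.datetime(2024, 3, 13, 9, 30)


def make_flux_records(day_flux_pairs, gas_name="N2O", plot="P1", qc=QCFlag.PASS):
    """FluxRecords at fractional days since a fixed campaign start."""
    gas = GASES[gas_name]
    return [
        FluxRecord(plot, gas, BASE_TIME + dt.timedelta(days=float(d)),
                   float(f), 0.0, 1.0, 4, qc)
        for d, f in day_flux_pairs
    ]


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic campaign, shared across tests (seed fixed)."""
    return simulate_campaign(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240313)
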