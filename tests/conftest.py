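import numpy as np
import pandas as pd
import pytest

from foray.detection import (
    assemble_monthly,
    assign_nights,
    count_active_nights,
    detect_etes,
)
from foray.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_uniform():
    """Six months, constant per-night excursion probability 0.15, full activity."""
    cfg = SimConfig(rng_seed=42, n_months=6, excursion_prob=0.15,
                    activity=1.0, collar_failure_rate=0.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_uniform_tables(sim_uniform):
    """The uniform simulation run through the detection pipeline."""
    nf = assign_nights(sim_uniform.fixes)
    etes = detect_etes(nf, sim_uniform.territory_map)
    active = count_active_nights(nf)
    monthly = assemble_monthly(etes, active, sim_uniform.animals)
    return {"night_fixes": nf, "etes": etes, "active": active, "monthly": monthly}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_fixes(rows):
    """Helper: fix table from (animal, group, timestamp, x, y) tuples."""
    return pd.DataFrame(rows, columns=["animal_id", "group_id", "timestamp", "x", "y"]).assign(
        timestamp=lambda d: pd.to_datetime(d["timestamp"])
    )
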