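import math

import numpy as np
import pytest

from island_assembly import (
    ColonistRecord,
    IslandDataset,
    ParameterSet,
    simulate_island,
)

DF = "DF-type"
NDF = "non-DF-type"
TWO_CLASS_FRACTIONS = {DF: 0.163, NDF: 0.837}


@pytest.fixture
def eight_colonist_dataset() -> IslandDataset:
    """Eight colonisations on a 4 My island with a 1000-species pool."""
    records = [
        ColonistRecord(
            label="radiation_A",
            status=4,
            lineage_class=DF,
            colonisation_time=3.2,
            branching_times=(1.9, 1.2, 0.8, 0.5),
        ),
        ColonistRecord(
            label="radiation_B",
            status=4,
            lineage_class=NDF,
            colonisation_time=3.5,
            branching_times=(2.1, 1.0),
        ),
        ColonistRecord(
            label="singleton_endemic",
            status=4,
            lineage_class=NDF,
            colonisation_time=2.8,
        ),
        ColonistRecord(
            label="endemic_plus_mainland",
            status=5,
            lineage_class=NDF,
            colonisation_time=1.6,
            branching_times=(0.9,),
        ),
        ColonistRecord(
            label="recent_nonendemic",
            status=3,
            lineage_class=NDF,
            colonisation_time=0.4,
        ),
        ColonistRecord(
            label="older_nonendemic",
            status=3,
            lineage_class=NDF,
            colonisation_time=1.1,
        ),
        ColonistRecord(
            label="upper_bound_1",
            status=2,
            lineage_class=NDF,
            colonisation_time=4.0,
            max_age=True,
        ),
        ColonistRecord(
            label="upper_bound_2",
            status=2,
            lineage_class=NDF,
            colonisation_time=2.3,
            max_age=True,
        ),
    ]
    return IslandDataset(
        island_age=4.0,
        M=1000,
        class_fractions=TWO_CLASS_FRACTIONS,
        colonists=tuple(records),
    )


@pytest.fixture
def small_sim_dataset() -> IslandDataset:
    """A small simulated two-class dataset for fitting tests."""
    params = {
        DF: ParameterSet(gamma=0.002, lambda_c=2.0, lambda_a=0.5, mu=1.0, K_prime=10),
        NDF: ParameterSet(gamma=0.002, lambda_c=0.2, lambda_a=0.5, mu=0.1),
    }
    return simulate_island(
        params, 1000, TWO_CLASS_FRACTIONS, 4.0, seed=11, keep_events=False
    ).dataset


def assert_close(a: float, b: float, tol: float = 1e-8) -> None:
    assert math.isfinite(a) and math.isfinite(b), (a, b)
    assert abs(a - b) <= tol, f"{a} != {b} (tol {tol})"
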