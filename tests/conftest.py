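import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from screenplan.simulate import CohortSpec, TestSpec, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=60, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230117)


@pytest.fixture(scope="session")
def large_independent_cohort():
    """10,000 participants per device group, conditionally independent trials."""
    spec = CohortSpec(
        n_participants=20_000,
        pi=0.5,
        sigma=0.0,
        tests={"A": TestSpec(0.848, 0.509), "B": TestSpec(0.842, 0.311), "C": TestSpec(0.940, 0.515)},
        dependence=0.0,
        seed=7,
    )
    return spec, simulate_cohort(spec)


@pytest.fixture()
def tiny_cohort():
    """Hand-built six-participant cohort with known confusion counts.

    At threshold 2 on test A: headphone users p1 (2 hits) and p2 (1 hit),
    loudspeaker users p3..p6 with 0, 2, 1, 0 headphone-indicating trials
    → tp=1, fn=1, tn=3, fp=1.
    """
    rows = []
    outcomes = {
        "p1": ("headphones", [1, 1]),
        "p2": ("headphones", [1, 0]),
        "p3": ("loudspeakers", [0, 0]),
        "p4": ("loudspeakers", [1, 1]),
        "p5": ("loudspeakers", [0, 1]),
        "p6": ("loudspeakers", [0, 0]),
    }
    for pid, (device, trials) in outcomes.items():
        rows.append(
            {
                "participant_id": pid,
                "device": device,
                "self_report": device,
                "testA_1": trials[0],
                "testA_2": trials[1],
            }
        )
    return pd.DataFrame(rows)
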