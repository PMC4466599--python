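import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import childcheck as cc

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    return cc.ReferenceTable.load_packaged()


@pytest.fixture(scope="session")
def ruleset():
    return cc.load_default_ruleset()


@pytest.fixture
def child():
    return cc.ChildRecord(
        age=10.0,
        sex="male",
        ethnicity="Asian",
        height_cm=145.0,
        weight_kg=50.0,
        lifestyle={
            "fruit_veg_portions": 3,
            "mvpa_minutes": 70,
            "screen_hours": 4,
            "sugary_drinks": 0,
            "sleep_hours": 10,
            "breakfast_days": 7,
        },
        bullied=True,
        victimised=False,
        sedentary_hours=4.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded cohort reused by read-only tests."""
    return cc.generate_cohort_frame(cc.CohortConfig(n=1500, seed=11))


def brute_force_auc(scores, outcomes):
    """Exhaustive case-control pair counting (Mann-Whitney), used as oracle."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, float)
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    wins = ties = 0
    for a in cases:
        for b in controls:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def brute_force_low_cutoff(scores, outcomes):
    """Enumerate every candidate cut-off; max NPV, ties to largest Low group."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, float)
    best = None
    for c in np.concatenate(([scores.min() - 1.0], np.unique(scores))):
        mask = scores <= c
        if not mask.any():
            continue
        npv = float(np.mean(outcomes[mask] == 0))
        key = (npv, int(mask.sum()))
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1], best[0][0]
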