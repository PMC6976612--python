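import dataclasses

import numpy as np
import pytest

from vchinrest import (
    DisplayCalibration,
    PopulationConfig,
    SessionConfig,
    SessionRecord,
    compute_lpd,
    generate_population,
    run_cohort,
)


@pytest.fixture
def cal2() -> DisplayCalibration:
    """Calibration with LPD = 2 px/mm."""
    return compute_lpd(171.20)


@pytest.fixture
def cal1() -> DisplayCalibration:
    """Calibration with LPD = 1 px/mm."""
    return compute_lpd(85.60)


@pytest.fixture(scope="session")
def default_cohort():
    """1000 default observers, eccentricity randomized 50/50, master seed 42.

    Shared by the cohort-level tests; one pipeline run kept session-scoped
    to keep the suite fast.
    """
    pop = generate_population(
        dataclasses.replace(PopulationConfig(), n=1000, seed=42))
    return pop, run_cohort(pop, SessionConfig(), master_seed=42)


def make_record(session_id="s0", ecc=4.0, crowding=2.0, dyslexia=False,
                age=26.0, d=(500.0, 505.0, 495.0), percent_correct=0.85):
    """Hand-built session record for analysis unit tests."""
    return SessionRecord(
        session_id=session_id,
        calibration=compute_lpd(342.4),
        alpha_deg=13.5,
        eccentricity_deg=ecc,
        distance_estimates_mm={"pre": d[0], "mid": d[1], "post": d[2]},
        true_distances_mm={"pre": d[0], "mid": d[1], "post": d[2]},
        block_thresholds_deg=[crowding, crowding],
        crowding_effect_deg=crowding,
        percent_correct=percent_correct,
        trial_log=[],
        observer_info={"age": age, "dyslexia": dyslexia, "bouma_ratio": 0.38,
                       "blindspot_entry_deg": 13.5, "true_distance_mm": 500.0,
                       "lapse": 0.01},
    )


@pytest.fixture
def record_factory():
    return make_record
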