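"""Shared fixtures: hand-built records and session-scoped synthetic benchmarks."""

import numpy as np
import pytest

from bolusrec import (
    BasalSegment, BolusEvent, GlucoseSample, MealEvent, SubjectRecord,
    make_benchmark,
)


def flat_record(hours: float = 12.0, bg: float = 120.0, subject_id: str = "fix",
                basal_rate: float = 1.0) -> SubjectRecord:
    """Record with constant measured glucose every 5 min and a basal profile
    that alternates so the basal channel is not constant."""
    n = int(hours * 12)
    glucose = [GlucoseSample(time=5 * k, value=bg) for k in range(n + 1)]
    basal = []
    t = 0
    rates = [basal_rate, basal_rate * 1.4]
    i = 0
    while t < 5 * n:
        end = min(t + 360, 5 * n)
        basal.append(BasalSegment(start=t, end=end, rate=rates[i % 2]))
        t = end
        i += 1
    return SubjectRecord(subject_id=subject_id, glucose=glucose, basal=basal)


def add_anchored_event(rec: SubjectRecord, bolus_time: int, dose: float,
                       carbs: float) -> None:
    """Insert a bolus and its anchored meal 10 min later (already clean)."""
    rec.boluses.append(BolusEvent(time=bolus_time, dose=dose,
                                  bw_carb_input=carbs))
    rec.meals.append(MealEvent(time=bolus_time + 10, carbs=carbs,
                               source="smartphone", shifted=True))
    rec.boluses.sort(key=lambda b: b.time)
    rec.meals.sort(key=lambda m: m.time)


@pytest.fixture
def record_12h():
    return flat_record(12.0)


@pytest.fixture(scope="session")
def bench3():
    """Three 30-day synthetic subjects (seed 42): the reduced benchmark used
    by the end-to-end learnability and ablation checks."""
    records, truths, manifest = make_benchmark(n_subjects=3, seed=42, days=30)
    return records, truths, manifest


@pytest.fixture(scope="session")
def sim_subject():
    """One 30-day simulated subject plus ground truth (cheap, reused)."""
    from bolusrec import SimConfig, simulate_subject_with_truth
    return simulate_subject_with_truth(SimConfig(seed=7, days=30))
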