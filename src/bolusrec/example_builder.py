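"""Turning pre-processed records into recommendation examples.

A recommendation example asks: given everything observed up to the present
time ``t``, how large should the meal (carbs, g) or insulin bolus (units) at
``t+10`` be so that blood glucose reaches a target value at ``t+10+tau``?
Each qualifying event yields one example per horizon ``tau`` in
{30, 35, ..., 90} minutes; the 13 examples share the label (the recorded
event magnitude) but differ in the target-glucose and horizon features.

Four scenario datasets are supported:

* ``carbs_pm_b`` - all carbohydrate intake events (with or without a bolus);
* ``carbs_m_b``  - carb events without an associated bolus (hypo corrections,
  pre-exercise and bedtime snacks);
* ``bolus_pm_c`` - all regular boluses;
* ``bolus_p_c``  - boluses paired with a meal 10 min later; the planned carb
  amount at ``t+20`` is an extra input feature.

*Inertial* examples admit no meal/bolus in the prediction window other than
the queried event (plus, for ``bolus_p_c``, its paired meal); *unrestricted*
examples admit anything.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import MEAL_OFFSET, is_admissible
from .timeseries_core import (
    DAY, STEP, MealEvent, SubjectRecord, ValidationError, to_grid,
)

logger = logging.getLogger("bolusrec")

SCENARIOS = ("carbs_pm_b", "carbs_m_b", "bolus_pm_c", "bolus_p_c")
CARB_SCENARIOS = ("carbs_pm_b", "carbs_m_b")
BOLUS_SCENARIOS = ("bolus_pm_c", "bolus_p_c")

#: prediction horizons, minutes
TAU_GRID = tuple(range(30, 95, 5))
#: history window length in 5-min steps, covering (t-355, t]
HISTORY_STEPS = 72

#: time-of-day window boundaries, minutes past midnight (left-closed)
TOD_BOUNDS = (0, 360, 600, 840, 1080, 1440)


@dataclass
class RecommendationExample:
    subject_id: str
    t: int                        # present grid time, minutes
    history: np.ndarray           # (72, 4): bg, carbs, bolus, basal
    window_events: np.ndarray     # ((10+tau)/5, 3): carbs, bolus, basal over (t, t+10+tau]
    target_bg: float              # G at t+10+tau, mg/dL
    tau: int                      # horizon, minutes
    tod_avg: float                # training-split ToD mean of the label (g or u)
    label: float                  # C at t+10 (g) or B at t+10 (u)
    inertial: bool
    scenario: str
    wall_minutes: int             # wall clock of the event time t+10
    planned_carbs: Optional[float] = None   # C at t+20, bolus_p_c only


def tod_interval(wall_clock) -> int:
    """Map a wall-clock time to its time-of-day window 1..5.

    Windows: [12am,6am) early breakfast/late snacks, [6am,10am) breakfast,
    [10am,2pm) lunch, [2pm,6pm) dinner, [6pm,12am) late dinner/snacks.
    Accepts minutes past midnight or a :class:`datetime.time`.
    """
    if isinstance(wall_clock, datetime.time):
        minutes = wall_clock.hour * 60 + wall_clock.minute
    else:
        minutes = int(wall_clock) % DAY
    for k in range(5):
        if TOD_BOUNDS[k] <= minutes < TOD_BOUNDS[k + 1]:
            return k + 1
    raise ValueError(f"bad wall clock {wall_clock!r}")  # pragma: no cover


def classify_meal(meal: MealEvent, record: SubjectRecord) -> str:
    """``with_bolus`` iff a bolus exists exactly 10 min before the meal
    (guaranteed for anchored bolus-wizard meals), else ``without_bolus``."""
    for b in record.boluses:
        if b.time == meal.time - MEAL_OFFSET:
            return "with_bolus"
    return "without_bolus"


def is_inertial(event_time: int, tau: int, scenario: str,
                record: SubjectRecord) -> bool:
    """True iff no meal/bolus occurs in ``(t, t+10+tau]`` other than the
    queried event at ``t+10`` (and, for ``bolus_p_c``, its meal at ``t+20``)."""
    from .timeseries_core import grid_index
    snap = lambda x: grid_index(x) * STEP   # compare on the 5-min grid
    t = snap(event_time) - MEAL_OFFSET
    end = t + MEAL_OFFSET + tau
    meals_in = [m for m in record.meals if t < snap(m.time) <= end]
    boluses_in = [b for b in record.boluses if t < snap(b.time) <= end]
    if scenario in CARB_SCENARIOS:
        return (not boluses_in and len(meals_in) == 1
                and snap(meals_in[0].time) == snap(event_time))
    if scenario == "bolus_pm_c":
        return (not meals_in and len(boluses_in) == 1
                and snap(boluses_in[0].time) == snap(event_time))
    if scenario == "bolus_p_c":
        return (len(boluses_in) == 1 and snap(boluses_in[0].time) == snap(event_time)
                and len(meals_in) == 1
                and snap(meals_in[0].time) == snap(event_time) + MEAL_OFFSET)
    raise ValueError(f"unknown scenario {scenario!r}")


def _check_anchored(record: SubjectRecord) -> None:
    for b in record.boluses:
        if b.bw_carb_input and b.bw_carb_input > 0:
            if not any(m.time == b.time + MEAL_OFFSET and m.carbs == b.bw_carb_input
                       for m in record.meals):
                raise ValidationError(
                    f"record not anchored: bolus at t={b.time} with bolus-wizard "
                    f"carbs {b.bw_carb_input} g has no meal at t+{MEAL_OFFSET}; "
                    "run anchor_meals first (or pass require_anchored=False)")


def _scenario_events(record: SubjectRecord, scenario: str):
    """Yield (event_time, label, planned_carbs) for a scenario's query events."""
    if scenario in CARB_SCENARIOS:
        for m in record.meals:
            if m.carbs <= 0:
                continue
            if scenario == "carbs_m_b" and classify_meal(m, record) == "with_bolus":
                continue
            yield m.time, m.carbs, None
    else:
        meal_at = {m.time: m for m in record.meals}
        for b in record.boluses:
            if b.kind == "dual" or b.dose <= 0:
                continue    # dual boluses are never prediction labels
            paired = meal_at.get(b.time + MEAL_OFFSET)
            if scenario == "bolus_p_c":
                if paired is None:
                    continue
                yield b.time, b.dose, paired.carbs
            else:
                yield b.time, b.dose, None


def _tod_averages(record: SubjectRecord, scenario: str) -> dict:
    """Per-ToD-window mean label over the subject's TRAINING split, with the
    global training mean as fallback for empty windows."""
    if record.split is None:
        raise ValidationError("record.split not set; run assign_split first")
    train_end = record.split[0]
    labels, windows = [], []
    for e, label, _ in _scenario_events(record, scenario):
        if e < train_end:
            labels.append(label)
            windows.append(tod_interval(record.wall_clock(e)))
    if not labels:
        logger.warning("no training events for %s; ToD averages default to 0",
                       scenario)
        return {k: 0.0 for k in range(1, 6)}
    labels = np.asarray(labels, dtype=float)
    windows = np.asarray(windows)
    mu = float(labels.mean())
    return {k: (float(labels[windows == k].mean()) if np.any(windows == k) else mu)
            for k in range(1, 6)}


def build_examples(record: SubjectRecord, scenario: str,
                   example_class: str = "unrestricted",
                   require_anchored: bool = True) -> list[RecommendationExample]:
    """Extract all admissible recommendation examples from one record.

    The record must be anchored and gap-interpolated, with split boundaries
    assigned (the ToD-average feature is computed on the training split only).
    Examples are returned in physical units; scaling happens at batch time.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if example_class not in ("inertial", "unrestricted"):
        raise ValueError(f"unknown example class {example_class!r}")
    if require_anchored:
        _check_anchored(record)
    grid = to_grid(record)
    n = len(grid)
    by_time = {s.time: s for s in record.glucose}
    tod_mu = _tod_averages(record, scenario)

    from .timeseries_core import grid_index
    out = []
    for e, label, planned in _scenario_events(record, scenario):
        e = grid_index(e) * STEP    # events are queried at their grid bin
        t = e - MEAL_OFFSET
        kt = t // STEP
        if kt < HISTORY_STEPS - 1:
            continue                      # not enough history
        hist = np.column_stack([
            grid.bg[kt - HISTORY_STEPS + 1: kt + 1],
            grid.carbs[kt - HISTORY_STEPS + 1: kt + 1],
            grid.bolus[kt - HISTORY_STEPS + 1: kt + 1],
            grid.basal[kt - HISTORY_STEPS + 1: kt + 1],
        ])
        if np.isnan(hist[:, 0]).any():
            continue                      # un-interpolated hole in history
        wall = record.wall_clock(e)
        tod_avg = tod_mu[tod_interval(wall)]
        for tau in TAU_GRID:
            k_end = (e + tau) // STEP
            if k_end >= n:
                continue                  # horizon past record end
            if not is_admissible(t, tau, record, _index=by_time):
                continue
            inert = is_inertial(e, tau, scenario, record)
            if example_class == "inertial" and not inert:
                continue
            target = by_time.get(e + tau)
            if target is None:
                continue
            steps = (MEAL_OFFSET + tau) // STEP
            win = np.column_stack([
                grid.carbs[kt + 1: kt + 1 + steps],
                grid.bolus[kt + 1: kt + 1 + steps],
                grid.basal[kt + 1: kt + 1 + steps],
            ]).copy()
            # mask the queried event (and the paired meal for bolus_p_c):
            # the label must never leak into the input channels
            if scenario in CARB_SCENARIOS:
                win[1, 0] -= label              # meal at t+10 (row j=2)
            else:
                win[1, 1] -= label              # bolus at t+10
                if scenario == "bolus_p_c":
                    win[3, 0] -= planned        # paired meal at t+20 (row j=4)
            out.append(RecommendationExample(
                subject_id=record.subject_id, t=t, history=hist,
                window_events=win, target_bg=float(target.value), tau=tau,
                tod_avg=tod_avg, label=float(label), inertial=inert,
                scenario=scenario, wall_minutes=wall,
                planned_carbs=planned))
    return out


def eligibility_report(records: list[SubjectRecord], scenario: str,
                       min_events: int = 50) -> pd.DataFrame:
    """Per-subject event counts by split and an eligibility flag.

    A subject is eligible when every split contains at least one query event;
    for ``carbs_m_b`` additionally at least ``min_events`` unbolused carb
    events overall (small populations make model fitting ineffective).
    """
    rows = []
    for rec in records:
        if rec.split is None:
            raise ValidationError(f"subject {rec.subject_id}: split not set")
        train_end, val_end = rec.split
        events = [e for e, _, _ in _scenario_events(rec, scenario)]
        n_train = sum(e < train_end for e in events)
        n_val = sum(train_end <= e < val_end for e in events)
        n_test = sum(e >= val_end for e in events)
        eligible = n_train > 0 and n_val > 0 and n_test > 0
        if scenario == "carbs_m_b":
            eligible = eligible and len(events) >= min_events
        rows.append({"subject_id": rec.subject_id, "train_events": n_train,
                     "val_events": n_val, "test_events": n_test,
                     "total_events": len(events), "eligible": eligible})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Columnar serialization (one row per example; windows as fixed-width arrays)
# ---------------------------------------------------------------------------

def save_examples(examples: list[RecommendationExample], path) -> None:
    n = len(examples)
    max_w = max((len(ex.window_events) for ex in examples), default=0)
    win = np.full((n, max_w, 3), np.nan)
    for i, ex in enumerate(examples):
        win[i, :len(ex.window_events)] = ex.window_events
    np.savez_compressed(
        path,
        subject_id=np.array([ex.subject_id for ex in examples]),
        t=np.array([ex.t for ex in examples]),
        history=np.array([ex.history for ex in examples]) if n else np.zeros((0, HISTORY_STEPS, 4)),
        window=win,
        target_bg=np.array([ex.target_bg for ex in examples]),
        tau=np.array([ex.tau for ex in examples]),
        tod_avg=np.array([ex.tod_avg for ex in examples]),
        label=np.array([ex.label for ex in examples]),
        inertial=np.array([ex.inertial for ex in examples]),
        scenario=np.array([ex.scenario for ex in examples]),
        wall_minutes=np.array([ex.wall_minutes for ex in examples]),
        planned_carbs=np.array([np.nan if ex.planned_carbs is None else ex.planned_carbs
                                for ex in examples]),
    )


def load_examples(path) -> list[RecommendationExample]:
    z = np.load(path, allow_pickle=False)
    out = []
    for i in range(len(z["t"])):
        steps = (MEAL_OFFSET + int(z["tau"][i])) // STEP
        pc = float(z["planned_carbs"][i])
        out.append(RecommendationExample(
            subject_id=str(z["subject_id"][i]), t=int(z["t"][i]),
            history=z["history"][i], window_events=z["window"][i, :steps],
            target_bg=float(z["target_bg"][i]), tau=int(z["tau"][i]),
            tod_avg=float(z["tod_avg"][i]), label=float(z["label"][i]),
            inertial=bool(z["inertial"][i]), scenario=str(z["scenario"][i]),
            wall_minutes=int(z["wall_minutes"][i]),
            planned_carbs=None if np.isnan(pc) else pc))
    return out
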