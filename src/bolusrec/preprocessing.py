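"""Pre-processing: meal-bolus anchoring, gap interpolation, admissibility, scaling.

Self-reported meal timestamps from a smartphone interface are unreliable: they
often precede the pump-recorded bolus even though subjects were advised to
bolus 10 minutes *before* eating.  ``anchor_meals`` therefore re-times every
meal that has an associated bolus-wizard carb entry to exactly 10 minutes
after that bolus, and uses the bolus-wizard carb amount (which is what the
dose was actually computed from) as the meal's carb value.  Missing smartphone
logs are reconstructed the same way.

CGM gaps are linearly interpolated, and examples built on heavily interpolated
stretches are rejected by :func:`is_admissible`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .timeseries_core import (
    STEP, GlucoseSample, GriddedSeries, MealEvent, SubjectRecord,
    ValidationError, copy_record,
)

logger = logging.getLogger("bolusrec")

#: meals are anchored this many minutes after their bolus
MEAL_OFFSET = 10


# ---------------------------------------------------------------------------
# Meal-bolus anchoring
# ---------------------------------------------------------------------------

def anchor_meals(record: SubjectRecord, match_window: int = 60) -> SubjectRecord:
    """Anchor every bolus-wizard meal to exactly ``MEAL_OFFSET`` min after its bolus.

    For each bolus with a positive bolus-wizard carb input (processed in
    chronological order), the closest unconsumed smartphone meal within
    ``match_window`` minutes is moved to ``bolus.time + 10`` and its carbs
    replaced by the bolus-wizard amount (flagged ``shifted``).  Ties in time
    distance are broken by carb closeness to the bolus-wizard amount, then by
    preferring the earlier meal.  If no meal is found, one is added (flagged
    ``added``).  Meals not matched to any bolus are left untouched.  The
    operation is idempotent.
    """
    rec = copy_record(record)
    for b in rec.boluses:
        if b.bw_carb_input is not None and b.bw_carb_input < 0:
            raise ValidationError(
                f"bolus at t={b.time}: negative bolus-wizard carb input {b.bw_carb_input}")

    consumed: set[int] = set()   # indices into rec.meals already claimed
    n0 = len(rec.meals)          # meals appended during THIS run are not claimable
    for b in rec.boluses:
        if not b.bw_carb_input or b.bw_carb_input <= 0:
            continue            # correction bolus: anchors nothing
        anchor_t = b.time + MEAL_OFFSET
        # already-anchored meal from a previous pass (idempotence)
        done = [i for i, m in enumerate(rec.meals[:n0])
                if i not in consumed and (m.shifted or m.added)
                and m.time == anchor_t and m.carbs == b.bw_carb_input]
        if done:
            consumed.add(done[0])
            continue
        cands = [i for i, m in enumerate(rec.meals)
                 if i not in consumed and m.source == "smartphone"
                 and not (m.shifted or m.added)
                 and abs(m.time - b.time) <= match_window]
        if cands:
            def key(i):
                m = rec.meals[i]
                return (abs(m.time - b.time),
                        abs(m.carbs - b.bw_carb_input),
                        m.time)  # earlier meal wins remaining ties
            i = min(cands, key=key)
            m = rec.meals[i]
            m.original_time = m.time
            m.original_carbs = m.carbs
            m.time = anchor_t
            m.carbs = float(b.bw_carb_input)
            m.shifted = True
            consumed.add(i)
        else:
            rec.meals.append(MealEvent(time=anchor_t, carbs=float(b.bw_carb_input),
                                       source="bolus_wizard", added=True))
    rec.meals.sort(key=lambda m: m.time)
    return rec


# ---------------------------------------------------------------------------
# Glucose gap interpolation
# ---------------------------------------------------------------------------

def interpolate_glucose(record: SubjectRecord) -> SubjectRecord:
    """Fill interior CGM gaps with linear interpolation on the 5-minute grid.

    Every grid step strictly between the first and last measurement gets a
    sample; filled samples are flagged ``interpolated``.  Measured samples are
    unchanged, and nothing is extrapolated beyond either end.
    """
    measured = [s for s in record.glucose if not s.interpolated]
    if len(measured) < 2:
        raise ValidationError("need >= 2 measured glucose samples to interpolate")
    rec = copy_record(record)
    times = np.array([s.time for s in measured], dtype=float)
    values = np.array([s.value for s in measured], dtype=float)
    t0, t1 = int(times[0]), int(times[-1])
    have = {s.time for s in measured}
    grid = np.arange(-(-t0 // STEP) * STEP, t1 + 1, STEP)
    fill_t = np.array([t for t in grid if t not in have], dtype=float)
    fill_v = np.interp(fill_t, times, values)
    rec.glucose = [GlucoseSample(time=s.time, value=s.value) for s in measured]
    rec.glucose += [GlucoseSample(time=int(t), value=float(v), interpolated=True)
                    for t, v in zip(fill_t, fill_v)]
    rec.glucose.sort(key=lambda s: s.time)
    return rec


# ---------------------------------------------------------------------------
# Example admissibility
# ---------------------------------------------------------------------------

def is_admissible(t: int, tau: int, record: SubjectRecord,
                  _index: dict | None = None) -> bool:
    """Reject examples whose glucose context is too heavily interpolated.

    ``False`` iff any of: the target sample at ``t+10+tau`` is interpolated (or
    absent); the sample at ``t`` is interpolated (or absent); more than 2
    interpolated samples fall in ``(t-60, t]``; more than 12 interpolated
    samples fall in ``(t-360, t]``.
    """
    by_time = _index if _index is not None else {s.time: s for s in record.glucose}
    target_t = t + MEAL_OFFSET + tau
    target = by_time.get(target_t)
    if target is None:
        logger.debug("t=%d tau=%d: horizon outside data", t, tau)
        return False
    if target.interpolated:
        return False
    now = by_time.get(t)
    if now is None or now.interpolated:
        return False
    n_hour = sum(1 for u in range(t - 60 + STEP, t + 1, STEP)
                 if (s := by_time.get(u)) is not None and s.interpolated)
    if n_hour > 2:
        return False
    n_six = sum(1 for u in range(t - 360 + STEP, t + 1, STEP)
                if (s := by_time.get(u)) is not None and s.interpolated)
    return n_six <= 12


# ---------------------------------------------------------------------------
# [0,1] min-max scaling
# ---------------------------------------------------------------------------

CHANNELS = ("bg", "carbs", "bolus", "basal", "label")


@dataclass
class Scaler:
    """Per-channel min-max scaler fit on training data; no clipping, so test
    values outside the training range map linearly outside [0,1]."""

    mins: dict = field(default_factory=dict)
    maxs: dict = field(default_factory=dict)

    def fit_channel(self, channel: str, values) -> "Scaler":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValidationError(f"channel {channel!r}: empty training data")
        lo, hi = float(np.min(values)), float(np.max(values))
        if hi <= lo:
            raise ValidationError(f"channel {channel!r} is constant (min == max == {lo})")
        self.mins[channel] = lo
        self.maxs[channel] = hi
        return self

    def scale(self, x, channel: str):
        lo, hi = self.mins[channel], self.maxs[channel]
        return (np.asarray(x, dtype=float) - lo) / (hi - lo)

    def unscale(self, x, channel: str):
        lo, hi = self.mins[channel], self.maxs[channel]
        return np.asarray(x, dtype=float) * (hi - lo) + lo


def fit_scaler(train: GriddedSeries, labels) -> Scaler:
    """Fit the per-channel scaler on a training-split grid plus training labels.

    Sparse event channels (carbs, bolus) are mostly zero; their minimum is
    therefore 0 on any realistic training split, and the maximum is the largest
    binned event.
    """
    sc = Scaler()
    bg = train.bg[~np.isnan(train.bg)]
    sc.fit_channel("bg", bg)
    sc.fit_channel("carbs", train.carbs)
    sc.fit_channel("bolus", train.bolus)
    sc.fit_channel("basal", train.basal)
    sc.fit_channel("label", labels)
    return sc
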