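"""Core time-series containers, gridding, I/O, and chronological splitting.

The package works on one subject at a time.  A :class:`SubjectRecord` holds the
four event streams recorded around an insulin pump + CGM setup:

* glucose samples (mg/dL) on a nominal 5-minute cadence,
* discrete insulin boluses (units),
* meals with carbohydrate estimates (grams),
* basal-rate segments (units/hour).

All times are integer minutes from the subject's record start.  The wall-clock
time of day at ``t = 0`` is kept separately (``start_clock``) so that
time-of-day features can be computed without carrying full datetimes around.
"""

from __future__ import annotations

import csv
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger("bolusrec")

#: grid resolution, minutes (CGM cadence)
STEP = 5
#: minutes per day
DAY = 1440


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class ParseError(ValueError):
    """An input file could not be parsed; the message names the element."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GlucoseSample:
    time: int                    # minutes since subject start
    value: float                 # mg/dL
    interpolated: bool = False


@dataclass
class BolusEvent:
    time: int
    dose: float                  # units of insulin
    kind: str = "normal"         # "normal" | "dual"
    bw_carb_input: Optional[float] = None   # grams entered into the bolus wizard


@dataclass
class MealEvent:
    time: int
    carbs: float                 # grams
    source: str = "smartphone"   # "smartphone" | "bolus_wizard" | "synthetic"
    shifted: bool = False        # timestamp moved by pre-processing
    added: bool = False          # created by pre-processing
    original_time: Optional[int] = None     # provenance, set when shifted
    original_carbs: Optional[float] = None  # provenance, set when re-carbed


@dataclass
class BasalSegment:
    start: int
    end: int
    rate: float                  # units/hour


@dataclass
class SubjectRecord:
    subject_id: str
    glucose: list[GlucoseSample] = field(default_factory=list)
    boluses: list[BolusEvent] = field(default_factory=list)
    meals: list[MealEvent] = field(default_factory=list)
    basal: list[BasalSegment] = field(default_factory=list)
    #: (train_end, val_end) boundaries in minutes, set by assign_split
    split: Optional[tuple[int, int]] = None
    #: wall-clock minutes past midnight at record time 0
    start_clock: int = 0

    def wall_clock(self, t: int) -> int:
        """Minutes past midnight of record minute ``t``."""
        return (self.start_clock + int(t)) % DAY

    def span(self) -> tuple[int, int]:
        """(first, last) minute covered by any stream."""
        starts, ends = [], []
        if self.glucose:
            starts.append(self.glucose[0].time)
            ends.append(self.glucose[-1].time)
        if self.boluses:
            starts.append(self.boluses[0].time)
            ends.append(self.boluses[-1].time)
        if self.meals:
            starts.append(self.meals[0].time)
            ends.append(self.meals[-1].time)
        for seg in self.basal:
            starts.append(seg.start)
            ends.append(seg.end)
        if not starts:
            raise ValidationError(f"subject {self.subject_id}: empty record")
        return min(starts), max(ends)

    def validate(self) -> "SubjectRecord":
        if not self.glucose:
            raise ValidationError(f"subject {self.subject_id}: empty glucose stream")
        for name, stream in (("glucose", self.glucose), ("bolus", self.boluses),
                             ("meal", self.meals)):
            times = [e.time for e in stream]
            if times != sorted(times):
                raise ValidationError(f"subject {self.subject_id}: {name} stream not time-sorted")
        for s in self.glucose:
            if s.value <= 0:
                raise ValidationError(f"glucose value {s.value} <= 0 at t={s.time}")
        for b in self.boluses:
            if b.dose < 0:
                raise ValidationError(f"bolus dose {b.dose} < 0 at t={b.time}")
        for m in self.meals:
            if m.carbs <= 0:
                raise ValidationError(f"meal carbs {m.carbs} <= 0 at t={m.time}")
        for seg in self.basal:
            if seg.start >= seg.end:
                raise ValidationError(f"basal segment [{seg.start},{seg.end}] empty")
        return self


@dataclass
class GriddedSeries:
    """Four aligned channels on the 5-minute grid (bin k covers minute 5k)."""

    bg: np.ndarray            # mg/dL; NaN where no sample
    carbs: np.ndarray         # grams summed into the bin
    bolus: np.ndarray         # units summed into the bin
    basal: np.ndarray         # units delivered during the bin
    interpolated: np.ndarray  # bool per step (True where bg was interpolated)

    def __len__(self) -> int:
        return len(self.bg)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.bg)) * STEP


# ---------------------------------------------------------------------------
# Gridding
# ---------------------------------------------------------------------------

def grid_index(t: int) -> int:
    """Nearest 5-minute grid point; exact midpoints never occur with integer
    minutes, and remainders of 1-2 round down, 3-4 round up."""
    t = int(t)
    r = t % STEP
    return t // STEP + (1 if r > STEP // 2 else 0)


def to_grid(record: SubjectRecord) -> GriddedSeries:
    """Bin a record's event streams onto the common 5-minute grid.

    Events are assigned to the nearest grid point (ties down); multiple events
    in one bin are summed; basal insulin is integrated over each bin.  Total
    carbs, bolus and basal insulin are conserved exactly.
    """
    record.validate()
    lo, hi = record.span()
    if lo < 0:
        raise ValidationError(f"event at t={lo} before record start")
    n = grid_index(hi) + 1
    bg = np.full(n, np.nan)
    interp = np.zeros(n, dtype=bool)
    carbs = np.zeros(n)
    bolus = np.zeros(n)
    basal = np.zeros(n)
    for s in record.glucose:
        k = grid_index(s.time)
        if np.isnan(bg[k]) or (interp[k] and not s.interpolated):
            bg[k] = s.value
            interp[k] = s.interpolated
    for m in record.meals:
        carbs[grid_index(m.time)] += m.carbs
    for b in record.boluses:
        bolus[grid_index(b.time)] += b.dose
    for seg in record.basal:
        k0, k1 = seg.start // STEP, -(-seg.end // STEP)  # bins overlapping segment
        for k in range(max(k0, 0), min(k1, n)):
            overlap = min(seg.end, (k + 1) * STEP) - max(seg.start, k * STEP)
            if overlap > 0:
                basal[k] += seg.rate * overlap / 60.0
    return GriddedSeries(bg=bg, carbs=carbs, bolus=bolus, basal=basal, interpolated=interp)


# ---------------------------------------------------------------------------
# Chronological splitting
# ---------------------------------------------------------------------------

def assign_split(record: SubjectRecord, test_days: int = 10,
                 val_days: int = 10) -> SubjectRecord:
    """Set ``record.split = (train_end, val_end)``: the last ``test_days`` are
    held out for testing and the ``val_days`` before them for validation."""
    lo, hi = record.span()
    if hi - lo <= (test_days + val_days) * DAY:
        raise ValidationError(
            f"record spans {(hi - lo) / DAY:.1f} days <= {test_days + val_days}; "
            "pass an explicit split override")
    val_end = hi - test_days * DAY
    train_end = val_end - val_days * DAY
    record.split = (train_end, val_end)
    return record


def _clip_basal(basal: list[BasalSegment], lo: float, hi: float) -> list[BasalSegment]:
    out = []
    for seg in basal:
        a, b = max(seg.start, lo), min(seg.end, hi)
        if a < b:
            out.append(BasalSegment(start=int(a), end=int(b), rate=seg.rate))
    return out


def split_record(record: SubjectRecord, test_days: int = 10, val_days: int = 10
                 ) -> tuple[SubjectRecord, SubjectRecord, SubjectRecord]:
    """Partition a record chronologically into (train, validation, test).

    Point events land in exactly one split; basal segments are clipped at the
    boundaries.  Event times stay on the original record clock.
    """
    if record.split is None:
        assign_split(record, test_days=test_days, val_days=val_days)
    train_end, val_end = record.split
    _, hi = record.span()

    def part(lo: float, up: float) -> SubjectRecord:
        return SubjectRecord(
            subject_id=record.subject_id,
            glucose=[s for s in record.glucose if lo <= s.time < up],
            boluses=[b for b in record.boluses if lo <= b.time < up],
            meals=[m for m in record.meals if lo <= m.time < up],
            basal=_clip_basal(record.basal, lo, up),
            start_clock=record.start_clock,
        )

    return (part(-np.inf, train_end), part(train_end, val_end),
            part(val_end, hi + 1))


# ---------------------------------------------------------------------------
# OhioT1DM-style XML I/O
# ---------------------------------------------------------------------------
# Element names follow the OhioT1DM distribution (glucose_level, bolus, meal,
# basal); timestamps are integer minutes from record start in this dialect.

def _fmt(x) -> str:
    """Round-trip-safe decimal text for a float (NumPy scalars included)."""
    return repr(float(x))


def _req(elem: ET.Element, attr: str, kind=float):
    v = elem.get(attr)
    if v is None:
        raise ParseError(f"<{elem.tag}> event missing attribute '{attr}'")
    try:
        return kind(v)
    except ValueError as e:
        raise ParseError(f"<{elem.tag}> attribute '{attr}'={v!r} not {kind.__name__}") from e


def read_subject_xml(path) -> SubjectRecord:
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ParseError(f"malformed XML in {path}: {e}") from e
    root = tree.getroot()
    if root.tag != "patient":
        raise ParseError(f"expected <patient> root, found <{root.tag}>")
    rec = SubjectRecord(subject_id=root.get("id", Path(path).stem),
                        start_clock=int(root.get("start_clock", 0)))
    for stream in root:
        if stream.tag == "glucose_level":
            for ev in stream:
                rec.glucose.append(GlucoseSample(
                    time=int(_req(ev, "ts")), value=_req(ev, "value"),
                    interpolated=ev.get("interpolated", "false") == "true"))
        elif stream.tag == "bolus":
            for ev in stream:
                bw = ev.get("bwz_carb_input")
                rec.boluses.append(BolusEvent(
                    time=int(_req(ev, "ts")), dose=_req(ev, "dose"),
                    kind=ev.get("type", "normal"),
                    bw_carb_input=float(bw) if bw not in (None, "") else None))
        elif stream.tag == "meal":
            for ev in stream:
                rec.meals.append(MealEvent(
                    time=int(_req(ev, "ts")), carbs=_req(ev, "carbs"),
                    source=ev.get("source", "smartphone"),
                    shifted=ev.get("shifted", "false") == "true",
                    added=ev.get("added", "false") == "true"))
        elif stream.tag == "basal":
            for ev in stream:
                rec.basal.append(BasalSegment(
                    start=int(_req(ev, "ts_begin")), end=int(_req(ev, "ts_end")),
                    rate=_req(ev, "value")))
        else:
            logger.warning("ignoring unknown record type <%s> in %s", stream.tag, path)
    return rec.validate()


def write_subject_xml(record: SubjectRecord, path) -> None:
    root = ET.Element("patient", id=str(record.subject_id),
                      start_clock=str(record.start_clock))
    gl = ET.SubElement(root, "glucose_level")
    for s in record.glucose:
        e = ET.SubElement(gl, "event", ts=str(s.time), value=_fmt(s.value))
        if s.interpolated:
            e.set("interpolated", "true")
    bo = ET.SubElement(root, "bolus")
    for b in record.boluses:
        e = ET.SubElement(bo, "event", ts=str(b.time), dose=_fmt(b.dose), type=b.kind)
        if b.bw_carb_input is not None:
            e.set("bwz_carb_input", _fmt(b.bw_carb_input))
    me = ET.SubElement(root, "meal")
    for m in record.meals:
        e = ET.SubElement(me, "event", ts=str(m.time), carbs=_fmt(m.carbs), source=m.source)
        if m.shifted:
            e.set("shifted", "true")
        if m.added:
            e.set("added", "true")
    ba = ET.SubElement(root, "basal")
    for seg in record.basal:
        ET.SubElement(ba, "event", ts_begin=str(seg.start), ts_end=str(seg.end),
                      value=_fmt(seg.rate))
    ET.indent(ET.ElementTree(root))
    ET.ElementTree(root).write(path, encoding="unicode")


# ---------------------------------------------------------------------------
# CSV dialect: one file per stream inside a directory, header row.
# ---------------------------------------------------------------------------

_CSV_FILES = {
    "glucose": ("glucose.csv", ["time", "value", "interpolated"]),
    "bolus": ("bolus.csv", ["time", "dose", "kind", "bw_carb_input"]),
    "meal": ("meal.csv", ["time", "carbs", "source", "shifted", "added"]),
    "basal": ("basal.csv", ["start", "end", "rate"]),
    "subject": ("subject.csv", ["subject_id", "start_clock"]),
}


def write_subject_csv(record: SubjectRecord, path) -> None:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)

    def dump(name, rows):
        fname, header = _CSV_FILES[name]
        with open(d / fname, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    dump("glucose", [[s.time, _fmt(s.value), int(s.interpolated)] for s in record.glucose])
    dump("bolus", [[b.time, _fmt(b.dose), b.kind,
                    "" if b.bw_carb_input is None else _fmt(b.bw_carb_input)]
                   for b in record.boluses])
    dump("meal", [[m.time, _fmt(m.carbs), m.source, int(m.shifted), int(m.added)]
                  for m in record.meals])
    dump("basal", [[seg.start, seg.end, _fmt(seg.rate)] for seg in record.basal])
    dump("subject", [[record.subject_id, record.start_clock]])


def read_subject_csv(path) -> SubjectRecord:
    d = Path(path)

    def load(name):
        fname, header = _CSV_FILES[name]
        f = d / fname
        if not f.exists():
            raise ParseError(f"missing stream file {fname} in {d}")
        with open(f, newline="") as fh:
            rows = list(csv.reader(fh))
        if not rows or rows[0] != header:
            raise ParseError(f"{fname}: expected header {header}")
        return rows[1:]

    meta = load("subject")
    sid, clock = (meta[0] if meta else ("unknown", "0"))
    rec = SubjectRecord(subject_id=sid, start_clock=int(clock))
    for r in load("glucose"):
        rec.glucose.append(GlucoseSample(time=int(r[0]), value=float(r[1]),
                                         interpolated=bool(int(r[2]))))
    for r in load("bolus"):
        rec.boluses.append(BolusEvent(time=int(r[0]), dose=float(r[1]), kind=r[2],
                                      bw_carb_input=float(r[3]) if r[3] else None))
    for r in load("meal"):
        rec.meals.append(MealEvent(time=int(r[0]), carbs=float(r[1]), source=r[2],
                                   shifted=bool(int(r[3])), added=bool(int(r[4]))))
    for r in load("basal"):
        rec.basal.append(BasalSegment(start=int(r[0]), end=int(r[1]), rate=float(r[2])))
    return rec.validate()


def read_subject(path, format: str = "ohio_xml") -> SubjectRecord:
    """Read one subject in either the XML dialect or the CSV directory dialect."""
    if format == "ohio_xml":
        return read_subject_xml(path)
    if format == "csv":
        return read_subject_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_subject(record: SubjectRecord, path, format: str = "ohio_xml") -> None:
    if format == "ohio_xml":
        write_subject_xml(record, path)
    elif format == "csv":
        write_subject_csv(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def copy_record(record: SubjectRecord) -> SubjectRecord:
    """Deep copy of a record (events are small dataclasses)."""
    return SubjectRecord(
        subject_id=record.subject_id,
        glucose=[replace(s) for s in record.glucose],
        boluses=[replace(b) for b in record.boluses],
        meals=[replace(m) for m in record.meals],
        basal=[replace(seg) for seg in record.basal],
        split=record.split,
        start_clock=record.start_clock,
    )
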