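"""Weekly algorithm-guided dose adjustment for twice-daily premixed insulin.

The treat-to-target rule set: SMBG readings are reviewed every 7 days; when
a slot's readings consistently fall outside the 4-8 mmol/L band, the dose
governing that slot is stepped up or down by 15% (moderate deviation) or
20% (severe), never more. Hypoglycemia takes precedence over any increment,
and a reading below 3.0 mmol/L triggers an out-of-cycle decrement without
waiting for the weekly review. Every recommendation passes a physician
accept/decline gate before it becomes the active regimen.

Dose-governance follows premixed-insulin pharmacodynamics: the evening
premix governs the next morning's fasting (prebreakfast) glucose and the
morning premix governs the predinner glucose.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from statistics import median
from typing import Iterable, Optional

from .config import GOVERNING_DOSE, PREBREAKFAST, PREDINNER, SLOTS, TitrationConfig
from .hypoglycemia import HypoLevel, classify


class Consistency(str, enum.Enum):
    CONSISTENTLY_ABOVE = "consistently_above"
    CONSISTENTLY_BELOW = "consistently_below"
    IN_RANGE = "in_range"
    MIXED = "mixed"
    INSUFFICIENT = "insufficient"


class Rationale(str, enum.Enum):
    IN_RANGE = "in_range"
    HYPER_INCREMENT = "hyper_increment"
    HYPO_DECREMENT = "hypo_decrement"
    INSUFFICIENT_DATA = "insufficient_data"
    CAPPED = "capped"


class Approval(str, enum.Enum):
    PENDING = "pending"
    ACCEPTED = "accepted"
    DECLINED = "declined"
    AUTO_ACCEPTED = "auto_accepted"


@dataclass(frozen=True)
class GlucoseReading:
    """One SMBG measurement with its slot label."""

    participant_id: str
    time: datetime
    slot: str
    glucose: float            # mmol/L
    assisted_event: bool = False

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise ValueError(f"unknown slot {self.slot!r}; expected one of {SLOTS}")
        if not (0.0 < self.glucose < 50.0):
            raise ValueError(f"glucose {self.glucose} mmol/L outside physiological bounds")


@dataclass(frozen=True)
class Regimen:
    """Active premixed-insulin doses (whole units) plus body weight."""

    morning_dose: int
    evening_dose: int
    weight_kg: float

    def __post_init__(self) -> None:
        if self.morning_dose < 0 or self.evening_dose < 0:
            raise ValueError("doses must be non-negative")
        if int(self.morning_dose) != self.morning_dose or int(self.evening_dose) != self.evening_dose:
            raise ValueError("doses must be whole units")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")

    @property
    def tdd_units(self) -> int:
        return self.morning_dose + self.evening_dose

    @property
    def tdd_per_kg(self) -> float:
        return self.tdd_units / self.weight_kg

    def dose(self, which: str) -> int:
        return self.morning_dose if which == "morning" else self.evening_dose


@dataclass(frozen=True)
class ReviewWindow:
    """Readings covering one review interval (default 7 days), half-open."""

    readings: tuple[GlucoseReading, ...]
    window_start: datetime
    window_end: datetime
    prescribed_count: int = 14

    def __post_init__(self) -> None:
        for r in self.readings:
            if not (self.window_start <= r.time < self.window_end):
                raise ValueError(f"reading at {r.time} outside window "
                                 f"[{self.window_start}, {self.window_end})")

    def deduplicated(self) -> tuple[GlucoseReading, ...]:
        """At most one reading per (day, slot); earliest wins."""
        seen: dict[tuple, GlucoseReading] = {}
        for r in sorted(self.readings, key=lambda r: r.time):
            key = (r.time.date(), r.slot)
            seen.setdefault(key, r)
        return tuple(sorted(seen.values(), key=lambda r: r.time))


@dataclass(frozen=True)
class SlotSummary:
    slot: str
    count: int
    median: Optional[float]
    frac_above: Optional[float]
    frac_below: Optional[float]
    minimum: Optional[float]
    n_level1: int = 0
    n_level2: int = 0

    @property
    def missing(self) -> bool:
        return self.count == 0


@dataclass
class Recommendation:
    """Proposed dose change awaiting the physician accept/decline gate."""

    slot_changes: dict[str, int]          # keyed by dose ("morning"/"evening"), signed units
    new_regimen: Regimen
    rationale: dict[str, Rationale]       # keyed by reading slot
    step_fraction: dict[str, float]       # keyed by reading slot, in [0, 0.20]
    urgent: bool = False
    approval: Approval = Approval.PENDING
    decided_at: Optional[datetime] = None

    @property
    def is_change(self) -> bool:
        return any(d != 0 for d in self.slot_changes.values())


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def summarize_window(window: ReviewWindow, band_low: float = 4.0,
                     band_high: float = 8.0) -> dict[str, SlotSummary]:
    """Per-slot count/median/band fractions/min over deduplicated readings.

    Slots with zero readings are returned with ``missing`` set rather than
    omitted, so downstream rules see both prescribed slots every week.
    """
    if not band_low < band_high:
        raise ValueError("band_low must be < band_high")
    readings = window.deduplicated()
    out: dict[str, SlotSummary] = {}
    for slot in SLOTS:
        vals = [r.glucose for r in readings if r.slot == slot]
        if not vals:
            out[slot] = SlotSummary(slot, 0, None, None, None, None)
            continue
        levels = [classify(v, False) for v in vals]
        out[slot] = SlotSummary(
            slot=slot,
            count=len(vals),
            median=median(vals),
            frac_above=sum(v > band_high for v in vals) / len(vals),
            frac_below=sum(v < band_low for v in vals) / len(vals),
            minimum=min(vals),
            n_level1=sum(lv is HypoLevel.LEVEL1 for lv in levels),
            n_level2=sum(lv is HypoLevel.LEVEL2 for lv in levels),
        )
    return out


def classify_consistency(summary: SlotSummary, config: TitrationConfig | None = None,
                         band_low: float | None = None, band_high: float | None = None) -> Consistency:
    """Label a slot's week as consistently above/below band, in range, mixed,
    or insufficient (< min_readings_per_slot readings).

    "Consistently outside" requires both a supermajority of readings
    (default >= 4/7 of the slot's readings) beyond the band edge and the
    slot median beyond it, so a single outlier cannot drive a dose change.
    """
    cfg = config or TitrationConfig()
    lo = cfg.band_low if band_low is None else band_low
    hi = cfg.band_high if band_high is None else band_high
    if summary.count < cfg.min_readings_per_slot:
        return Consistency.INSUFFICIENT
    thresh = cfg.consistency_threshold - 1e-12
    if summary.frac_above >= thresh and summary.median > hi:
        return Consistency.CONSISTENTLY_ABOVE
    if summary.frac_below >= thresh and summary.median < lo:
        return Consistency.CONSISTENTLY_BELOW
    if summary.frac_above == 0 and summary.frac_below == 0:
        return Consistency.IN_RANGE
    return Consistency.MIXED


def _step_delta(dose: int, fraction: float, sign: int) -> int:
    """Signed whole-unit step: half-away-from-zero rounding, minimum 1 unit."""
    if dose <= 0:
        return 0
    magnitude = max(1, _round_half_away(fraction * dose))
    magnitude = min(magnitude, math.ceil(0.20 * dose))  # hard ceiling
    return sign * magnitude


def recommend(window: ReviewWindow, regimen: Regimen,
              config: TitrationConfig | None = None) -> Recommendation:
    """The weekly titration decision for one participant.

    Per reading slot: consistently-above -> increment the governing dose
    (15% within ``severity_margin`` of the band edge, 20% beyond);
    consistently-below -> symmetric decrement. Any level-2 reading, or at
    least two level-1 readings, in a slot vetoes an increment and forces a
    decrement of that slot's governing dose (20% if level 2 was seen, else
    15%). The resulting total daily dose may not exceed the configured
    units/kg cap; excess increments are truncated and flagged ``capped``.
    """
    cfg = config or TitrationConfig()
    summaries = summarize_window(window, cfg.band_low, cfg.band_high)

    deltas = {"morning": 0, "evening": 0}
    rationale: dict[str, Rationale] = {}
    step_fraction: dict[str, float] = {}

    for slot in SLOTS:
        s = summaries[slot]
        gov = GOVERNING_DOSE[slot]
        dose = regimen.dose(gov)
        cls = classify_consistency(s, cfg)

        hypo_forced = s.n_level2 >= 1 or s.n_level1 >= cfg.level1_weekly_trigger
        if hypo_forced:
            frac = cfg.step_severe if s.n_level2 >= 1 else cfg.step_moderate
            delta = _step_delta(dose, frac, -1)
            if delta == 0:  # dose already at zero: nothing left to cut
                rationale[slot] = Rationale.CAPPED
                step_fraction[slot] = 0.0
            else:
                rationale[slot] = Rationale.HYPO_DECREMENT
                step_fraction[slot] = frac
            deltas[gov] += delta
            continue

        if cls is Consistency.CONSISTENTLY_ABOVE:
            severe = s.median > cfg.band_high + cfg.severity_margin
            frac = cfg.step_severe if severe else cfg.step_moderate
            delta = _step_delta(dose, frac, +1)
            deltas[gov] += delta
            rationale[slot] = Rationale.HYPER_INCREMENT if delta else Rationale.CAPPED
            step_fraction[slot] = frac if delta else 0.0
        elif cls is Consistency.CONSISTENTLY_BELOW:
            severe = s.median < cfg.band_low - cfg.severity_margin
            frac = cfg.step_severe if severe else cfg.step_moderate
            delta = _step_delta(dose, frac, -1)
            deltas[gov] += delta
            if delta == 0:
                rationale[slot] = Rationale.CAPPED
                step_fraction[slot] = 0.0
            else:
                rationale[slot] = Rationale.HYPO_DECREMENT
                step_fraction[slot] = frac
        elif cls is Consistency.INSUFFICIENT:
            rationale[slot] = Rationale.INSUFFICIENT_DATA
            step_fraction[slot] = 0.0
        else:
            rationale[slot] = Rationale.IN_RANGE
            step_fraction[slot] = 0.0

    # clamp decrements at zero dose
    for gov in ("morning", "evening"):
        if regimen.dose(gov) + deltas[gov] < 0:
            deltas[gov] = -regimen.dose(gov)

    # total-daily-dose safety cap: truncate increments, flag the slot capped
    max_tdd = math.floor(cfg.tdd_cap_per_kg * regimen.weight_kg)
    new_tdd = regimen.tdd_units + deltas["morning"] + deltas["evening"]
    excess = new_tdd - max_tdd
    if excess > 0:
        # fixed shave order (morning first) keeps the recommendation
        # monotone in each slot's readings even when the cap binds
        for gov in ("morning", "evening"):
            if excess <= 0 or deltas[gov] <= 0:
                continue
            cut = min(excess, deltas[gov])
            deltas[gov] -= cut
            excess -= cut
            slot = next(s for s, g in GOVERNING_DOSE.items() if g == gov)
            rationale[slot] = Rationale.CAPPED

    new_regimen = Regimen(
        morning_dose=regimen.morning_dose + deltas["morning"],
        evening_dose=regimen.evening_dose + deltas["evening"],
        weight_kg=regimen.weight_kg,
    )
    return Recommendation(slot_changes=deltas, new_regimen=new_regimen,
                          rationale=rationale, step_fraction=step_fraction)


def hypoglycemia_trigger(readings: Iterable[GlucoseReading], regimen: Regimen,
                         config: TitrationConfig | None = None,
                         already_triggered: frozenset[str] | set[str] = frozenset(),
                         ) -> Optional[Recommendation]:
    """Out-of-cycle decrement when any reading drops below the urgent
    threshold (default 3.0 mmol/L, i.e. level 2).

    Fires at most once per slot per review window: slots listed in
    ``already_triggered`` are ignored. Returns ``None`` when no slot fires.
    """
    cfg = config or TitrationConfig()
    urgent_slots = []
    for r in readings:
        if r.glucose < cfg.urgent_threshold and r.slot not in already_triggered \
                and r.slot not in urgent_slots:
            urgent_slots.append(r.slot)
    if not urgent_slots:
        return None

    deltas = {"morning": 0, "evening": 0}
    rationale: dict[str, Rationale] = {}
    step_fraction: dict[str, float] = {}
    for slot in urgent_slots:
        gov = GOVERNING_DOSE[slot]
        delta = _step_delta(regimen.dose(gov), cfg.step_severe, -1)
        deltas[gov] += delta
        rationale[slot] = Rationale.HYPO_DECREMENT if delta else Rationale.CAPPED
        step_fraction[slot] = cfg.step_severe if delta else 0.0

    new_regimen = Regimen(
        morning_dose=max(0, regimen.morning_dose + deltas["morning"]),
        evening_dose=max(0, regimen.evening_dose + deltas["evening"]),
        weight_kg=regimen.weight_kg,
    )
    deltas["morning"] = new_regimen.morning_dose - regimen.morning_dose
    deltas["evening"] = new_regimen.evening_dose - regimen.evening_dose
    return Recommendation(slot_changes=deltas, new_regimen=new_regimen,
                          rationale=rationale, step_fraction=step_fraction,
                          urgent=True)


def apply_approval(rec: Recommendation, regimen: Regimen, decision: str,
                   when: datetime | None = None) -> Regimen:
    """Physician gate: ``accept`` activates the recommended regimen,
    ``decline`` leaves the current one. A recommendation may be decided
    exactly once."""
    if rec.approval is not Approval.PENDING:
        raise ValueError(f"recommendation already {rec.approval.value}")
    if decision not in ("accept", "decline"):
        raise ValueError(f"decision must be 'accept' or 'decline', got {decision!r}")
    rec.decided_at = when or datetime.now()
    if decision == "accept":
        rec.approval = Approval.ACCEPTED
        return rec.new_regimen
    rec.approval = Approval.DECLINED
    return regimen


def make_window(readings: Iterable[GlucoseReading], window_start: datetime,
                days: int = 7, slots_per_day: int = 2) -> ReviewWindow:
    """Convenience constructor: keep only readings inside the half-open
    ``[window_start, window_start + days)`` interval."""
    end = window_start + timedelta(days=days)
    inside = tuple(r for r in readings if window_start <= r.time < end)
    return ReviewWindow(readings=inside, window_start=window_start,
                        window_end=end, prescribed_count=days * slots_per_day)
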