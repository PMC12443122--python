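"""Routine-anchored dose scheduling.

A :class:`Regimen` binds one formulary entry to anchor clock times (one per
daily dose, e.g. "breakfast" -> 08:00) over a date range.  Each intended
dose occurrence becomes a :class:`DoseSlot` carrying its dosing window:
the half-open interval starting 1 hour before the intended time and ending
``safe_window_hours`` after it.

Conventions (fixed here, relied on everywhere downstream):

* windows are half-open ``[window_start, window_end)`` so any instant maps
  to exactly one classification;
* clock granularity is one minute;
* anchors are wall-clock times in the regimen's IANA zone — on DST
  transition days a skipped or repeated wall-clock hour resolves to the
  earliest valid instant (patients follow clocks, not UTC offsets);
* consecutive intended doses must be separated by strictly more than
  ``safe_window_hours + 1`` hours, which makes consecutive windows disjoint
  and the classifier unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

from .errors import RegimenError, WindowsOverlapError
from .formulary import Formulary, MedicationEntry, lookup, validate_dose

__all__ = ["Regimen", "DoseSlot", "generate_slots", "window_for", "in_window"]

PRE_WINDOW = timedelta(hours=1)  # dosing window opens 1 h before intended time
MINUTE = timedelta(minutes=1)


@dataclass(frozen=True)
class Regimen:
    """A prescription bound to daily anchor times over a date range."""

    generic_name: str
    frequency_per_day: int
    dose: tuple[float, ...]
    anchor_times: tuple[time, ...]
    timezone: str = "UTC"
    start_date: date = date(2025, 1, 6)
    end_date: date = date(2025, 1, 6)
    anchor_labels: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, int]:
        return (self.generic_name, self.frequency_per_day)

    def n_days(self) -> int:
        return max(0, (self.end_date - self.start_date).days + 1)

    def with_days(self, n_days: int) -> "Regimen":
        if n_days < 1:
            return replace(self, end_date=self.start_date - timedelta(days=1))
        return replace(self, end_date=self.start_date + timedelta(days=n_days - 1))


@dataclass(frozen=True)
class DoseSlot:
    """One intended dose occurrence with its computed dosing window."""

    slot_id: int
    intended_time: datetime
    window_start: datetime
    window_end: datetime
    regimen_key: tuple[str, int] = ("", 0)

    @property
    def window(self) -> tuple[datetime, datetime]:
        return (self.window_start, self.window_end)


def validate_regimen(regimen: Regimen, formulary: Formulary) -> MedicationEntry:
    """Resolve the regimen against the formulary and check its structure.

    Returns the matched entry.  Raises on: unknown medication/frequency,
    a dose that is not a listed option, a wrong anchor count, non-increasing
    anchors, or anchor spacing that would let dosing windows overlap.
    """
    entry = lookup(formulary, regimen.generic_name, regimen.frequency_per_day)
    if not validate_dose(entry, regimen.dose):
        raise RegimenError(
            f"dose {regimen.dose} is not a listed option for "
            f"{entry.generic_name!r}: {list(entry.dose_options)}"
        )
    if len(regimen.anchor_times) != regimen.frequency_per_day:
        raise RegimenError(
            f"{len(regimen.anchor_times)} anchor times for frequency "
            f"{regimen.frequency_per_day}/day"
        )
    minutes = [t.hour * 60 + t.minute for t in regimen.anchor_times]
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise RegimenError("anchor times must be strictly increasing within the day")
    _check_spacing(minutes, entry.safe_window_hours)
    return entry


def _check_spacing(anchor_minutes: list[int], safe_window_hours: float) -> None:
    # gaps between consecutive intended doses, including the wrap across
    # midnight back to the first anchor of the next day
    gaps = [b - a for a, b in zip(anchor_minutes, anchor_minutes[1:])]
    gaps.append(24 * 60 - (anchor_minutes[-1] - anchor_minutes[0]))
    required = (safe_window_hours + 1) * 60
    for gap in gaps:
        if gap <= required:
            raise WindowsOverlapError(
                f"consecutive doses {gap / 60:g} h apart; must exceed "
                f"safe window + 1 h = {required / 60:g} h"
            )


def _localize(day: date, clock: time, zone: ZoneInfo) -> datetime:
    """Wall-clock instant; a nonexistent (spring-forward) time maps to the
    earliest valid instant, an ambiguous (fall-back) one to the first."""
    dt = datetime.combine(day, clock, tzinfo=zone)
    # PEP 495: nonexistent wall times normalize through a UTC round-trip
    roundtrip = dt.astimezone(ZoneInfo("UTC")).astimezone(zone)
    if roundtrip != dt or roundtrip.utcoffset() != dt.utcoffset():
        return roundtrip
    return dt


def generate_slots(regimen: Regimen, formulary: Formulary) -> list[DoseSlot]:
    """One slot per anchor time per day, strictly ordered, windows disjoint."""
    entry = validate_regimen(regimen, formulary)
    zone = ZoneInfo(regimen.timezone)
    window = timedelta(hours=entry.safe_window_hours)
    slots: list[DoseSlot] = []
    day = regimen.start_date
    while day <= regimen.end_date:
        for clock in regimen.anchor_times:
            intended = _localize(day, clock, zone)
            slots.append(
                DoseSlot(
                    slot_id=len(slots),
                    intended_time=intended,
                    window_start=intended - PRE_WINDOW,
                    window_end=intended + window,
                    regimen_key=regimen.key,
                )
            )
        day += timedelta(days=1)
    for prev, cur in zip(slots, slots[1:]):
        if cur.window_start < prev.window_end:
            raise WindowsOverlapError(
                f"slots {prev.slot_id} and {cur.slot_id} have overlapping windows"
            )
    return slots


def window_for(slot: DoseSlot) -> tuple[datetime, datetime]:
    """The half-open dosing window ``[window_start, window_end)``."""
    return slot.window


def in_window(slot: DoseSlot, now: datetime) -> bool:
    """Membership in the dosing window: closed at start, open at end."""
    return slot.window_start <= now < slot.window_end
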