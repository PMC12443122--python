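"""Adherence summaries computed from the event log."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Sequence

from .engine import DoseEvent, DoseStatus, Engine
from .errors import LogValidationError
from .schedule import DoseSlot

__all__ = ["AdherenceSummary", "summarize"]

#: "On time" in the strict sense: within an hour of the intended time.
STRICT_TOLERANCE = timedelta(hours=1)


@dataclass(frozen=True)
class AdherenceSummary:
    """Per-regimen adherence counts and rates.

    ``on_time_rate`` counts takes performed inside the dosing window;
    ``strict_on_time_rate`` is the stricter notion of within one hour of
    the intended time.  ``n_pending`` is nonzero only for logs summarized
    mid-run; completed engine logs partition every slot into the four
    terminal counts and have ``duplicate_dose_count == 0``.
    """

    n_slots: int
    n_taken_on_time: int
    n_taken_late: int
    n_skipped: int
    n_missed: int
    n_pending: int
    on_time_rate: float
    any_take_rate: float
    strict_on_time_rate: float
    duplicate_dose_count: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _rate(num: int, den: int) -> float:
    return num / den if den else 0.0


def summarize(
    events: Iterable[DoseEvent], slots: Sequence[DoseSlot]
) -> AdherenceSummary:
    """Fold an event log into an :class:`AdherenceSummary`.

    The log is first replayed through the engine, so any sequence the engine
    would not have produced — unknown slot ids, a second take on a resolved
    slot, an action outside its legal status — raises
    :class:`LogValidationError`.  The result is invariant to event
    permutations that preserve per-slot ordering, because replay sorts by
    timestamp.
    """
    events = list(events)
    engine = Engine.from_events(slots, events)
    counts = {status: 0 for status in DoseStatus}
    for slot in slots:
        resolution = engine.resolution_of(slot.slot_id)
        if resolution is not None:
            counts[resolution] += 1
    n_slots = len(slots)
    n_on_time = counts[DoseStatus.RESOLVED_TAKEN]
    n_late = counts[DoseStatus.RESOLVED_TAKEN_LATE]
    n_skipped = counts[DoseStatus.RESOLVED_SKIPPED]
    n_missed = counts[DoseStatus.RESOLVED_MISSED]
    n_pending = n_slots - (n_on_time + n_late + n_skipped + n_missed)

    by_id = {s.slot_id: s for s in slots}
    strict = 0
    takes_per_slot: dict[int, int] = {}
    for ev in events:
        if ev.resulting_status in (
            DoseStatus.RESOLVED_TAKEN,
            DoseStatus.RESOLVED_TAKEN_LATE,
        ):
            takes_per_slot[ev.slot_id] = takes_per_slot.get(ev.slot_id, 0) + 1
            intended = by_id[ev.slot_id].intended_time
            if abs(ev.timestamp - intended) <= STRICT_TOLERANCE:
                strict += 1
    duplicates = sum(1 for n in takes_per_slot.values() if n > 1)
    if duplicates:
        # unreachable for engine-produced logs; replay above raises first
        raise LogValidationError(f"{duplicates} slot(s) have more than one take")

    return AdherenceSummary(
        n_slots=n_slots,
        n_taken_on_time=n_on_time,
        n_taken_late=n_late,
        n_skipped=n_skipped,
        n_missed=n_missed,
        n_pending=n_pending,
        on_time_rate=_rate(n_on_time, n_slots),
        any_take_rate=_rate(n_on_time + n_late, n_slots),
        strict_on_time_rate=_rate(strict, n_slots),
        duplicate_dose_count=duplicates,
    )
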