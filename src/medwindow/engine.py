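"""Missed-dose state machine.

Classifies the current instant against a dose slot's window —
``UPCOMING`` before the window opens, ``ACT_NOW`` inside it, ``OVERDUE``
after it closes — and drives the take/snooze/skip actions:

* ``SNOOZE`` (only while ``ACT_NOW``) schedules another reminder 15 minutes
  later and leaves the slot active; at most 4 consecutive snoozes are
  accepted per slot.
* ``TAKE`` inside the window resolves the slot taken; a ``TAKE`` on an
  overdue slot is recorded as a late take and, when a next slot exists,
  raises a take-or-skip prompt on that next slot so a double dose is never
  taken silently.
* ``SKIP`` resolves the slot skipped.  Skipping is the recommended choice
  for an overdue slot, but it is a recommendation only — the choice stays
  with the user.

State is an append-only event log; the current status of every slot is a
pure fold over the events, which makes logs replayable and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import (
    AlreadyResolvedError,
    EngineError,
    IllegalActionError,
    LogValidationError,
    PendingDecisionError,
    SnoozeLimitError,
)
from .schedule import DoseSlot

__all__ = [
    "DoseStatus",
    "Action",
    "ActionSet",
    "DoseEvent",
    "NextDoseDecision",
    "Engine",
    "classify",
    "available_actions",
    "write_event_log",
    "read_event_log",
    "SNOOZE_INTERVAL",
    "MAX_CONSECUTIVE_SNOOZES",
    "LAST_SLOT_GRACE",
]

SNOOZE_INTERVAL = timedelta(minutes=15)
MAX_CONSECUTIVE_SNOOZES = 4
#: How long a slot with no successor stays actionable past its window end.
LAST_SLOT_GRACE = timedelta(hours=24)

LOG_SCHEMA_VERSION = 1


class DoseStatus(str, Enum):
    UPCOMING = "UPCOMING"
    ACT_NOW = "ACT_NOW"
    OVERDUE = "OVERDUE"
    RESOLVED_TAKEN = "RESOLVED_TAKEN"
    RESOLVED_TAKEN_LATE = "RESOLVED_TAKEN_LATE"
    RESOLVED_SKIPPED = "RESOLVED_SKIPPED"
    RESOLVED_MISSED = "RESOLVED_MISSED"

    @property
    def terminal(self) -> bool:
        return self.name.startswith("RESOLVED")


class Action(str, Enum):
    TAKE = "TAKE"
    SNOOZE = "SNOOZE"
    SKIP = "SKIP"
    TAKE_NEXT = "TAKE_NEXT"
    SKIP_NEXT = "SKIP_NEXT"


@dataclass(frozen=True)
class ActionSet:
    """Ordered legal actions for a status, with the recommended one flagged."""

    actions: tuple[Action, ...]
    recommended: Action | None = None

    def __contains__(self, action: Action) -> bool:
        return action in self.actions


@dataclass(frozen=True)
class DoseEvent:
    """One entry of the append-only log.

    ``action`` is ``None`` for synthetic expiry events.  ``overdue_take``
    marks a take performed at or after the window end; ``reminder_at`` is
    set only by snoozes (timestamp + 15 min).
    """

    slot_id: int
    timestamp: datetime
    action: Action | None
    resulting_status: DoseStatus
    overdue_take: bool = False
    reminder_at: datetime | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": LOG_SCHEMA_VERSION,
            "slot_id": self.slot_id,
            "timestamp": self.timestamp.isoformat(),
            "action": self.action.value if self.action else None,
            "resulting_status": self.resulting_status.value,
            "overdue_take": self.overdue_take,
            "reminder_at": self.reminder_at.isoformat() if self.reminder_at else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseEvent":
        return cls(
            slot_id=int(d["slot_id"]),
            timestamp=datetime.fromisoformat(d["timestamp"]),
            action=Action(d["action"]) if d.get("action") else None,
            resulting_status=DoseStatus(d["resulting_status"]),
            overdue_take=bool(d.get("overdue_take", False)),
            reminder_at=(
                datetime.fromisoformat(d["reminder_at"]) if d.get("reminder_at") else None
            ),
        )


@dataclass
class NextDoseDecision:
    """Take-or-skip prompt on the dose after an overdue take."""

    triggering_slot_id: int
    next_slot_id: int
    resolution: Action | None = None  # TAKE_NEXT or SKIP_NEXT once answered

    @property
    def pending(self) -> bool:
        return self.resolution is None


def classify(now: datetime, slot: DoseSlot) -> DoseStatus:
    """Pure time classification against the slot's half-open window."""
    if now < slot.window_start:
        return DoseStatus.UPCOMING
    if now < slot.window_end:
        return DoseStatus.ACT_NOW
    return DoseStatus.OVERDUE


def available_actions(status: DoseStatus) -> ActionSet:
    """Legal user actions for a non-terminal status.

    ``UPCOMING`` offers nothing (no early taking before the window opens);
    ``OVERDUE`` recommends the skip but leaves the choice to the user.
    """
    if status.terminal:
        raise AlreadyResolvedError(f"no actions for terminal status {status.value}")
    if status is DoseStatus.UPCOMING:
        return ActionSet(actions=())
    if status is DoseStatus.ACT_NOW:
        return ActionSet(actions=(Action.TAKE, Action.SNOOZE, Action.SKIP))
    return ActionSet(actions=(Action.SKIP, Action.TAKE), recommended=Action.SKIP)


class Engine:
    """Event-sourced state over an ordered list of dose slots."""

    def __init__(self, slots: Sequence[DoseSlot]):
        ids = [s.slot_id for s in slots]
        if ids != sorted(set(ids)):
            raise EngineError("slot ids must be unique and ordered")
        times = [s.intended_time for s in slots]
        if times != sorted(times):
            raise EngineError("slots must be ordered by intended time")
        self._slots: dict[int, DoseSlot] = {s.slot_id: s for s in slots}
        self._order: list[int] = ids
        self._events: list[DoseEvent] = []
        self._resolution: dict[int, DoseStatus] = {}
        self._snoozes: dict[int, int] = {}
        self._decisions: list[NextDoseDecision] = []
        self._clock: datetime | None = None  # last user-action timestamp

    # -- inspection ------------------------------------------------------

    @property
    def slots(self) -> list[DoseSlot]:
        return [self._slots[i] for i in self._order]

    @property
    def events(self) -> tuple[DoseEvent, ...]:
        return tuple(self._events)

    @property
    def decisions(self) -> tuple[NextDoseDecision, ...]:
        return tuple(self._decisions)

    def is_resolved(self, slot_id: int) -> bool:
        return slot_id in self._resolution

    def resolution_of(self, slot_id: int) -> DoseStatus | None:
        return self._resolution.get(slot_id)

    def all_terminal(self) -> bool:
        return len(self._resolution) == len(self._slots)

    def status_of(self, slot_id: int, now: datetime) -> DoseStatus:
        """Terminal resolution if resolved, else the time classification."""
        resolved = self._resolution.get(slot_id)
        if resolved is not None:
            return resolved
        return classify(now, self._slot(slot_id))

    def classify(self, now: datetime, slot_id: int) -> DoseStatus:
        """Time classification; errors if the slot is already resolved."""
        if slot_id in self._resolution:
            raise AlreadyResolvedError(
                f"slot {slot_id} already resolved {self._resolution[slot_id].value}"
            )
        return classify(now, self._slot(slot_id))

    def pending_decision_for(self, slot_id: int) -> NextDoseDecision | None:
        """The unresolved prompt blocking a TAKE on this slot, if any."""
        for d in self._decisions:
            if d.pending and d.next_slot_id == slot_id and slot_id not in self._resolution:
                return d
        return None

    # -- transitions -----------------------------------------------------

    def apply(
        self, slot_id: int, action: Action, now: datetime
    ) -> tuple[DoseEvent, NextDoseDecision | None]:
        """Apply a user action; returns the event and any new prompt raised.

        Action timestamps must be non-decreasing: the engine models a user
        moving forward in time, and back-dated actions could sidestep the
        duplicate-dose protection.
        """
        if self._clock is not None and now < self._clock:
            raise EngineError(
                f"action at {now.isoformat()} predates last action at "
                f"{self._clock.isoformat()}"
            )
        self._clock = now
        # lapsed slots stop being actionable the moment they lapse, whether
        # or not the caller ran expire() — otherwise a take on a stale slot
        # could slip past the duplicate-dose prompt
        self.expire(now)
        if action in (Action.TAKE_NEXT, Action.SKIP_NEXT):
            return self._resolve_decision(slot_id, action, now), None
        status = self.classify(now, slot_id)
        legal = available_actions(status)
        if action not in legal:
            raise IllegalActionError(
                f"action {action.value} not available while {status.value}"
            )
        slot = self._slot(slot_id)
        if action is Action.TAKE and self.pending_decision_for(slot_id) is not None:
            raise PendingDecisionError(
                f"slot {slot_id} has an unanswered take-or-skip prompt"
            )
        if action is Action.SNOOZE:
            if self._snoozes.get(slot_id, 0) >= MAX_CONSECUTIVE_SNOOZES:
                raise SnoozeLimitError(
                    f"slot {slot_id} already snoozed {MAX_CONSECUTIVE_SNOOZES} times"
                )
            self._snoozes[slot_id] = self._snoozes.get(slot_id, 0) + 1
            event = DoseEvent(
                slot_id=slot_id,
                timestamp=now,
                action=action,
                resulting_status=status,
                reminder_at=now + SNOOZE_INTERVAL,
            )
            self._events.append(event)
            return event, None
        if action is Action.SKIP:
            return self._record(slot_id, action, now, DoseStatus.RESOLVED_SKIPPED), None
        # TAKE: a take at/after window_end is an overdue take regardless of
        # any snooze history
        overdue = now >= slot.window_end
        if overdue:
            event = self._record(
                slot_id, action, now, DoseStatus.RESOLVED_TAKEN_LATE, overdue_take=True
            )
            decision = self._raise_prompt(slot_id)
            return event, decision
        return self._record(slot_id, action, now, DoseStatus.RESOLVED_TAKEN), None

    def expire(self, now: datetime) -> list[DoseEvent]:
        """Resolve abandoned slots as missed.

        A slot whose successor's window has opened can no longer be acted
        on; a final slot lapses 24 h after its own window closes.  Synthetic
        events are stamped at the lapse boundary, not at ``now``.
        """
        emitted: list[DoseEvent] = []
        for idx, slot_id in enumerate(self._order):
            if slot_id in self._resolution:
                continue
            if idx + 1 < len(self._order):
                boundary = self._slots[self._order[idx + 1]].window_start
            else:
                boundary = self._slots[slot_id].window_end + LAST_SLOT_GRACE
            if now >= boundary:
                emitted.append(
                    self._record(slot_id, None, boundary, DoseStatus.RESOLVED_MISSED)
                )
        return emitted

    # -- internals -------------------------------------------------------

    def _slot(self, slot_id: int) -> DoseSlot:
        try:
            return self._slots[slot_id]
        except KeyError:
            raise EngineError(f"unknown slot id {slot_id}") from None

    def _record(
        self,
        slot_id: int,
        action: Action | None,
        when: datetime,
        status: DoseStatus,
        *,
        overdue_take: bool = False,
    ) -> DoseEvent:
        event = DoseEvent(
            slot_id=slot_id,
            timestamp=when,
            action=action,
            resulting_status=status,
            overdue_take=overdue_take,
        )
        self._events.append(event)
        self._resolution[slot_id] = status
        return event

    def _raise_prompt(self, slot_id: int) -> NextDoseDecision | None:
        idx = self._order.index(slot_id)
        if idx + 1 >= len(self._order):
            return None  # end of regimen: nothing to protect
        next_id = self._order[idx + 1]
        if next_id in self._resolution:
            return None
        decision = NextDoseDecision(triggering_slot_id=slot_id, next_slot_id=next_id)
        self._decisions.append(decision)
        return decision

    def _resolve_decision(
        self, slot_id: int, choice: Action, now: datetime
    ) -> DoseEvent:
        decision = next(
            (
                d
                for d in self._decisions
                if d.pending
                and d.next_slot_id == slot_id
                and slot_id not in self._resolution
            ),
            None,
        )
        if decision is None:
            raise IllegalActionError(
                f"{choice.value} is only legal in answer to a take-or-skip prompt"
            )
        decision.resolution = choice
        if choice is Action.SKIP_NEXT:
            return self._record(slot_id, choice, now, DoseStatus.RESOLVED_SKIPPED)
        # TAKE_NEXT: slot stays active; record the confirmation for audit
        event = DoseEvent(
            slot_id=slot_id,
            timestamp=now,
            action=choice,
            resulting_status=classify(now, self._slot(slot_id)),
        )
        self._events.append(event)
        return event

    # -- replay ----------------------------------------------------------

    @classmethod
    def from_events(
        cls, slots: Sequence[DoseSlot], events: Iterable[DoseEvent]
    ) -> "Engine":
        """Rebuild state by replaying a log, validating every transition.

        Events are replayed in timestamp order; at equal timestamps, prompt
        answers (TAKE_NEXT/SKIP_NEXT) replay after the overdue take that
        raised them, and remaining ties keep input order.  An illegal
        transition raises :class:`LogValidationError`.
        """
        engine = cls(slots)
        def rank(ev: DoseEvent) -> int:
            if ev.action is None:
                return 0  # synthetic expiry precedes actions at the same instant
            if ev.action in (Action.TAKE_NEXT, Action.SKIP_NEXT):
                return 2  # prompt answers follow the take that raised them
            return 1

        ordered = sorted(
            enumerate(events), key=lambda p: (p[1].timestamp, rank(p[1]), p[0])
        )
        for _, ev in ordered:
            try:
                if ev.action is None:
                    if ev.resulting_status is not DoseStatus.RESOLVED_MISSED:
                        raise LogValidationError(
                            f"synthetic event with status {ev.resulting_status.value}"
                        )
                    if ev.slot_id not in engine._slots:
                        raise EngineError(f"unknown slot id {ev.slot_id}")
                    if ev.slot_id in engine._resolution:
                        raise AlreadyResolvedError(f"slot {ev.slot_id} already resolved")
                    engine._record(
                        ev.slot_id, None, ev.timestamp, DoseStatus.RESOLVED_MISSED
                    )
                else:
                    replayed, _ = engine.apply(ev.slot_id, ev.action, ev.timestamp)
                    if replayed.resulting_status is not ev.resulting_status:
                        raise LogValidationError(
                            f"event for slot {ev.slot_id} claims "
                            f"{ev.resulting_status.value} but replay gives "
                            f"{replayed.resulting_status.value}"
                        )
            except LogValidationError:
                raise
            except EngineError as exc:
                raise LogValidationError(f"illegal event in log: {exc}") from exc
        return engine


def write_event_log(events: Iterable[DoseEvent], dest: str | Path | IO[str]) -> None:
    """JSON Lines, one event per line, ISO-8601 timestamps."""
    lines = "".join(json.dumps(e.to_dict()) + "\n" for e in events)
    if hasattr(dest, "write"):
        dest.write(lines)  # type: ignore[union-attr]
    else:
        Path(dest).write_text(lines, encoding="utf-8")


def read_event_log(source: str | Path | IO[str]) -> list[DoseEvent]:
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        text = Path(source).read_text(encoding="utf-8")
    events = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            events.append(DoseEvent.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise LogValidationError(f"bad event on line {i}: {exc}") from exc
    return events
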