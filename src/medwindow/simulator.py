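"""Synthetic user behavior and synthetic formularies.

The simulator drives the decision engine with randomized app-open events so
every rule — on-time takes, snoozes, overdue recommendations, the
take-or-skip prompt, and expiry — is exercisable without patient data.
Behavioral distributions are purely illustrative defaults, not empirical.

Reproducibility: each dose slot consumes its own pseudorandom stream keyed
by ``(seed, slot_id)``, so per-slot outcomes do not depend on iteration
order, and all draws for a slot are made up front so changing one parameter
(e.g. the safe window) never re-routes randomness between slots.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .adherence import AdherenceSummary, summarize
from .engine import Action, DoseEvent, DoseStatus, Engine, LAST_SLOT_GRACE
from .formulary import Formulary, MedicationEntry, make_entry
from .schedule import Regimen, generate_slots

__all__ = [
    "DelayModel",
    "BehaviorModel",
    "simulate",
    "generate_synthetic_formulary",
]

#: Delays are in minutes relative to the intended dose time and must stay
#: inside the dosing window's open end: strictly above -60.
_MIN_DELAY_MINUTES = -59.0


@dataclass(frozen=True)
class DelayModel:
    """Distribution of (app-open time − intended time) in minutes."""

    kind: str = "lognormal"  # "point" or "lognormal"
    minutes: float = 0.0  # point mass location
    median_minutes: float = 5.0
    sigma: float = 3.0

    @classmethod
    def point(cls, minutes: float) -> "DelayModel":
        return cls(kind="point", minutes=float(minutes))

    @classmethod
    def lognormal(cls, median_minutes: float = 5.0, sigma: float = 3.0) -> "DelayModel":
        return cls(kind="lognormal", median_minutes=float(median_minutes), sigma=float(sigma))

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            rng.random()  # burn one draw so all kinds consume equally
            value = self.minutes
        elif self.kind == "lognormal":
            value = float(rng.lognormal(mean=np.log(self.median_minutes), sigma=self.sigma))
        else:
            raise ValueError(f"unknown delay kind {self.kind!r}")
        return max(value, _MIN_DELAY_MINUTES)


@dataclass(frozen=True)
class BehaviorModel:
    """Illustrative app-usage behavior (non-empirical defaults)."""

    open_probability: float = 0.9
    delay: DelayModel = DelayModel()
    overdue_take_probability: float = 0.25
    snooze_probability: float = 0.2
    take_next_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "open_probability",
            "overdue_take_probability",
            "snooze_probability",
            "take_next_probability",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _slot_draws(model: BehaviorModel, slot_id: int) -> dict[str, float]:
    rng = np.random.default_rng([model.seed, slot_id])
    return {
        "open": float(rng.random()),
        "delay": model.delay.sample(rng),
        "snooze": float(rng.random()),
        "overdue_take": float(rng.random()),
        "take_next": float(rng.random()),
    }


def simulate(
    regimen: Regimen,
    formulary: Formulary,
    model: BehaviorModel,
    n_days: int,
) -> tuple[list[DoseEvent], AdherenceSummary]:
    """Run the behavior model against the engine for ``n_days``.

    Every emitted action is applied through the engine, so it is legal for
    the slot's status at its timestamp by construction; the returned log
    replays cleanly.  Events come back in timestamp order.
    """
    regimen = regimen.with_days(n_days)
    if n_days < 1:
        return [], summarize([], [])
    slots = generate_slots(regimen, formulary)
    engine = Engine(slots)

    # App opens are processed in chronological order (the engine requires a
    # forward-moving clock); a heavily delayed open can land after the next
    # slot's, so a simple slot-order walk would run time backwards.
    agenda: list[tuple[datetime, int, bool]] = []  # (when, slot_id, post_snooze)
    all_draws: dict[int, dict[str, float]] = {}
    for slot in slots:
        draws = _slot_draws(model, slot.slot_id)
        all_draws[slot.slot_id] = draws
        if draws["open"] >= model.open_probability:
            continue  # never opened; expiry will mark it missed
        t_open = slot.intended_time + timedelta(minutes=round(draws["delay"]))
        agenda.append((t_open, slot.slot_id, False))
    heapq.heapify(agenda)

    while agenda:
        t, slot_id, post_snooze = heapq.heappop(agenda)
        slot = slots[slot_id]
        draws = all_draws[slot_id]
        engine.expire(t)
        if engine.is_resolved(slot_id):
            continue  # lapsed (or skipped via a prompt) before this open
        status = engine.classify(t, slot_id)
        if (
            status is DoseStatus.ACT_NOW
            and not post_snooze
            and draws["snooze"] < model.snooze_probability
        ):
            ev, _ = engine.apply(slot_id, Action.SNOOZE, t)
            heapq.heappush(agenda, (ev.reminder_at, slot_id, True))
            continue
        if status is DoseStatus.ACT_NOW:
            engine.apply(slot_id, Action.TAKE, t)
        elif status is DoseStatus.OVERDUE:
            if draws["overdue_take"] < model.overdue_take_probability:
                _, decision = engine.apply(slot_id, Action.TAKE, t)
                if decision is not None:
                    choice = (
                        Action.TAKE_NEXT
                        if draws["take_next"] < model.take_next_probability
                        else Action.SKIP_NEXT
                    )
                    engine.apply(decision.next_slot_id, choice, t)
            else:
                engine.apply(slot_id, Action.SKIP, t)

    end = slots[-1].window_end + LAST_SLOT_GRACE + timedelta(minutes=1)
    engine.expire(end)
    events = sorted(engine.events, key=lambda e: e.timestamp)
    return events, summarize(engine.events, slots)


# -- synthetic formularies ------------------------------------------------

_SYLLABLES = (
    "al", "be", "car", "dol", "el", "fen", "gli", "hy", "iso", "jun",
    "kel", "lor", "met", "nol", "oxa", "per", "quin", "ral", "sel", "tam",
    "ur", "vel", "zan",
)
_SUFFIXES = ("pril", "sartan", "olol", "dipine", "zide", "mide", "ren", "statin")
_BASE_DOSES = (1.0, 2.5, 5.0, 10.0, 12.5, 20.0, 25.0, 40.0, 50.0, 80.0, 100.0)
_WINDOWS = (2.0, 3.0, 4.0, 6.0)


def _component_name(rng: np.random.Generator) -> str:
    n = int(rng.integers(1, 3))
    stem = "".join(rng.choice(_SYLLABLES) for _ in range(n))
    return stem + str(rng.choice(_SUFFIXES))


def generate_synthetic_formulary(n_entries: int, seed: int) -> Formulary:
    """An invariant-satisfying random formulary for fuzzing.

    Deterministic in ``seed``; includes single, double, and triple
    combination products whenever ``n_entries >= 3``.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[MedicationEntry] = []
    used_names: set[str] = set()
    for i in range(n_entries):
        # guarantee coverage of 1-, 2-, and 3-component products early on
        n_comp = i + 1 if i < 3 and n_entries >= 3 else int(rng.choice((1, 1, 1, 2, 2, 3)))
        while True:
            comps = []
            while len(comps) < n_comp:
                c = _component_name(rng)
                if c not in comps:
                    comps.append(c)
            name = "-".join(comps)
            if name not in used_names:
                used_names.add(name)
                break
        freq = int(rng.choice((1, 1, 1, 2, 2, 3)))
        window = float(rng.choice([w for w in _WINDOWS if w < 24 / freq - 1]))
        lo = tuple(float(rng.choice(_BASE_DOSES)) for _ in range(n_comp))
        mult = int(rng.choice((1, 2, 4, 8)))
        hi = tuple(d * mult for d in lo)
        if lo == hi:
            options = [lo]
        else:
            n_opts = int(rng.integers(2, 6))
            options = [
                tuple(a + (b - a) * k / (n_opts - 1) for a, b in zip(lo, hi))
                for k in range(n_opts)
            ]
        brands = [str(rng.choice(_SYLLABLES)).capitalize() + "ex"] if rng.random() < 0.5 else []
        entries.append(
            make_entry(
                name,
                brands,
                min_dose_mg=lo,
                max_dose_mg=hi,
                frequency_per_day=freq,
                safe_window_hours=window,
                dose_options=options,
            )
        )
    entries.sort(key=lambda e: (e.generic_name, e.frequency_per_day))
    return Formulary(entries=tuple(entries), version=f"synthetic-seed-{seed}")
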