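"""Exception hierarchy.

Every domain failure derives from :class:`MedWindowError` so the CLI can map
it to exit code 1, keeping exit code 2 for usage errors.
"""

from __future__ import annotations


class MedWindowError(Exception):
    """Base class for all domain errors."""

    rule_id: str = "error"


class FormularyError(MedWindowError):
    rule_id = "formulary"


class FormularyParseError(FormularyError):
    """Malformed formulary input; carries row/column context when known."""

    rule_id = "parse"

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        where = ""
        if row is not None:
            where += f" (row {row}"
            where += f", column {column!r})" if column else ")"
        elif column:
            where += f" (column {column!r})"
        super().__init__(message + where)


class NotFoundError(FormularyError):
    """Medication name not present; carries near-match suggestions."""

    rule_id = "not-found"

    def __init__(self, name: str, suggestions: list[str] | None = None):
        self.name = name
        self.suggestions = suggestions or []
        msg = f"medication {name!r} not found in formulary"
        if self.suggestions:
            msg += f"; near matches: {', '.join(self.suggestions)}"
        super().__init__(msg)


class FrequencyNotCoveredError(FormularyError):
    """Known medication but the requested dosing frequency has no entry.

    Deliberately distinct from :class:`NotFoundError`: a safe window for an
    unlisted frequency must never be invented or interpolated.
    """

    rule_id = "frequency-not-covered"

    def __init__(self, name: str, frequency_per_day: int, available: list[int]):
        self.name = name
        self.frequency_per_day = frequency_per_day
        self.available = available
        super().__init__(
            f"{name!r} has no entry at frequency {frequency_per_day}/day; "
            f"covered frequencies: {sorted(available)}"
        )


class DoseArityError(FormularyError):
    rule_id = "dose-arity"


class RegimenError(MedWindowError):
    rule_id = "regimen"


class WindowsOverlapError(RegimenError):
    rule_id = "windows-overlap"


class EngineError(MedWindowError):
    rule_id = "engine"


class AlreadyResolvedError(EngineError):
    rule_id = "already-resolved"


class IllegalActionError(EngineError):
    rule_id = "illegal-action"


class PendingDecisionError(EngineError):
    rule_id = "pending-next-dose-decision"


class SnoozeLimitError(EngineError):
    rule_id = "snooze-limit"


class LogValidationError(MedWindowError):
    rule_id = "log-validation"
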