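"""Safe-window formulary: loading, validation, and lookup.

The formulary is the data table that parameterizes all decision logic: one
row per medication x dosing frequency, carrying per-component dose bounds,
selectable dose options, and the safe window (hours after the intended time
during which a missed dose may still be taken).

Canonical on-disk formats are a 7-column CSV
(``generic_name,brand_names,min_dose_mg,max_dose_mg,frequency_per_day,
safe_window_hours,dose_options``) and an equivalent versioned JSON schema.
Combination-product dose strings like ``5-12.5-20`` split into component
tuples; en-dash, em-dash, and hyphen are all accepted and canonicalized to
hyphen, and thousands separators (``1,200``) are stripped.
"""

from __future__ import annotations

import csv
import difflib
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import (
    DoseArityError,
    FormularyParseError,
    FrequencyNotCoveredError,
    NotFoundError,
)

__all__ = [
    "MedicationEntry",
    "Formulary",
    "ValidationReport",
    "canonical_name",
    "load_formulary",
    "write_formulary",
    "lookup",
    "validate_formulary",
    "validate_dose",
    "example_formulary",
    "EXAMPLE_FIXTURE",
]

CSV_COLUMNS = (
    "generic_name",
    "brand_names",
    "min_dose_mg",
    "max_dose_mg",
    "frequency_per_day",
    "safe_window_hours",
    "dose_options",
)

JSON_SCHEMA_VERSION = 1

#: Dash-like code points accepted in names and dose strings.
_DASHES = re.compile(r"[‐‑‒–—―−-]")
_THOUSANDS = re.compile(r"(?<=\d),(?=\d{3}(?:\D|$))")

EXAMPLE_FIXTURE = Path(__file__).parent / "data" / "safe_windows_example.csv"


def canonical_name(name: str) -> str:
    """Lowercase, collapse whitespace, and normalize all dashes to hyphen."""
    name = _DASHES.sub("-", name.strip().lower())
    return re.sub(r"\s+", " ", name)


def _parse_number(text: str) -> float:
    return float(_THOUSANDS.sub("", text.strip()))


def _parse_dose_tuple(text: str) -> tuple[float, ...]:
    text = _DASHES.sub("-", _THOUSANDS.sub("", text.strip()))
    parts = [p for p in text.split("-") if p.strip()]
    if not parts:
        raise ValueError(f"empty dose string {text!r}")
    return tuple(float(p) for p in parts)


def _format_number(x: float) -> str:
    # repr round-trips floats exactly; integers print without the ".0"
    return str(int(x)) if x == int(x) else repr(x)


def _format_dose_tuple(dose: tuple[float, ...]) -> str:
    return "-".join(_format_number(d) for d in dose)


@dataclass(frozen=True)
class MedicationEntry:
    """One formulary row: a medication (or combination product) at one
    dosing frequency, with its dose bounds, options, and safe window."""

    generic_name: str
    brand_names: tuple[str, ...]
    components: tuple[str, ...]
    min_dose_mg: tuple[float, ...]
    max_dose_mg: tuple[float, ...]
    frequency_per_day: int
    safe_window_hours: float
    dose_options: tuple[tuple[float, ...], ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.generic_name, self.frequency_per_day)

    @property
    def is_combination(self) -> bool:
        return len(self.components) >= 2

    def violations(self) -> list[tuple[str, str]]:
        """All structural-rule violations as (rule id, message) pairs."""
        out: list[tuple[str, str]] = []
        k = len(self.components)
        if not 1 <= k <= 3:
            out.append(("component-count", f"{k} components; must be 1-3"))
        if len(self.min_dose_mg) != k or len(self.max_dose_mg) != k:
            out.append(
                (
                    "dose-arity",
                    f"dose tuples have arity ({len(self.min_dose_mg)}, "
                    f"{len(self.max_dose_mg)}) but entry has {k} components",
                )
            )
        elif any(lo > hi for lo, hi in zip(self.min_dose_mg, self.max_dose_mg)):
            out.append(
                (
                    "dose-bounds",
                    f"min dose {self.min_dose_mg} exceeds max {self.max_dose_mg}",
                )
            )
        if self.frequency_per_day < 1:
            out.append(("frequency-positive", f"frequency {self.frequency_per_day} < 1"))
        else:
            if self.safe_window_hours <= 0:
                out.append(("window-positive", f"safe window {self.safe_window_hours} <= 0"))
            elif self.safe_window_hours >= 24 / self.frequency_per_day:
                out.append(
                    (
                        "window-exceeds-interval",
                        f"safe window {self.safe_window_hours} h does not end before "
                        f"the next intended dose ({24 / self.frequency_per_day:g} h apart)",
                    )
                )
        if not 1 <= len(self.dose_options) <= 11:
            out.append(
                ("dose-options-count", f"{len(self.dose_options)} dose options; must be 1-11")
            )
        for opt in self.dose_options:
            if len(opt) != len(self.min_dose_mg):
                out.append(("dose-option-arity", f"dose option {opt} has wrong arity"))
            elif not all(
                lo <= d <= hi for d, lo, hi in zip(opt, self.min_dose_mg, self.max_dose_mg)
            ):
                out.append(
                    ("dose-option-range", f"dose option {opt} outside [min, max] bounds")
                )
        return out

    def to_dict(self) -> dict:
        return {
            "generic_name": self.generic_name,
            "brand_names": list(self.brand_names),
            "components": list(self.components),
            "min_dose_mg": list(self.min_dose_mg),
            "max_dose_mg": list(self.max_dose_mg),
            "frequency_per_day": self.frequency_per_day,
            "safe_window_hours": self.safe_window_hours,
            "dose_options": [list(o) for o in self.dose_options],
        }


def make_entry(
    generic_name: str,
    brand_names: Iterable[str] = (),
    *,
    min_dose_mg: Iterable[float],
    max_dose_mg: Iterable[float],
    frequency_per_day: int,
    safe_window_hours: float,
    dose_options: Iterable[Iterable[float]] | None = None,
    components: Iterable[str] | None = None,
) -> MedicationEntry:
    """Build an entry with canonical naming and defaulted fields.

    When ``components`` is omitted it is derived by splitting the canonical
    generic name on hyphens (combination products are named that way).  When
    ``dose_options`` is omitted the min and max dose tuples become the only
    selectable options.
    """
    name = canonical_name(generic_name)
    comps = tuple(components) if components is not None else tuple(name.split("-"))
    lo = tuple(float(x) for x in min_dose_mg)
    hi = tuple(float(x) for x in max_dose_mg)
    if dose_options is None:
        opts = (lo,) if lo == hi else (lo, hi)
    else:
        opts = tuple(tuple(float(x) for x in o) for o in dose_options)
    return MedicationEntry(
        generic_name=name,
        brand_names=tuple(b.strip() for b in brand_names if b.strip()),
        components=comps,
        min_dose_mg=lo,
        max_dose_mg=hi,
        frequency_per_day=int(frequency_per_day),
        safe_window_hours=float(safe_window_hours),
        dose_options=opts,
    )


@dataclass(frozen=True)
class Formulary:
    entries: tuple[MedicationEntry, ...]
    version: str = "unversioned"

    def __iter__(self) -> Iterator[MedicationEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def generic_names(self) -> list[str]:
        return sorted({e.generic_name for e in self.entries})


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": [
                {"entry": k, "rule": r, "message": m} for k, r, m in self.errors
            ],
            "warnings": [
                {"entry": k, "rule": r, "message": m} for k, r, m in self.warnings
            ],
        }


def _sort_key(entry: MedicationEntry) -> tuple[str, int]:
    return (entry.generic_name, entry.frequency_per_day)


def _open_source(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, str) and ("\n" in source or source.lstrip().startswith("[")):
        return io.StringIO(source)
    path = Path(source)
    if path.exists():
        return path.open("r", encoding="utf-8")
    raise FileNotFoundError(source)


def load_formulary(
    source: str | Path | IO[str],
    format: str = "csv",
    *,
    version: str | None = None,
    strict: bool = True,
) -> Formulary:
    """Parse and validate a formulary from CSV or JSON.

    Raises :class:`FormularyParseError` on malformed rows, duplicate
    (generic name, frequency) keys, structural-rule violations, or empty
    input.  Entries are returned in canonical (name, frequency) order.
    With ``strict=False``, rows that parse but break structural rules are
    kept so :func:`validate_formulary` can enumerate every violation.
    """
    stream = _open_source(source)
    try:
        if format == "csv":
            entries = list(_read_csv(stream))
        elif format == "json":
            entries, version_in = _read_json(stream)
            version = version if version is not None else version_in
        else:
            raise FormularyParseError(f"unknown format {format!r}")
    finally:
        if stream is not source:
            stream.close()
    if not entries:
        raise FormularyParseError("no entries")
    if strict:
        seen: dict[tuple[str, int], int] = {}
        for i, entry in enumerate(entries):
            bad = entry.violations()
            if bad:
                rule, msg = bad[0]
                raise FormularyParseError(
                    f"entry {entry.generic_name!r} violates rule {rule!r}: {msg}",
                    row=i + 1,
                )
            if entry.key in seen:
                raise FormularyParseError(
                    f"duplicate (generic_name, frequency) key {entry.key}", row=i + 1
                )
            seen[entry.key] = i
    return Formulary(
        entries=tuple(sorted(entries, key=_sort_key)),
        version=version if version is not None else "unversioned",
    )


def _read_csv(stream: IO[str]) -> Iterator[MedicationEntry]:
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        return
    missing = [c for c in CSV_COLUMNS[:-1] if c not in reader.fieldnames]
    if missing:
        raise FormularyParseError(f"missing required columns: {missing}")
    for i, row in enumerate(reader, start=1):
        yield _entry_from_row(row, i)


def _entry_from_row(row: dict[str, str], rownum: int) -> MedicationEntry:
    def cell(col: str) -> str:
        return (row.get(col) or "").strip()

    try:
        brands_cell = cell("brand_names")
        brands = () if brands_cell in ("", "N") else tuple(
            b.strip() for b in brands_cell.split(",") if b.strip()
        )
        min_dose = _parse_dose_tuple(cell("min_dose_mg"))
        max_dose = _parse_dose_tuple(cell("max_dose_mg"))
        freq = int(cell("frequency_per_day"))
        window = _parse_number(cell("safe_window_hours"))
        opts_cell = cell("dose_options")
        opts = (
            None
            if not opts_cell
            else [_parse_dose_tuple(o) for o in opts_cell.split(";") if o.strip()]
        )
        return make_entry(
            cell("generic_name"),
            brands,
            min_dose_mg=min_dose,
            max_dose_mg=max_dose,
            frequency_per_day=freq,
            safe_window_hours=window,
            dose_options=opts,
        )
    except (ValueError, KeyError) as exc:
        raise FormularyParseError(f"malformed row: {exc}", row=rownum) from exc


def _read_json(stream: IO[str]) -> tuple[list[MedicationEntry], str]:
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise FormularyParseError(f"invalid JSON: {exc}") from exc
    if isinstance(doc, dict):
        version = str(doc.get("version", "unversioned"))
        items = doc.get("entries", [])
    else:
        version, items = "unversioned", doc
    entries = []
    for i, item in enumerate(items, start=1):
        try:
            entries.append(
                make_entry(
                    item["generic_name"],
                    item.get("brand_names", ()),
                    min_dose_mg=item["min_dose_mg"],
                    max_dose_mg=item["max_dose_mg"],
                    frequency_per_day=item["frequency_per_day"],
                    safe_window_hours=item["safe_window_hours"],
                    dose_options=item.get("dose_options"),
                    components=item.get("components"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormularyParseError(f"malformed entry: {exc}", row=i) from exc
    return entries, version


def write_formulary(
    formulary: Formulary, dest: str | Path | IO[str] | None = None, format: str = "csv"
) -> str:
    """Serialize canonically (sorted, hyphens, no thousands separators).

    Returns the serialized text; also writes it to ``dest`` when given.
    """
    entries = sorted(formulary.entries, key=_sort_key)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.generic_name,
                    ", ".join(e.brand_names) if e.brand_names else "N",
                    _format_dose_tuple(e.min_dose_mg),
                    _format_dose_tuple(e.max_dose_mg),
                    e.frequency_per_day,
                    _format_number(e.safe_window_hours),
                    ";".join(_format_dose_tuple(o) for o in e.dose_options),
                ]
            )
        text = buf.getvalue()
    elif format == "json":
        text = json.dumps(
            {
                "schema_version": JSON_SCHEMA_VERSION,
                "version": formulary.version,
                "entries": [e.to_dict() for e in entries],
            },
            indent=2,
        )
    else:
        raise FormularyParseError(f"unknown format {format!r}")
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text, encoding="utf-8")
    return text


def lookup(formulary: Formulary, name: str, frequency_per_day: int) -> MedicationEntry:
    """Resolve a generic or brand name (case-insensitive) at a frequency.

    Unknown names raise :class:`NotFoundError` with near matches; a known
    name at an unlisted frequency raises :class:`FrequencyNotCoveredError`
    so callers can refuse to invent a safe window.
    """
    wanted = canonical_name(name)
    by_generic: dict[str, list[MedicationEntry]] = {}
    by_brand: dict[str, set[str]] = {}
    for e in formulary.entries:
        by_generic.setdefault(e.generic_name, []).append(e)
        for b in e.brand_names:
            by_brand.setdefault(canonical_name(b), set()).add(e.generic_name)
    generic = wanted
    if generic not in by_generic:
        brands = by_brand.get(wanted)
        if brands and len(brands) == 1:
            generic = next(iter(brands))
        elif brands:
            raise NotFoundError(name, sorted(brands))
        else:
            pool = list(by_generic) + list(by_brand)
            raise NotFoundError(name, difflib.get_close_matches(wanted, pool, n=3))
    candidates = by_generic[generic]
    for e in candidates:
        if e.frequency_per_day == int(frequency_per_day):
            return e
    raise FrequencyNotCoveredError(
        generic, int(frequency_per_day), [e.frequency_per_day for e in candidates]
    )


#: Safe windows seen in the published excerpt; anything else is flagged as a
#: warning (legal, but worth a second look against the source table).
_TYPICAL_WINDOWS = {2.0, 3.0, 4.0, 6.0}


def validate_formulary(formulary: Formulary) -> ValidationReport:
    """Check every structural rule; violations are reported, not raised."""
    report = ValidationReport()
    seen: set[tuple[str, int]] = set()
    for entry in formulary.entries:
        key = f"{entry.generic_name}@{entry.frequency_per_day}"
        for rule, msg in entry.violations():
            report.errors.append((key, rule, msg))
        if entry.key in seen:
            report.errors.append((key, "duplicate-key", "duplicate (generic_name, frequency)"))
        seen.add(entry.key)
        if entry.safe_window_hours not in _TYPICAL_WINDOWS:
            report.warnings.append(
                (key, "unusual-window", f"safe window {entry.safe_window_hours} h is atypical")
            )
    keys = [_sort_key(e) for e in formulary.entries]
    if keys != sorted(keys):
        report.errors.append(("*", "ordering", "entries not in canonical alphabetical order"))
    return report


def validate_dose(entry: MedicationEntry, dose: Iterable[float]) -> bool:
    """True iff ``dose`` exactly matches one of the entry's dose options."""
    dose_t = tuple(float(d) for d in dose)
    if len(dose_t) != len(entry.components):
        raise DoseArityError(
            f"dose {dose_t} has arity {len(dose_t)} but "
            f"{entry.generic_name!r} has {len(entry.components)} components"
        )
    return any(
        len(opt) == len(dose_t) and all(abs(a - b) < 1e-9 for a, b in zip(opt, dose_t))
        for opt in entry.dose_options
    )


def example_formulary() -> Formulary:
    """The shipped 21-row published-excerpt fixture."""
    return load_formulary(EXAMPLE_FIXTURE, "csv", version="published-excerpt")
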