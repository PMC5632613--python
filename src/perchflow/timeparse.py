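"""Flexible timestamp parsing driven by a token-order specification.

RFID loggers write timestamps in many dialects ("2017-05-21 14:50:43",
"31/12/17 09:12 pm", ...).  Rather than a strftime pattern, the order of the
fields is given as a compact spec string over the letters

    y  year (2- or 4-digit)    H  hour
    m  month                   M  minute
    d  day                     S  second
                               p  am/pm marker

e.g. ``"ymd HMS"`` or ``"dmy HM p"``.  Separators in the data (``-``, ``/``,
``:``, ``.``, space) are ignored; only the order of the numeric fields
matters.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass

from .errors import ParseError, TimeSpecError

_VALID_TOKENS = "ymdHMSp"
_FIELD_RE = re.compile(r"[0-9]+|[A-Za-z]+")

#: POSIX-style pivot for 2-digit years: 00-68 -> 2000s, 69-99 -> 1900s.
_YEAR_PIVOT = 68


@dataclass(frozen=True)
class TimeSpec:
    """Ordered timestamp field specification."""

    tokens: tuple[str, ...]

    def __str__(self) -> str:
        return "".join(self.tokens)

    @property
    def has_time(self) -> bool:
        return "H" in self.tokens


def parse_time_spec(spec: str | TimeSpec) -> TimeSpec:
    """Validate a spec string such as ``"ymd HMS"`` and return a :class:`TimeSpec`.

    Raises :class:`TimeSpecError` naming the offending token for unknown or
    repeated letters, for a ``p`` (am/pm) marker without an hour, and for
    minute/second fields without their coarser neighbour.
    """
    if isinstance(spec, TimeSpec):
        return spec
    letters = [c for c in spec if not c.isspace()]
    for c in letters:
        if c not in _VALID_TOKENS:
            raise TimeSpecError(f"unknown token {c!r} in time format {spec!r}")
    seen: set[str] = set()
    for c in letters:
        if c in seen:
            raise TimeSpecError(f"repeated token {c!r} in time format {spec!r}")
        seen.add(c)
    for required in "ymd":
        if required not in seen:
            raise TimeSpecError(f"time format {spec!r} is missing token {required!r}")
    if "p" in seen and "H" not in seen:
        raise TimeSpecError(f"token 'p' requires an hour token 'H' in {spec!r}")
    if "M" in seen and "H" not in seen:
        raise TimeSpecError(f"token 'M' requires token 'H' in {spec!r}")
    if "S" in seen and "M" not in seen:
        raise TimeSpecError(f"token 'S' requires token 'M' in {spec!r}")
    return TimeSpec(tuple(letters))


def _expand_year(raw: str) -> int:
    value = int(raw)
    if len(raw) > 2:
        return value
    return 2000 + value if value <= _YEAR_PIVOT else 1900 + value


def parse_timestamp(value: str, spec: TimeSpec) -> dt.datetime:
    """Parse one timestamp string under *spec* into a naive datetime.

    Impossible calendar values (month 13, hour 25, ...) raise
    :class:`ParseError`.
    """
    fields = _FIELD_RE.findall(str(value).strip())
    if len(fields) != len(spec.tokens):
        raise ParseError(
            f"expected {len(spec.tokens)} fields ({spec}) but found "
            f"{len(fields)} in {value!r}"
        )
    parts: dict[str, int] = {}
    ampm: str | None = None
    for raw, token in zip(fields, spec.tokens):
        if token == "p":
            marker = raw.lower()
            if marker not in ("am", "pm"):
                raise ParseError(f"expected am/pm marker, found {raw!r} in {value!r}")
            ampm = marker
        else:
            if not raw.isdigit():
                raise ParseError(f"expected digits for token {token!r}, found {raw!r} in {value!r}")
            parts[token] = _expand_year(raw) if token == "y" else int(raw)
    hour = parts.get("H", 0)
    if ampm is not None:
        if not 1 <= hour <= 12:
            raise ParseError(f"hour {hour} out of 1-12 range for am/pm time {value!r}")
        hour = hour % 12 + (12 if ampm == "pm" else 0)
    try:
        return dt.datetime(
            parts["y"], parts["m"], parts["d"], hour, parts.get("M", 0), parts.get("S", 0)
        )
    except ValueError as exc:
        raise ParseError(f"invalid calendar time {value!r}: {exc}") from exc
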