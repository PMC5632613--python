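"""Loading, georeferencing and writing detection tables.

A *detection table* is a :class:`pandas.DataFrame` with one row per RFID read
and at least the columns ``animal_id``, ``logger_id`` and ``time`` (tz-aware,
1-second precision).  A ``date`` column (local calendar date) is derived on
load, rows are sorted by ``(animal_id, time)``, and any further columns
(species, sex, experiment, coordinates, ...) are carried through unmodified.

Two input shapes are supported:

* pre-formatted labeled tables (:func:`load_format`, :func:`read_detections`);
* raw per-logger text files with three unlabeled columns — animal id, date,
  time — in three dialects (:func:`load_raw_file`, :func:`load_raw_all`):
  ``details=1`` logger id on the first line; ``details=2`` logger id on the
  first line and a ``lat, lon`` pair on the second; ``details=0`` logger id
  taken from the file name.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .timeparse import TimeSpec, parse_time_spec, parse_timestamp

REQUIRED_COLUMNS = ("animal_id", "logger_id", "time")

_SEP_ALIASES = {
    "whitespace": None, "ws": None, None: None,
    ",": ",", "comma": ",",
    ";": ";", "semicolon": ";",
}

_COORD_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d+)?)\s*,\s*([+-]?\d+(?:\.\d+)?)\s*$"
)


def _check_coordinates(df: pd.DataFrame) -> None:
    if "lat" in df.columns:
        lat = pd.to_numeric(df["lat"], errors="coerce")
        bad = lat.notna() & ((lat < -90) | (lat > 90))
        if bad.any():
            raise ValidationError(f"latitude out of [-90, 90] at rows {list(df.index[bad])}")
        df["lat"] = lat
    if "lon" in df.columns:
        lon = pd.to_numeric(df["lon"], errors="coerce")
        bad = lon.notna() & ((lon < -180) | (lon > 180))
        if bad.any():
            raise ValidationError(f"longitude out of [-180, 180] at rows {list(df.index[bad])}")
        df["lon"] = lon


def _localize(naive: list, tz: str, n: int) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(naive)
    # Ambiguous wall times during DST fall-back resolve to the earlier offset;
    # nonexistent spring-forward times are an error.
    return idx.tz_localize(tz, ambiguous=np.full(n, True), nonexistent="raise")


def load_format(
    table: pd.DataFrame,
    time_format: str | TimeSpec = "ymd HMS",
    tz: str = "UTC",
    dedup: bool = False,
) -> pd.DataFrame:
    """Format a labeled table of reads into a canonical detection table.

    Parameters
    ----------
    table
        Must contain ``animal_id``, ``logger_id`` and ``time`` columns; any
        other columns are carried through.
    time_format
        Field-order spec for the ``time`` column (see :mod:`.timeparse`).
    tz
        IANA timezone name the timestamps are recorded in.
    dedup
        Drop rows that are exact duplicates across all columns.  Default is
        to keep them: duplicate reads within a second are consolidated by the
        visits transformation anyway.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    spec = parse_time_spec(time_format)
    df = table.copy()
    df["animal_id"] = df["animal_id"].astype(str).str.strip()
    df["logger_id"] = df["logger_id"].astype(str).str.strip()
    if (df["animal_id"] == "").any() or (df["logger_id"] == "").any():
        raise ValidationError("empty animal_id or logger_id")

    naive = []
    for i, value in enumerate(df["time"]):
        try:
            naive.append(parse_timestamp(value, spec))
        except ParseError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    times = _localize(naive, tz, len(df))
    df = df.drop(columns=["time"])
    df.insert(1, "time", times)
    df["date"] = times.date

    _check_coordinates(df)
    if dedup:
        df = df.drop_duplicates()
    df = df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)
    front = ["animal_id", "time", "logger_id", "date"]
    df = df[front + [c for c in df.columns if c not in front]]
    df.attrs["tz"] = tz
    return df


def _split_line(line: str, sep: str | None) -> list[str]:
    if sep is None:
        return line.split()
    return [f.strip() for f in line.split(sep)]


def load_raw_file(
    path: str | Path,
    details: int = 1,
    sep: str | None = "whitespace",
    time_format: str | TimeSpec = "mdy HMS",
    logger_pattern: str | None = None,
    tz: str = "UTC",
) -> pd.DataFrame:
    """Load one raw logger file into a detection table.

    Data lines hold exactly three unlabeled columns — animal id, date, time —
    separated by runs of whitespace or by a literal ``,``/``;``.  Where the
    logger id (and, for ``details=2``, its coordinates) come from is governed
    by *details*; ``logger_pattern`` is a regular expression applied to the
    file name under ``details=0`` (group 1 is used when the pattern has
    groups, otherwise the whole match; without a pattern the file stem is the
    logger id).
    """
    path = Path(path)
    if details not in (0, 1, 2):
        raise ValidationError(f"details must be 0, 1 or 2, got {details!r}")
    if sep not in _SEP_ALIASES:
        raise ValidationError(f"sep must be whitespace, ',' or ';', got {sep!r}")
    sep_char = _SEP_ALIASES[sep]

    lines = path.read_text(encoding="utf-8").splitlines()
    lat = lon = None
    logger_id: str
    start = 0
    if details in (1, 2):
        if not lines or not lines[0].strip():
            raise ValidationError(f"{path}: empty logger_id in first line")
        logger_id = lines[0].strip()
        # a header that splits like a data line means the file is headerless
        if len(_split_line(logger_id, sep_char)) != 1:
            raise ValidationError(
                f"{path}: first line {logger_id!r} does not look like a logger id "
                f"(wrong details value for this file?)"
            )
        start = 1
        if details == 2:
            if len(lines) < 2:
                raise ParseError(f"{path}: missing coordinate line")
            m = _COORD_RE.match(lines[1])
            if not m:
                raise ParseError(f"{path}: malformed coordinate line {lines[1]!r}")
            lat, lon = float(m.group(1)), float(m.group(2))
            start = 2
    else:
        if logger_pattern is not None:
            m = re.search(logger_pattern, path.name)
            if not m:
                raise ValidationError(
                    f"logger_pattern {logger_pattern!r} matched nothing in file name {path.name!r}"
                )
            logger_id = m.group(1) if m.groups() else m.group(0)
        else:
            logger_id = path.stem

    animals, stamps = [], []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = _split_line(line, sep_char)
        if len(fields) != 3:
            raise ParseError(f"{path}, line {lineno}: expected 3 columns, got {len(fields)}")
        animals.append(fields[0])
        stamps.append(f"{fields[1]} {fields[2]}")

    df = pd.DataFrame({"animal_id": animals, "logger_id": logger_id, "time": stamps})
    if details == 2:
        df["lat"] = lat
        df["lon"] = lon
    if df.empty:
        df = df.astype({"animal_id": str, "logger_id": str})
    return load_format(df, time_format=time_format, tz=tz)


def load_raw_all(
    r_dir: str | Path,
    details: int = 1,
    sep: str | None = "whitespace",
    time_format: str | TimeSpec = "mdy HMS",
    logger_pattern: str | None = None,
    tz: str = "UTC",
) -> pd.DataFrame:
    """Load and combine every raw logger file in a directory.

    Several files may belong to one logger; their records are merged and the
    combined table re-sorted by ``(animal_id, time)``.
    """
    r_dir = Path(r_dir)
    files = sorted(p for p in r_dir.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise ValidationError(f"no data files found in {r_dir}")
    parts = [
        load_raw_file(p, details=details, sep=sep, time_format=time_format,
                      logger_pattern=logger_pattern, tz=tz)
        for p in files
    ]
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)
    df.attrs["tz"] = tz
    return df


class LoggerIndex:
    """Mapping of logger ids to WGS84 coordinates (``logger_id``, ``lat``, ``lon``)."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ("logger_id", "lat", "lon") if c not in table.columns]
        if missing:
            raise ValidationError(f"logger index missing column(s): {', '.join(missing)}")
        df = table.copy()
        df["logger_id"] = df["logger_id"].astype(str).str.strip()
        dup = df["logger_id"][df["logger_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate logger_id in index: {sorted(set(dup))}")
        _check_coordinates(df)
        self.table = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LoggerIndex":
        return cls(pd.read_csv(path, dtype={"logger_id": str}))

    def coords(self) -> dict[str, tuple[float, float]]:
        return {
            r.logger_id: (r.lat, r.lon) for r in self.table.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.table)


def merge_logger_index(
    d: pd.DataFrame, idx: LoggerIndex | pd.DataFrame, overwrite: bool = False
) -> pd.DataFrame:
    """Attach station coordinates to a detection table by ``logger_id``.

    Coordinates already present are kept unless ``overwrite=True``.  Loggers
    absent from the index keep missing coordinates; their ids are listed in a
    warning and in ``result.attrs["unmatched_loggers"]``.
    """
    if not isinstance(idx, LoggerIndex):
        idx = LoggerIndex(idx)
    coords = idx.coords()
    out = d.copy()
    lat = out["logger_id"].map({k: v[0] for k, v in coords.items()})
    lon = out["logger_id"].map({k: v[1] for k, v in coords.items()})
    for col, new in (("lat", lat), ("lon", lon)):
        if col not in out.columns or overwrite:
            out[col] = new
        else:
            out[col] = out[col].where(out[col].notna(), new)
    unmatched = sorted(set(out["logger_id"]) - set(coords))
    out.attrs = dict(d.attrs)
    out.attrs["unmatched_loggers"] = unmatched
    if unmatched:
        warnings.warn(f"loggers missing from index: {unmatched}", stacklevel=2)
    return out


def read_detections(
    path: str | Path,
    time_format: str | TimeSpec = "ymd HMS",
    tz: str = "UTC",
    dedup: bool = False,
) -> pd.DataFrame:
    """Read a labeled CSV of reads and format it (see :func:`load_format`)."""
    raw = pd.read_csv(path, dtype={"animal_id": str, "logger_id": str})
    return load_format(raw, time_format=time_format, tz=tz, dedup=dedup)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any stage table as UTF-8 CSV with ISO 8601 local timestamps.

    tz-aware timestamp columns are rendered as local wall-clock
    ``YYYY-MM-DD HH:MM:SS`` (the timezone lives in the loading options, not
    the file); this makes CSV round trips exact to the second.
    """
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.DatetimeTZDtype) or (
            pd.api.types.is_datetime64_any_dtype(out[col])
        ):
            out[col] = out[col].dt.strftime("%Y-%m-%d %H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
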