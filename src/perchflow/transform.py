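"""Gap-rule transformations: reads -> visits -> displacements / movements / presence.

All four transformations share a single merge rule, centralized in
:func:`gap_merges`: two events are merged (chained, paired) when the gap
between them is *strictly less than* the cutoff ``bw``.

* :func:`visits` — consolidate read trains at one logger into visits
  (default cutoff 3 s).
* :func:`displacements` — supplanting events at a feeder: one animal starts a
  visit within the cutoff (default 2 s) of another's departure.
* :func:`movements` — transitions between loggers from consecutive visits of
  one animal at different stations; edge strength is the inverse travel time
  in 1/hours.
* :func:`presence` — chains of regular visits at one logger into bouts
  (default cutoff 15 min), whose length includes inter-visit gaps.

:func:`apply_grouped` runs any stage independently within groups defined by
metadata columns (e.g. experiment site) so no event ever spans two groups.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import ImpossibleReadError, ValidationError

_CORE_READ_COLS = ("animal_id", "time", "logger_id", "date")
_CORE_VISIT_COLS = ("animal_id", "date", "start", "end", "logger_id", "animal_n")


def gap_merges(gap_seconds: float, bw_seconds: float) -> bool:
    """The shared boundary rule: merge when the gap is strictly below the cutoff."""
    return gap_seconds < bw_seconds


def _extra_columns(df: pd.DataFrame, core: tuple[str, ...]) -> list[str]:
    return [c for c in df.columns if c not in core]


def _require(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table missing column(s): {', '.join(missing)}")


def visits(d: pd.DataFrame, bw: float = 3.0, allow_imp: bool = False) -> pd.DataFrame:
    """Consolidate reads into visits.

    Per animal, a maximal run of reads at one logger whose successive gaps are
    all below ``bw`` seconds becomes one visit spanning first to last read.  A
    logger change always ends a visit.  A change of logger *within* the cutoff
    is physically impossible for one tag; it raises
    :class:`ImpossibleReadError` unless ``allow_imp=True``, in which case the
    offending later read is dropped with a warning.

    Every output row carries ``animal_n``, the number of distinct animals in
    the input table (used downstream for per-individual averaging).
    """
    _require(d, ("animal_id", "time", "logger_id"), "detection")
    animal_n = int(d["animal_id"].nunique())
    extras = _extra_columns(d, _CORE_READ_COLS)
    rows: list[dict] = []
    dropped = 0
    for animal, grp in d.sort_values(["animal_id", "time"], kind="stable").groupby(
        "animal_id", sort=True
    ):
        times = grp["time"].array  # DatetimeArray: keeps the timezone
        loggers = grp["logger_id"].to_numpy()
        meta = grp[extras].to_numpy(dtype=object) if extras else None
        i0 = 0  # first read of current visit
        prev = 0
        for i in range(1, len(grp) + 1):
            if i < len(grp):
                gap = (times[i] - times[prev]) / pd.Timedelta(seconds=1)
                same_logger = loggers[i] == loggers[prev]
                if gap_merges(gap, bw) and not same_logger:
                    if not allow_imp:
                        raise ImpossibleReadError(
                            f"animal {animal} read at loggers {loggers[prev]} and "
                            f"{loggers[i]} only {gap:g}s apart "
                            f"({times[prev]} -> {times[i]})"
                        )
                    dropped += 1
                    continue  # drop the later, conflicting read
                if gap_merges(gap, bw) and same_logger:
                    prev = i
                    continue
            # close the visit [i0, prev]
            row = {
                "animal_id": animal,
                "date": times[i0].date(),
                "start": times[i0],
                "end": times[prev],
                "logger_id": loggers[i0],
                "animal_n": animal_n,
            }
            if meta is not None:
                row.update(dict(zip(extras, meta[i0])))
            rows.append(row)
            i0 = prev = i
    if dropped:
        warnings.warn(f"dropped {dropped} impossible read(s)", stacklevel=2)
    out = pd.DataFrame(rows, columns=list(_CORE_VISIT_COLS) + extras)
    if len(out):
        out = out.sort_values(["animal_id", "start"], kind="stable").reset_index(drop=True)
    out.attrs = dict(d.attrs)
    return out


def displacements(v: pd.DataFrame, bw: float = 2.0) -> pd.DataFrame:
    """Extract displacement (supplanting) events from visits.

    At each logger, a visit by animal B starting within ``bw`` seconds of the
    end of the most recently ended visit by a *different* animal A yields one
    event: B displaces A.  Visits are ordered by ``(start, end, animal_id)``
    so simultaneous starts resolve deterministically.
    """
    _require(v, ("animal_id", "logger_id", "start", "end"), "visit")
    events: list[dict] = []
    for logger, grp in v.groupby("logger_id", sort=True):
        grp = grp.sort_values(["start", "end", "animal_id"], kind="stable")
        starts = grp["start"].array
        ends = grp["end"].array
        animals = grp["animal_id"].to_numpy()
        best = -1  # index of most recently ended prior visit
        for i in range(1, len(grp)):
            j = i - 1
            if best < 0 or (ends[j], animals[j]) >= (ends[best], animals[best]):
                best = j
            gap = (starts[i] - ends[best]) / pd.Timedelta(seconds=1)
            if animals[best] != animals[i] and 0 <= gap and gap_merges(gap, bw):
                events.append(
                    {
                        "logger_id": logger,
                        "displacee": animals[best],
                        "displacer": animals[i],
                        "displacee_end": ends[best],
                        "displacer_start": starts[i],
                        "gap_seconds": gap,
                    }
                )
    out = pd.DataFrame(
        events,
        columns=["logger_id", "displacee", "displacer", "displacee_end",
                 "displacer_start", "gap_seconds"],
    )
    if len(out):
        out = out.sort_values("displacer_start", kind="stable").reset_index(drop=True)
    out.attrs = dict(v.attrs)
    return out


def movements(v: pd.DataFrame, allow_imp: bool = False) -> pd.DataFrame:
    """Build movement events from consecutive visits at different loggers.

    One event per logger switch in each animal's chronological visit
    sequence: departure at the earlier visit's end, arrival at the later
    visit's start.  ``move_dir`` is the directed ``from_to`` pair,
    ``move_path`` the same pair sorted lexicographically (undirected), and
    ``strength = 3600 / travel seconds`` (1/hours) so short hops weigh more.

    Zero travel time leaves strength undefined and raises unless
    ``allow_imp=True`` (the event is then skipped with a warning).
    """
    _require(v, ("animal_id", "logger_id", "start", "end"), "visit")
    extras = _extra_columns(v, _CORE_VISIT_COLS)
    keep_extras = [c for c in extras if c not in ("lat", "lon")]
    rows: list[dict] = []
    skipped = 0
    for animal, grp in v.groupby("animal_id", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        move_id = 0
        prev = None
        for rec in grp.itertuples(index=False):
            if prev is not None and rec.logger_id != prev.logger_id:
                dt_s = (rec.start - prev.end) / pd.Timedelta(seconds=1)
                if dt_s <= 0:
                    if not allow_imp:
                        raise ImpossibleReadError(
                            f"animal {animal}: zero or negative travel time between "
                            f"loggers {prev.logger_id} and {rec.logger_id} at {rec.start}"
                        )
                    skipped += 1
                    prev = rec
                    continue
                move_id += 1
                pair = sorted((str(prev.logger_id), str(rec.logger_id)))
                row = {
                    "animal_id": animal,
                    "date": prev.end.date(),
                    "move_id": move_id,
                    "left_logger": prev.logger_id,
                    "left_time": prev.end,
                    "arrived_logger": rec.logger_id,
                    "arrived_time": rec.start,
                    "move_dir": f"{prev.logger_id}_{rec.logger_id}",
                    "move_path": "_".join(pair),
                    "strength": 3600.0 / dt_s,
                }
                if "animal_n" in v.columns:
                    row["animal_n"] = rec.animal_n
                for c in keep_extras:
                    row[c] = getattr(rec, c)
                rows.append(row)
            prev = rec
    if skipped:
        warnings.warn(f"skipped {skipped} zero-travel movement(s)", stacklevel=2)
    cols = ["animal_id", "date", "move_id", "left_logger", "left_time",
            "arrived_logger", "arrived_time", "move_dir", "move_path", "strength"]
    if "animal_n" in v.columns:
        cols.append("animal_n")
    out = pd.DataFrame(rows, columns=cols + keep_extras)
    out.attrs = dict(v.attrs)
    return out


def movements_long(m: pd.DataFrame) -> pd.DataFrame:
    """Two-row-per-event view of movements (direction in {left, arrived})."""
    rows = []
    for rec in m.itertuples(index=False):
        common = {
            "animal_id": rec.animal_id,
            "move_id": rec.move_id,
            "move_dir": rec.move_dir,
            "move_path": rec.move_path,
            "strength": rec.strength,
        }
        rows.append({**common, "date": rec.left_time.date(), "time": rec.left_time,
                     "logger_id": rec.left_logger, "direction": "left"})
        rows.append({**common, "date": rec.arrived_time.date(), "time": rec.arrived_time,
                     "logger_id": rec.arrived_logger, "direction": "arrived"})
    out = pd.DataFrame(
        rows,
        columns=["animal_id", "date", "time", "logger_id", "direction",
                 "move_id", "move_dir", "move_path", "strength"],
    )
    out.attrs = dict(m.attrs)
    return out


def presence(v: pd.DataFrame, bw: float = 15.0) -> pd.DataFrame:
    """Chain regular visits into presence bouts.

    Per animal, successive visits at the *same* logger separated by less than
    ``bw`` minutes belong to one bout; a visit at a different logger breaks
    the chain.  Bout length (minutes) runs from the first chained visit's
    start to the last one's end, so it includes the gaps between visits —
    presence measures time spent *around* a station, visits time spent *at*
    it.
    """
    _require(v, ("animal_id", "logger_id", "start", "end"), "visit")
    extras = _extra_columns(v, _CORE_VISIT_COLS)
    rows: list[dict] = []

    def close(first, last, animal):
        row = {
            "animal_id": animal,
            "date": first.start.date(),
            "logger_id": first.logger_id,
            "start": first.start,
            "end": last.end,
            "length": (last.end - first.start) / pd.Timedelta(minutes=1),
        }
        if "animal_n" in v.columns:
            row["animal_n"] = first.animal_n
        for c in extras:
            row[c] = getattr(first, c)
        rows.append(row)

    for animal, grp in v.groupby("animal_id", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        first = last = None
        for rec in grp.itertuples(index=False):
            if first is not None:
                gap_min = (rec.start - last.end) / pd.Timedelta(minutes=1)
                if rec.logger_id == last.logger_id and gap_merges(gap_min, bw):
                    last = rec
                    continue
                close(first, last, animal)
            first = last = rec
        if first is not None:
            close(first, last, animal)
    cols = ["animal_id", "date", "logger_id", "start", "end", "length"]
    if "animal_n" in v.columns:
        cols.append("animal_n")
    out = pd.DataFrame(rows, columns=cols + extras)
    if len(out):
        out = out.sort_values(["animal_id", "start"], kind="stable").reset_index(drop=True)
    out.attrs = dict(v.attrs)
    return out


#: stage name -> callable, for grouped application and the CLI
STAGES = {
    "visits": visits,
    "disp": displacements,
    "move": movements,
    "presence": presence,
}


def apply_grouped(d: pd.DataFrame, keys: list[str] | str, stage, **params) -> pd.DataFrame:
    """Apply a transformation independently within groups of *keys* columns.

    *stage* is a name from :data:`STAGES` (or any callable taking a table).
    Outputs are concatenated with the key columns attached, so no visit,
    movement or bout ever spans two groups, and ``animal_n`` counts animals
    within each group only.
    """
    if isinstance(keys, str):
        keys = [keys]
    missing = [k for k in keys if k not in d.columns]
    if missing:
        raise ValidationError(f"unknown group key(s): {', '.join(missing)}")
    if callable(stage):
        fn = stage
    else:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
        fn = STAGES[stage]
    parts = []
    for key_vals, grp in d.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        res = fn(grp.reset_index(drop=True), **params)
        for k, val in zip(keys, key_vals):
            res[k] = val
        parts.append(res)
    if not parts:
        return pd.DataFrame()
    out = pd.concat(parts, ignore_index=True)
    out.attrs = dict(d.attrs)
    return out
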