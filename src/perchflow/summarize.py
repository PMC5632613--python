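"""Map-ready summaries and export adapters for downstream analyses.

Summaries reduce presence bouts and movement events to one row per station
(or station pair) for rendering:

* ``"sum"`` — total minutes of presence per logger / total movements per path;
* ``"sum_indiv"`` — the same, averaged by ``animal_n`` (the number of
  distinct animals counted when visits were built);
* ``"indiv"`` — per-animal totals, optionally restricted to chosen ids;
* ``"none"`` — caller-precomputed amounts are validated and passed through
  (the route grouped workflows take to the renderer).

Exports reshape displacement events into the winner/loser sequence and
square interaction matrix used by dominance-hierarchy packages, and reads
into the plain event stream used by gambit-of-the-group association tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LoggerIndex

MODES = ("sum", "sum_indiv", "indiv", "none")


def _check_mode(mode: str, which) -> None:
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if which is not None and mode != "indiv":
        raise ValidationError("'which' may only be used with mode='indiv'")


def _check_which(df: pd.DataFrame, which) -> list[str] | None:
    if which is None:
        return None
    which = [str(w) for w in which]
    unknown = sorted(set(which) - set(df["animal_id"].astype(str)))
    if unknown:
        raise ValidationError(f"unknown animal id(s): {', '.join(unknown)}")
    return which


def summarize_presence(
    p: pd.DataFrame,
    mode: str = "sum",
    which: list[str] | None = None,
    keys: list[str] | None = None,
) -> pd.DataFrame:
    """Summarize presence bouts per logger for mapping.

    ``amount`` is in minutes.  *keys* adds extra grouping columns (e.g. an
    experiment id) that are carried into the output so grouped workflows stay
    separated all the way to the map.
    """
    _check_mode(mode, which)
    if mode == "none":
        for c in ("logger_id", "amount"):
            if c not in p.columns:
                raise ValidationError(f"mode='none' expects precomputed column {c!r}")
        return p.copy()
    for c in ("logger_id", "length"):
        if c not in p.columns:
            raise ValidationError(f"presence table missing column {c!r}")
    keys = list(keys or [])
    which = _check_which(p, which)
    group = keys + ["logger_id"] + (["animal_id"] if mode == "indiv" else [])
    work = p if which is None else p[p["animal_id"].astype(str).isin(which)]
    agg: dict = {"amount": ("length", "sum")}
    for c in ("lat", "lon"):
        if c in work.columns:
            agg[c] = (c, "first")
    if mode == "sum_indiv":
        if "animal_n" not in work.columns:
            raise ValidationError("mode='sum_indiv' needs the animal_n column from visits()")
        agg["animal_n"] = ("animal_n", "first")
    out = work.groupby(group, sort=True).agg(**agg).reset_index()
    if mode == "sum_indiv":
        out["amount"] = out["amount"] / out.pop("animal_n")
    cols = group + [c for c in ("lat", "lon") if c in out.columns] + ["amount"]
    return out[cols]


def summarize_movements(
    m: pd.DataFrame,
    mode: str = "sum",
    which: list[str] | None = None,
    keys: list[str] | None = None,
    index: LoggerIndex | None = None,
) -> pd.DataFrame:
    """Summarize movement events per undirected path for mapping.

    ``path_use`` is a movement count (mode ``sum``/``indiv``) or a count per
    individual (``sum_indiv``).  Endpoint coordinates are attached from
    *index* when given; otherwise they are left missing and can be resolved
    from the presence summary at render time.
    """
    _check_mode(mode, which)
    if mode == "none":
        for c in ("move_path", "path_use"):
            if c not in m.columns:
                raise ValidationError(f"mode='none' expects precomputed column {c!r}")
        return m.copy()
    for c in ("move_path", "left_logger", "arrived_logger"):
        if c not in m.columns:
            raise ValidationError(f"movement table missing column {c!r}")
    keys = list(keys or [])
    which = _check_which(m, which)
    work = m if which is None else m[m["animal_id"].astype(str).isin(which)]
    pairs = [
        tuple(sorted((str(a), str(b))))
        for a, b in zip(work["left_logger"], work["arrived_logger"])
    ]
    work = work.assign(
        logger_1=[p[0] for p in pairs],
        logger_2=[p[1] for p in pairs],
    )
    group = keys + ["move_path", "logger_1", "logger_2"] + (
        ["animal_id"] if mode == "indiv" else []
    )
    agg: dict = {"path_use": ("move_path", "size")}
    if mode == "sum_indiv":
        if "animal_n" not in work.columns:
            raise ValidationError("mode='sum_indiv' needs the animal_n column from visits()")
        agg["animal_n"] = ("animal_n", "first")
    out = work.groupby(group, sort=True).agg(**agg).reset_index()
    if mode == "sum_indiv":
        out["path_use"] = out["path_use"] / out.pop("animal_n")
    if index is not None:
        coords = index.coords()
        for side in ("1", "2"):
            out[f"lat_{side}"] = out[f"logger_{side}"].map(lambda x: coords.get(x, (np.nan,) * 2)[0])
            out[f"lon_{side}"] = out[f"logger_{side}"].map(lambda x: coords.get(x, (np.nan,) * 2)[1])
    return out


@dataclass
class InteractionExport:
    """Displacements as a winner/loser sequence and a square count matrix."""

    sequence: pd.DataFrame  # columns winner, loser, time; chronological
    matrix: pd.DataFrame  # rows = winners, cols = losers, identical order


def export_interactions(d: pd.DataFrame) -> InteractionExport:
    """Reshape displacement events for dominance-hierarchy packages.

    The sequence is ordered by displacer start time (winner = displacer,
    loser = displacee); the matrix counts wins of the row animal over the
    column animal, animals sorted lexicographically on both axes.
    """
    if len(d):
        for c in ("displacer", "displacee", "displacer_start"):
            if c not in d.columns:
                raise ValidationError(f"displacement table missing column {c!r}")
        seq = (
            d.sort_values("displacer_start", kind="stable")
            .rename(columns={"displacer": "winner", "displacee": "loser",
                             "displacer_start": "time"})
            .loc[:, ["winner", "loser", "time"]]
            .reset_index(drop=True)
        )
        animals = sorted(set(seq["winner"]) | set(seq["loser"]))
    else:
        seq = pd.DataFrame(columns=["winner", "loser", "time"])
        animals = []
    mat = pd.DataFrame(0, index=animals, columns=animals, dtype=int)
    for rec in seq.itertuples(index=False):
        mat.loc[rec.winner, rec.loser] += 1
    return InteractionExport(sequence=seq, matrix=mat)


def export_event_stream(d: pd.DataFrame) -> pd.DataFrame:
    """Reads as a (time, id, location) stream for association analyses.

    Time is in seconds elapsed since the first read; rows are sorted so the
    stream is non-decreasing.
    """
    for c in ("animal_id", "time", "logger_id"):
        if c not in d.columns:
            raise ValidationError(f"detection table missing column {c!r}")
    if not len(d):
        return pd.DataFrame(columns=["time", "animal_id", "location"])
    work = d.sort_values("time", kind="stable")
    t0 = work["time"].iloc[0]
    return pd.DataFrame(
        {
            "time": ((work["time"] - t0) / pd.Timedelta(seconds=1)).to_numpy(),
            "animal_id": work["animal_id"].to_numpy(),
            "location": work["logger_id"].to_numpy(),
        }
    )
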