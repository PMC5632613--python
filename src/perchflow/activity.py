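"""Activity budgets: presence bouts -> binary time-bin grid -> daily pattern.

The grid is anchored at local midnight and scored in half-open bins
``[t, t + res)``; a bin is active when it overlaps any presence bout.  Bins
are wall-clock local times (timezone information is dropped once bouts are
converted), so every bin start is an exact multiple of ``res`` minutes after
midnight even across daylight-saving transitions.

:func:`daily_pattern` averages the grid across days into a 24-h profile of
per-bin activity proportions, and :func:`export_time_vectors` maps event
times onto the circle ``[0, 2*pi)`` for circular-statistics packages that fit
diel activity curves with circular kernel densities.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ValidationError


def _naive_local(col: pd.Series) -> pd.Series:
    if isinstance(col.dtype, pd.DatetimeTZDtype):
        return col.dt.tz_localize(None)
    return pd.to_datetime(col)


def activity_grid(p: pd.DataFrame, res: int = 15, by_logger: bool = False) -> pd.DataFrame:
    """Score presence bouts onto a binary active/inactive grid.

    Parameters
    ----------
    p
        Presence bouts with ``animal_id``, ``start``, ``end`` (and
        ``logger_id`` when ``by_logger``).
    res
        Bin resolution in minutes; must divide 1440 so bins tile the day.
    by_logger
        Score each station separately instead of pooling an animal's bouts.

    The grid for each animal (or animal x logger) spans from its first bout
    start, floored to the bin grid, to its last bout end, ceiled — absence of
    deployment outside that range is not scored as inactivity.
    """
    res = int(res)
    if res <= 0 or 1440 % res != 0:
        raise ValidationError(f"res must be a positive divisor of 1440 minutes, got {res}")
    group_cols = ["animal_id", "logger_id"] if by_logger else ["animal_id"]
    for c in group_cols + ["start", "end"]:
        if c not in p.columns:
            raise ValidationError(f"presence table missing column {c!r}")
    step = pd.Timedelta(minutes=res)
    out_rows: list[pd.DataFrame] = []
    if len(p):
        work = p.assign(_s=_naive_local(p["start"]), _e=_naive_local(p["end"]))
        for key, grp in work.groupby(group_cols, sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            s = grp["_s"].to_numpy()
            e = grp["_e"].to_numpy()
            lo = min(grp["_s"]).floor(f"{res}min")
            hi = max(grp["_e"]).ceil(f"{res}min")
            bins = pd.date_range(lo, max(hi - step, lo), freq=step)
            b = bins.to_numpy()
            bres = (bins + step).to_numpy()
            # overlap of bout [s, e] with half-open bin [b, b+res); an
            # instantaneous bout activates the bin containing its instant
            overlaps = (s[None, :] < bres[:, None]) & (
                (e[None, :] > b[:, None])
                | ((s[None, :] == e[None, :]) & (s[None, :] >= b[:, None]))
            )
            frame = pd.DataFrame({"bin_start": bins, "active": overlaps.any(axis=1).astype(int)})
            for col, val in zip(group_cols, key):
                frame.insert(0, col, val)
            out_rows.append(frame)
    if out_rows:
        out = pd.concat(out_rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=group_cols + ["bin_start", "active"])
    out.attrs = dict(p.attrs)
    out.attrs["res"] = res
    return out


def _infer_res(a: pd.DataFrame) -> int:
    if "res" in a.attrs:
        return int(a.attrs["res"])
    tod = np.sort(
        (
            (pd.to_datetime(a["bin_start"]) - pd.to_datetime(a["bin_start"]).dt.normalize())
            / pd.Timedelta(minutes=1)
        ).unique()
    )
    if len(tod) < 2:
        return 1440
    return int(math.gcd(*(int(x) for x in np.diff(tod) if x > 0), int(tod[0]) or 1440))


def daily_pattern(a: pd.DataFrame) -> pd.DataFrame:
    """Average an activity grid across days into a 24-h pattern.

    For each animal and time-of-day bin, ``p_active`` is the fraction of
    observed days on which the bin was active and ``n_days`` counts those
    days; days without a cell in a bin do not enter the denominator.  The
    output covers the full set of 1440/res bins per animal; bins never
    observed carry ``n_days = 0`` and ``p_active = 0``.
    """
    for c in ("animal_id", "bin_start", "active"):
        if c not in a.columns:
            raise ValidationError(f"activity table missing column {c!r}")
    res = _infer_res(a)
    all_bins = np.arange(0, 1440, res)
    rows = []
    if len(a):
        work = a.copy()
        bs = pd.to_datetime(work["bin_start"])
        work["time_of_day"] = ((bs - bs.dt.normalize()) / pd.Timedelta(minutes=1)).astype(int)
        for animal, grp in work.groupby("animal_id", sort=True):
            agg = grp.groupby("time_of_day")["active"].agg(["sum", "count"])
            for tod in all_bins:
                if tod in agg.index:
                    s, n = int(agg.loc[tod, "sum"]), int(agg.loc[tod, "count"])
                else:
                    s, n = 0, 0
                rows.append(
                    {
                        "animal_id": animal,
                        "time_of_day": int(tod),
                        "p_active": s / n if n else 0.0,
                        "n_days": n,
                    }
                )
    out = pd.DataFrame(rows, columns=["animal_id", "time_of_day", "p_active", "n_days"])
    out.attrs = dict(a.attrs)
    return out


def export_time_vectors(d: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-animal event times as radians on the day circle.

    Works on detection tables (``time`` column) or visit tables (``start``);
    each event maps to ``2*pi * seconds_after_local_midnight / 86400``.
    """
    col = "start" if "start" in d.columns else "time"
    if col not in d.columns or "animal_id" not in d.columns:
        raise ValidationError("need animal_id and a time or start column")
    out: dict[str, np.ndarray] = {}
    if not len(d):
        return out
    t = _naive_local(d[col])
    seconds = (t - t.dt.normalize()) / pd.Timedelta(seconds=1)
    radians = 2.0 * np.pi * seconds.to_numpy() / 86400.0
    for animal, grp_idx in d.groupby("animal_id", sort=True).groups.items():
        out[animal] = radians[d.index.get_indexer(grp_idx)]
    return out
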