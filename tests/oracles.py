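"""Independent brute-force re-derivations of the gap-rule transformations.

Pure-Python, list-of-tuple based, written directly from the definitions
(merge when gap < cutoff) without touching the package implementation.
Quadratic search is used wherever the definition allows it, so these stay
structurally independent of the linear-scan production code.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

SEC = dt.timedelta(seconds=1)


def oracle_visits(reads, bw_s):
    """reads: iterable of (animal, time, logger) -> list of visit dicts."""
    out = []
    by_animal = {}
    for a, t, lg in reads:
        by_animal.setdefault(a, []).append((t, lg))
    for a in sorted(by_animal):
        seq = sorted(by_animal[a])
        visit = None
        for t, lg in seq:
            if visit is not None and lg == visit["logger"] and (
                (t - visit["end"]) / SEC < bw_s
            ):
                visit["end"] = t
                continue
            if visit is not None:
                out.append(visit)
            visit = {"animal": a, "logger": lg, "start": t, "end": t}
        if visit is not None:
            out.append(visit)
    return out


def oracle_displacements(visits, bw_s):
    """O(n^2) pairing: each visit against the most recently ended prior one."""
    events = []
    loggers = {v["logger"] for v in visits}
    for lg in sorted(loggers):
        vs = sorted(
            (v for v in visits if v["logger"] == lg),
            key=lambda v: (v["start"], v["end"], v["animal"]),
        )
        for j, vj in enumerate(vs):
            prior = vs[:j]
            if not prior:
                continue
            vi = max(prior, key=lambda v: (v["end"], v["animal"]))
            gap = (vj["start"] - vi["end"]) / SEC
            if vi["animal"] != vj["animal"] and 0 <= gap < bw_s:
                events.append(
                    {"logger": lg, "displacee": vi["animal"], "displacer": vj["animal"],
                     "gap": gap, "time": vj["start"]}
                )
    events.sort(key=lambda e: e["time"])
    return events


def oracle_movements(visits):
    """O(n^2): for each visit, scan all others for its chronological successor."""
    events = []
    for a in sorted({v["animal"] for v in visits}):
        vs = [v for v in visits if v["animal"] == a]
        order = sorted(range(len(vs)), key=lambda i: (vs[i]["start"], vs[i]["end"]))
        move_id = 0
        for k in range(1, len(order)):
            prev, cur = vs[order[k - 1]], vs[order[k]]
            if prev["logger"] != cur["logger"]:
                move_id += 1
                delta = (cur["start"] - prev["end"]) / SEC
                events.append(
                    {"animal": a, "move_id": move_id,
                     "left": prev["logger"], "arrived": cur["logger"],
                     "strength": 3600.0 / delta}
                )
    return events


def oracle_presence(visits, bw_min):
    bouts = []
    for a in sorted({v["animal"] for v in visits}):
        vs = sorted((v for v in visits if v["animal"] == a),
                    key=lambda v: (v["start"], v["end"]))
        bout = None
        for v in vs:
            if bout is not None and v["logger"] == bout["logger"] and (
                (v["start"] - bout["end"]) / SEC / 60.0 < bw_min
            ):
                bout["end"] = v["end"]
                continue
            if bout is not None:
                bouts.append(bout)
            bout = {"animal": a, "logger": v["logger"], "start": v["start"], "end": v["end"]}
        if bout is not None:
            bouts.append(bout)
    for b in bouts:
        b["length"] = (b["end"] - b["start"]) / SEC / 60.0
    return bouts


def random_detection_table(rng: np.random.Generator, max_reads: int = 200,
                           min_switch_gap_s: int = 15) -> pd.DataFrame:
    """Random multi-animal read stream safe for cutoffs up to *min_switch_gap_s*.

    Within a run at one logger successive gaps are 0-10 s; between runs (and
    around any logger switch) gaps are at least ``min_switch_gap_s`` so the
    same animal is never seen at two loggers within a tested cutoff.
    """
    n_animals = int(rng.integers(1, 5))
    loggers = [f"L{i}" for i in range(1, 1 + int(rng.integers(1, 5)))]
    quota = int(rng.integers(5, max_reads + 1))
    rows = []
    base = 1_600_000_000
    # one timeline per animal so the stream never violates physics
    state = {
        f"A{i + 1}": [base + int(rng.integers(0, 6 * 3600)),
                      loggers[int(rng.integers(len(loggers)))]]
        for i in range(n_animals)
    }
    while len(rows) < quota:
        a = f"A{int(rng.integers(n_animals)) + 1}"
        t, lg = state[a]
        for _ in range(int(rng.integers(1, 8))):  # reads in one run
            if len(rows) >= quota:
                break
            rows.append((a, t, lg))
            t += int(rng.integers(0, 11))
        t += int(rng.integers(min_switch_gap_s, 2000))
        lg = loggers[int(rng.integers(len(loggers)))]
        state[a] = [t, lg]
    df = pd.DataFrame(rows, columns=["animal_id", "secs", "logger_id"])
    df["time"] = pd.to_datetime(df.pop("secs"), unit="s", utc=True)
    df = df[["animal_id", "time", "logger_id"]]
    df["date"] = [ts.date() for ts in df["time"]]
    df = df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)
    df.attrs["tz"] = "UTC"
    return df


def records_of(d: pd.DataFrame):
    return [(r.animal_id, r.time.to_pydatetime(), r.logger_id)
            for r in d.itertuples(index=False)]


def visit_records_of(v: pd.DataFrame):
    return [{"animal": r.animal_id, "logger": r.logger_id,
             "start": r.start.to_pydatetime(), "end": r.end.to_pydatetime()}
            for r in v.itertuples(index=False)]
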