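"""Ground-truth-aware simulator of RFID detection streams.

Animals perform bouts of visits at stations: within a visit the tag is read
at a fixed interval (perch read trains); visits within a bout are separated
by short gaps; bouts are separated by long gaps (including overnight-scale
ones) and may switch stations.  All timestamps are integer seconds so the
streams survive text round trips exactly.

Gap distributions are *guard-banded* around the transformation cutoffs:

* read interval  <  visit cutoff (default 3 s) — reads merge into visits;
* within-bout visit gaps lie strictly between the visit cutoff and the
  presence cutoff — visits stay separate but chain into one bout;
* between-bout gaps exceed the presence cutoff — bouts stay separate.

Under these conditions the transformations must recover the emitted visits,
bouts and movements *exactly*, which is what the recovery tests assert.  The
emitted ground truth is consistent with the reads by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .timeparse import parse_time_spec

#: default station grid, spaced a few hundred metres apart
DEFAULT_STATIONS = (
    ("2100", 50.66896, -120.3624),
    ("2200", 50.66803, -120.3617),
    ("2700", 50.66909, -120.3632),
    ("2400", 50.66770, -120.3640),
)


@dataclass
class SimConfig:
    """Simulation settings; distribution fields may be ints or ``rng -> int`` callables."""

    n_animals: int = 3
    stations: tuple = DEFAULT_STATIONS
    start: str = "2015-10-01 06:00:00"
    span_hours: float = 36.0
    tz: str = "UTC"
    read_interval_s: int = 2
    #: reads per visit (visit duration = (reads - 1) * read_interval)
    reads_per_visit: object = None  # default: 1 + Poisson(3)
    #: visits per bout
    visits_per_bout: object = None  # default: 1 + Poisson(2)
    #: gap between visits within a bout, seconds
    intervisit_gap_s: object = None  # default: Uniform{6..300}
    #: gap between bouts, seconds (overnight-scale tail)
    interbout_gap_s: object = None  # default: 1800 + Exp(mean 2 h)
    station_switch_p: float = 0.5
    #: cutoffs the guard bands are validated against
    visit_bw_s: float = 3.0
    presence_bw_min: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.reads_per_visit is None:
            self.reads_per_visit = lambda rng: 1 + int(rng.poisson(3))
        if self.visits_per_bout is None:
            self.visits_per_bout = lambda rng: 1 + int(rng.poisson(2))
        if self.intervisit_gap_s is None:
            self.intervisit_gap_s = lambda rng: int(rng.integers(6, 301))
        if self.interbout_gap_s is None:
            self.interbout_gap_s = lambda rng: 1800 + int(rng.exponential(7200))

    def validate(self) -> None:
        presence_bw_s = self.presence_bw_min * 60.0
        if not self.read_interval_s < self.visit_bw_s:
            raise ValidationError(
                f"infeasible guard band: read interval {self.read_interval_s}s must be "
                f"below the visit cutoff {self.visit_bw_s}s"
            )
        if self.visit_bw_s >= presence_bw_s:
            raise ValidationError("infeasible guard band: visit cutoff >= presence cutoff")
        if self.n_animals < 0 or not self.stations:
            raise ValidationError("need n_animals >= 0 and at least one station")


def _draw(dist, rng) -> int:
    return int(dist(rng)) if callable(dist) else int(dist)


@dataclass
class GroundTruth:
    """True visits, presence bouts and movements per animal, as emitted."""

    visits: pd.DataFrame
    bouts: pd.DataFrame
    moves: pd.DataFrame


def simulate_detections(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a detection table plus its ground truth.

    Deterministic for a fixed ``cfg.seed``.  Gap draws are clipped into
    their guard bands, so recovery is exact for any seed; infeasible guard
    bands raise up front.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start).tz_localize(cfg.tz)
    end = start + pd.Timedelta(hours=cfg.span_hours)
    presence_gap_floor = int(cfg.presence_bw_min * 60) + 1
    visit_gap_floor = int(cfg.visit_bw_s) + 1
    visit_gap_ceiling = int(cfg.presence_bw_min * 60) - 1
    station_ids = [s[0] for s in cfg.stations]
    coords = {s[0]: (s[1], s[2]) for s in cfg.stations}

    reads, true_visits, true_bouts, true_moves = [], [], [], []
    for a in range(cfg.n_animals):
        animal = f"BIRD{a + 1:02d}"
        max_offset = max(1, min(3600, int(cfg.span_hours * 3600)))
        t = start + pd.Timedelta(seconds=int(rng.integers(0, max_offset)))
        station = station_ids[int(rng.integers(len(station_ids)))]
        prev_station, prev_bout_end = None, None
        while t < end:
            n_visits = max(1, _draw(cfg.visits_per_bout, rng))
            bout_start = t
            visit_end = t
            for vi in range(n_visits):
                n_reads = max(1, _draw(cfg.reads_per_visit, rng))
                times = [t + pd.Timedelta(seconds=k * cfg.read_interval_s)
                         for k in range(n_reads)]
                for ts in times:
                    reads.append((animal, ts, station))
                visit_end = times[-1]
                true_visits.append((animal, station, t, visit_end))
                if vi < n_visits - 1:
                    gap = _draw(cfg.intervisit_gap_s, rng)
                    gap = int(np.clip(gap, visit_gap_floor, visit_gap_ceiling))
                    t = visit_end + pd.Timedelta(seconds=gap)
            true_bouts.append((animal, station, bout_start, visit_end))
            if prev_station is not None and station != prev_station:
                true_moves.append((animal, prev_station, station, prev_bout_end, bout_start))
            prev_station, prev_bout_end = station, visit_end
            gap = max(_draw(cfg.interbout_gap_s, rng), presence_gap_floor)
            t = visit_end + pd.Timedelta(seconds=gap)
            if len(station_ids) > 1 and rng.random() < cfg.station_switch_p:
                others = [s for s in station_ids if s != station]
                station = others[int(rng.integers(len(others)))]

    d = pd.DataFrame(reads, columns=["animal_id", "time", "logger_id"])
    if len(d):
        d["lat"] = d["logger_id"].map(lambda s: coords[s][0])
        d["lon"] = d["logger_id"].map(lambda s: coords[s][1])
        d["date"] = [ts.date() for ts in d["time"]]
        d = d.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)
        d = d[["animal_id", "time", "logger_id", "date", "lat", "lon"]]
    else:
        d = pd.DataFrame(columns=["animal_id", "time", "logger_id", "date", "lat", "lon"])
    d.attrs["tz"] = cfg.tz

    truth = GroundTruth(
        visits=pd.DataFrame(true_visits, columns=["animal_id", "logger_id", "start", "end"]),
        bouts=pd.DataFrame(true_bouts, columns=["animal_id", "logger_id", "start", "end"]),
        moves=pd.DataFrame(
            true_moves,
            columns=["animal_id", "left_logger", "arrived_logger", "left_time", "arrived_time"],
        ),
    )
    return d, truth


def emit_raw_files(
    d: pd.DataFrame,
    out_dir: str | Path,
    details: int = 1,
    sep: str | None = "whitespace",
    time_format: str = "mdy HMS",
) -> list[Path]:
    """Write a detection table as raw per-logger text files.

    One file per logger in the chosen dialect; loading the directory back
    with :func:`perchflow.io.load_raw_all` under the same options reproduces
    the table (coordinates only under ``details=2``).
    """
    if details not in (0, 1, 2):
        raise ValidationError(f"details must be 0, 1 or 2, got {details!r}")
    spec = parse_time_spec(time_format)
    if "p" in spec.tokens:
        raise ValidationError("am/pm time formats are not supported for raw file output")
    date_fmt = "/".join({"y": "%Y", "m": "%m", "d": "%d"}[t] for t in spec.tokens if t in "ymd")
    sep_char = {"whitespace": " ", "ws": " ", None: " ", ",": ",", ";": ";",
                "comma": ",", "semicolon": ";"}[sep]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for logger, grp in d.groupby("logger_id", sort=True):
        path = out_dir / f"{logger}.txt"
        lines = []
        if details in (1, 2):
            lines.append(str(logger))
        if details == 2:
            lat, lon = grp["lat"].iloc[0], grp["lon"].iloc[0]
            if pd.isna(lat) or pd.isna(lon):
                raise ValidationError(f"details=2 needs coordinates for logger {logger}")
            lines.append(f"{float(lat)!r}, {float(lon)!r}")
        for rec in grp.sort_values("time").itertuples(index=False):
            ts = rec.time
            lines.append(sep_char.join(
                [str(rec.animal_id), ts.strftime(date_fmt), ts.strftime("%H:%M:%S")]
            ))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
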