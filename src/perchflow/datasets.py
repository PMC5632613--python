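"""Small bundled example dataset: one PIT-tagged house finch.

A female house finch (tag ``041868E9A8``) detected at three RFID-enabled
feeders (``2100``, ``2200``, ``2700``) on a university campus in early
October 2015.  :func:`finch_reads` holds a short train of raw reads at two
feeders on the first evening; :func:`finch_visits` holds consolidated
visit boundaries over the following week, including the return trips to
feeder ``2200`` (the final visit there is known only by its departure time
and is recorded as instantaneous).  Useful for demos, docs and tests.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .io import load_format

_READS_CSV = """\
animal_id,time,logger_id,species,sex,lon,lat
041868E9A8,2015-10-01 17:38:52,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:38:54,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:38:56,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:38:58,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:39:00,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:39:12,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:40:53,2100,House Finch,F,-120.3624,50.66896
041868E9A8,2015-10-01 17:45:00,2700,House Finch,F,-120.3632,50.66909
041868E9A8,2015-10-01 17:45:02,2700,House Finch,F,-120.3632,50.66909
041868E9A8,2015-10-01 17:45:04,2700,House Finch,F,-120.3632,50.66909
"""

_VISITS_CSV = """\
animal_id,start,end,logger_id
041868E9A8,2015-10-01 17:38:52,2015-10-01 17:39:00,2100
041868E9A8,2015-10-01 17:39:12,2015-10-01 17:39:12,2100
041868E9A8,2015-10-01 17:40:53,2015-10-01 17:40:53,2100
041868E9A8,2015-10-01 17:45:00,2015-10-01 17:45:56,2700
041868E9A8,2015-10-01 17:46:31,2015-10-01 17:46:31,2700
041868E9A8,2015-10-01 17:51:03,2015-10-01 17:51:16,2700
041868E9A8,2015-10-01 17:51:42,2015-10-01 17:51:58,2700
041868E9A8,2015-10-01 17:52:51,2015-10-01 17:53:07,2700
041868E9A8,2015-10-01 17:53:41,2015-10-01 17:54:57,2700
041868E9A8,2015-10-01 17:56:42,2015-10-01 17:56:42,2700
041868E9A8,2015-10-02 10:57:00,2015-10-02 11:11:43,2200
041868E9A8,2015-10-02 12:45:37,2015-10-02 13:06:27,2200
041868E9A8,2015-10-02 14:22:58,2015-10-02 14:27:30,2200
041868E9A8,2015-10-06 14:24:50,2015-10-06 14:24:50,2200
041868E9A8,2015-10-06 16:05:40,2015-10-06 16:05:40,2700
"""

_INDEX_CSV = """\
logger_id,lat,lon
2100,50.66896,-120.3624
2200,50.66803,-120.3617
2700,50.66909,-120.3632
"""


def finch_reads(tz: str = "UTC") -> pd.DataFrame:
    """Raw reads from the example finch's first evening (10 reads, 2 feeders)."""
    return load_format(pd.read_csv(_io.StringIO(_READS_CSV), dtype=str), tz=tz)


def finch_visits(tz: str = "UTC") -> pd.DataFrame:
    """Consolidated visit boundaries for the example finch (15 visits, 3 feeders)."""
    df = pd.read_csv(_io.StringIO(_VISITS_CSV), dtype=str)
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col]).dt.tz_localize(tz)
    df.insert(1, "date", [ts.date() for ts in df["start"]])
    df["animal_n"] = 1
    df = df[["animal_id", "date", "start", "end", "logger_id", "animal_n"]]
    df.attrs["tz"] = tz
    return df


def finch_logger_index() -> pd.DataFrame:
    """Coordinates of the three example feeders (``logger_id``, ``lat``, ``lon``)."""
    return pd.read_csv(_io.StringIO(_INDEX_CSV), dtype={"logger_id": str})
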