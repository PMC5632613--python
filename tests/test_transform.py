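import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import perchflow as pf
from perchflow.errors import ImpossibleReadError, ValidationError

import oracles

UTC = dt.timezone.utc


def make_reads(rows, tz="UTC"):
    """rows: (animal, iso_time, logger) -> canonical detection table."""
    df = pd.DataFrame(rows, columns=["animal_id", "time", "logger_id"])
    return pf.load_format(df, tz=tz)


def make_visits(rows, animal_n=None):
    """rows: (animal, iso_start, iso_end, logger) -> visit table."""
    df = pd.DataFrame(rows, columns=["animal_id", "start", "end", "logger_id"])
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c]).dt.tz_localize("UTC")
    df.insert(1, "date", [t.date() for t in df["start"]])
    df["animal_n"] = animal_n if animal_n is not None else df["animal_id"].nunique()
    return df


# --- visits -----------------------------------------------------------------

def test_read_trains_consolidate_into_printed_visit_boundaries(reads):
    v = pf.visits(reads, bw=3)
    at_2100 = v[v["logger_id"] == "2100"]
    assert [(s.strftime("%H:%M:%S"), e.strftime("%H:%M:%S"))
            for s, e in zip(at_2100["start"], at_2100["end"])] == [
        ("17:38:52", "17:39:00"), ("17:39:12", "17:39:12"), ("17:40:53", "17:40:53")]
    assert (v["animal_n"] == 1).all()
    # the metadata columns ride along
    assert set(v["species"]) == {"House Finch"}


def test_single_read_yields_instantaneous_visit():
    v = pf.visits(make_reads([("a", "2015-10-01 10:00:00", "L")]))
    assert len(v) == 1
    assert v["start"].iloc[0] == v["end"].iloc[0]


def test_dense_train_merges_or_splits_with_cutoff():
    t0 = dt.datetime(2015, 10, 1, 10, 0, 0)
    rows = [("a", (t0 + dt.timedelta(seconds=i)).isoformat(sep=" "), "L")
            for i in range(100)]
    one = pf.visits(make_reads(rows), bw=3)
    assert len(one) == 1
    assert (one["end"].iloc[0] - one["start"].iloc[0]).total_seconds() == 99
    each = pf.visits(make_reads(rows), bw=1)
    assert len(each) == 100


def test_same_animal_two_loggers_within_cutoff_is_impossible():
    rows = [("a", "2015-10-01 10:00:00", "L1"), ("a", "2015-10-01 10:00:01", "L2")]
    with pytest.raises(ImpossibleReadError, match="L1.*L2"):
        pf.visits(make_reads(rows), bw=3)
    with pytest.warns(UserWarning, match="impossible"):
        v = pf.visits(make_reads(rows), bw=3, allow_imp=True)
    assert len(v) == 1 and v["logger_id"].iloc[0] == "L1"


def test_animal_n_counts_every_animal_in_the_input():
    rows = [("a", "2015-10-01 10:00:00", "L1"), ("b", "2015-10-01 12:00:00", "L2"),
            ("c", "2015-10-01 14:00:00", "L1")]
    v = pf.visits(make_reads(rows))
    assert (v["animal_n"] == 3).all()


# --- displacements ----------------------------------------------------------

def test_arrival_just_after_departure_is_a_displacement():
    v = make_visits([("A", "2015-10-01 09:59:00", "2015-10-01 10:00:00", "L1"),
                     ("B", "2015-10-01 10:00:01", "2015-10-01 10:00:30", "L1")])
    d = pf.displacements(v, bw=2)
    assert len(d) == 1
    rec = d.iloc[0]
    assert (rec.displacer, rec.displacee, rec.gap_seconds) == ("B", "A", 1.0)


def test_slow_arrival_is_not_a_displacement():
    v = make_visits([("A", "2015-10-01 09:59:00", "2015-10-01 10:00:00", "L1"),
                     ("B", "2015-10-01 10:00:05", "2015-10-01 10:00:30", "L1")])
    assert len(pf.displacements(v, bw=2)) == 0


def test_single_animal_never_displaces_itself(visit_table):
    assert len(pf.displacements(visit_table)) == 0


def test_simultaneous_starts_pair_deterministically():
    v = make_visits([("A", "2015-10-01 10:00:00", "2015-10-01 10:00:04", "L1"),
                     ("B", "2015-10-01 10:00:00", "2015-10-01 10:00:02", "L1"),
                     ("C", "2015-10-01 10:00:05", "2015-10-01 10:00:09", "L1")])
    d = pf.displacements(v, bw=2)
    # C arrives 1 s after A's end (the most recently ended prior visit)
    assert list(d["displacee"]) == ["A"]
    assert list(d["displacer"]) == ["C"]


# --- movements --------------------------------------------------------------

def test_logger_switches_become_movements_with_inverse_hour_strength(visit_table):
    m = pf.movements(visit_table)
    assert list(m["move_id"]) == [1, 2, 3]
    assert list(m["move_dir"]) == ["2100_2700", "2700_2200", "2200_2700"]
    assert list(m["move_path"]) == ["2100_2700", "2200_2700", "2200_2700"]
    assert [round(s, 2) for s in m["strength"]] == [14.57, 0.06, 0.60]
    # overnight transition spans midnight without special handling
    assert m["left_time"].iloc[1].date() != m["arrived_time"].iloc[1].date()


def test_long_format_emits_left_and_arrived_rows(visit_table):
    long = pf.movements_long(pf.movements(visit_table))
    assert len(long) == 6
    assert list(long["direction"]) == ["left", "arrived"] * 3
    first = long.iloc[:2]
    assert list(first["logger_id"]) == ["2100", "2700"]
    assert (first["strength"].round(2) == 14.57).all()


def test_single_logger_data_has_no_movements():
    v = make_visits([("a", "2015-10-01 10:00:00", "2015-10-01 10:00:05", "L"),
                     ("a", "2015-10-01 11:00:00", "2015-10-01 11:00:05", "L")])
    assert len(pf.movements(v)) == 0


def test_zero_travel_time_is_an_error_unless_allowed():
    v = make_visits([("a", "2015-10-01 10:00:00", "2015-10-01 10:00:05", "L1"),
                     ("a", "2015-10-01 10:00:05", "2015-10-01 10:00:09", "L2")])
    with pytest.raises(ImpossibleReadError, match="zero"):
        pf.movements(v)
    with pytest.warns(UserWarning, match="zero-travel"):
        assert len(pf.movements(v, allow_imp=True)) == 0


# --- presence ---------------------------------------------------------------

def test_regular_visits_chain_into_printed_bout_lengths(visit_table):
    p = pf.presence(visit_table, bw=15)
    by_start = p.sort_values("start").reset_index(drop=True)
    assert by_start["length"].iloc[0] == pytest.approx(2.016667, abs=5e-7)
    assert by_start["length"].iloc[1] == pytest.approx(11.700000, abs=5e-7)
    assert by_start["logger_id"].tolist()[:2] == ["2100", "2700"]


def test_gap_above_cutoff_splits_bouts_and_below_merges():
    v = make_visits([("a", "2015-10-01 10:00:00", "2015-10-01 10:01:00", "L"),
                     ("a", "2015-10-01 10:31:00", "2015-10-01 10:32:00", "L")])
    assert len(pf.presence(v, bw=15)) == 2
    assert len(pf.presence(v, bw=45)) == 1


def test_logger_change_breaks_a_bout_even_within_cutoff():
    v = make_visits([("a", "2015-10-01 10:00:00", "2015-10-01 10:01:00", "L1"),
                     ("a", "2015-10-01 10:02:00", "2015-10-01 10:03:00", "L2"),
                     ("a", "2015-10-01 10:04:00", "2015-10-01 10:05:00", "L1")])
    p = pf.presence(v, bw=15)
    assert len(p) == 3


# --- grouped application ----------------------------------------------------

def test_groups_never_share_events(reads):
    two = pd.concat(
        [reads.assign(experiment=1), reads.assign(experiment=2)], ignore_index=True
    )
    v = pf.apply_grouped(two, ["experiment"], "visits", bw=3)
    for _, grp in v.groupby("experiment"):
        assert len(grp) == 4  # the ungrouped visit set, per group
        assert (grp["animal_n"] == 1).all()
    m = pf.apply_grouped(v, ["experiment"], "move")
    assert set(m["experiment"]) == {1, 2}
    # movements never pair visits across experiments: each group has its own
    assert len(m) == 2 * len(pf.movements(pf.visits(reads)))


def test_single_group_equals_ungrouped_call(reads):
    one = pf.apply_grouped(reads.assign(experiment="x"), ["experiment"], "visits")
    plain = pf.visits(reads.assign(experiment="x"))
    pd.testing.assert_frame_equal(
        one[["animal_id", "start", "end", "logger_id"]],
        plain[["animal_id", "start", "end", "logger_id"]],
    )


def test_unknown_stage_or_key_rejected(reads):
    with pytest.raises(ValidationError, match="unknown group key"):
        pf.apply_grouped(reads, ["nope"], "visits")
    with pytest.raises(ValidationError, match="unknown stage"):
        pf.apply_grouped(reads.assign(g=1), ["g"], "teleport")


# --- oracle equivalence and invariants on random streams --------------------

@pytest.mark.parametrize("seed", range(5))
def test_random_streams_match_brute_force_oracles(seed):
    rng = np.random.default_rng(1000 + seed)
    d = oracles.random_detection_table(rng, max_reads=150)
    v = pf.visits(d, bw=3)
    expect = oracles.oracle_visits(oracles.records_of(d), 3)
    got = oracles.visit_records_of(v)
    assert [(g["animal"], g["logger"], g["start"], g["end"]) for g in got] == [
        (e["animal"], e["logger"], e["start"], e["end"]) for e in expect]

    vis = oracles.visit_records_of(v)
    d_events = pf.displacements(v, bw=2)
    o_events = oracles.oracle_displacements(vis, 2)
    assert [(r.displacer, r.displacee) for r in d_events.itertuples(index=False)] == [
        (e["displacer"], e["displacee"]) for e in o_events]

    m = pf.movements(v)
    o_moves = oracles.oracle_movements(vis)
    assert [(r.animal_id, r.left_logger, r.arrived_logger)
            for r in m.itertuples(index=False)] == [
        (e["animal"], e["left"], e["arrived"]) for e in o_moves]
    np.testing.assert_allclose(
        m["strength"].to_numpy(dtype=float),
        np.array([e["strength"] for e in o_moves], dtype=float),
    )

    p = pf.presence(v, bw=5)
    o_bouts = oracles.oracle_presence(vis, 5)
    assert [(r.animal_id, r.logger_id, r.start.to_pydatetime(), r.end.to_pydatetime())
            for r in p.itertuples(index=False)] == [
        (b["animal"], b["logger"], b["start"], b["end"]) for b in o_bouts]


@given(st.integers(0, 10_000))
def test_conservation_and_monotonicity(seed):
    rng = np.random.default_rng(seed)
    d = oracles.random_detection_table(rng, max_reads=60)
    counts = []
    for bw in (1, 2, 3, 5, 8, 13):
        v = pf.visits(d, bw=bw)
        counts.append(len(v))
        # read conservation: visit spans tile each animal's reads exactly
        spans = sum(
            ((d["animal_id"] == r.animal_id) & (d["logger_id"] == r.logger_id)
             & (d["time"] >= r.start) & (d["time"] <= r.end)).sum()
            for r in v.itertuples(index=False))
        assert spans >= len(d)
    assert counts == sorted(counts, reverse=True)  # non-increasing in bw

    v = pf.visits(d, bw=3)
    bouts = [len(pf.presence(v, bw=bw)) for bw in (1, 5, 15, 60)]
    assert bouts == sorted(bouts, reverse=True)
    # every visit lies inside exactly one bout
    p = pf.presence(v, bw=15)
    for r in v.itertuples(index=False):
        inside = ((p["animal_id"] == r.animal_id) & (p["logger_id"] == r.logger_id)
                  & (p["start"] <= r.start) & (p["end"] >= r.end)).sum()
        assert inside == 1
    # bout lengths include inter-visit gaps
    v_tot = ((v["end"] - v["start"]).dt.total_seconds() / 60).sum()
    assert p["length"].sum() >= v_tot - 1e-9


def test_movement_count_equals_logger_switches():
    rng = np.random.default_rng(7)
    d = oracles.random_detection_table(rng, max_reads=120)
    v = pf.visits(d, bw=3)
    switches = sum(
        (grp.sort_values("start")["logger_id"].shift() != grp.sort_values("start")["logger_id"])
        .iloc[1:].sum()
        for _, grp in v.groupby("animal_id"))
    m = pf.movements(v)
    assert len(m) == switches
    assert (m["strength"] > 0).all() and np.isfinite(m["strength"]).all()
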