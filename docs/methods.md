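# Methods

## The detection-stream model

The unit of input is a *read*: one animal (opaque `animal_id`, e.g. a PIT
tag code) detected at one georeferenced station (`logger_id`) at a
timestamp with 1-second precision. All downstream structure is imposed by a
single family of gap rules applied to chronologically ordered reads of each
animal. The rules assume the stations are fixed and that a tag cannot be at
two stations at once; nothing else about the animals' behaviour is assumed.

### Gap rule and boundary convention

Every transformation merges two events when the gap between them is
**strictly less than** its cutoff (`gap < bw`), implemented once in
`transform.gap_merges` and reused by visits, displacements and presence.
The published example tables do not discriminate between `<` and `<=`
(observed gaps sit well away from the cutoffs), so the strict rule was
chosen for all three and documented rather than split per stage.

### Stages and their parameters

| stage | cutoff `bw` | default | meaning |
|---|---|---|---|
| `visits` | seconds | 3 | max inter-read gap inside one visit |
| `disp` | seconds | 2 | max departure→arrival gap for a supplant |
| `presence` | minutes | 15 | max inter-visit gap inside one bout |
| `activity` | `res`, minutes | 15 | bin width of the activity grid |

Defaults follow established practice for perch-mounted RFID feeders, where
the antenna reports roughly every 2 s while the bird sits in range.

**Visits.** A logger change always ends a visit. The same animal appearing
at two loggers *within* the visit cutoff is physically impossible and
raises an error by default; with `allow_imp=True` the later conflicting
read is dropped with a warning (data-integrity first, recovery second).
Each visit row carries `animal_n`, the number of distinct animals in the
input table, so later per-individual averaging uses the population that was
actually monitored rather than the subset appearing in a filtered table.

**Displacements.** Each arriving visit is paired with the *most recently
ended* prior visit at that logger; an event is scored when the animals
differ and `0 <= gap < bw`. Pairing with the most recent departure (rather
than requiring the displacee's visit to still be ongoing) is the design
choice here; ties between simultaneous starts are broken by
`(start, end, animal_id)` ordering, so output is deterministic.

**Movements.** Strength is `3600 / Δt` with `Δt` in seconds — the inverse
of travel time expressed in 1/hours, so a 4-minute hop scores ≈ 14.6 and an
overnight transition ≈ 0.06. `move_dir` is the directed `from_to` string;
`move_path` sorts the pair lexicographically to give the undirected edge
label used in path-use summaries. Zero travel time (arrival at the instant
of departure, only possible in hand-edited visit tables) leaves strength
undefined and is an error unless explicitly skipped. A two-row
left/arrived long format is available via `movements_long` for
interoperability with event-per-row workflows.

**Presence.** Bouts run from the first chained visit's start to the last
chained visit's *end* (not its start; the example tables cannot
distinguish the two because their final chained visits are instantaneous,
so this is a documented choice). Bout length therefore includes inter-visit
gaps. No day-boundary logic exists anywhere: visits, bouts and movements
span midnight naturally.

**Grouped application.** `apply_grouped` runs any stage independently
within groups defined by metadata columns (e.g. experiment site), so no
event ever spans two groups and `animal_n` is computed within each group.
This supports designs where the same individuals appear in spatially or
temporally separate experiments whose movements must not be conflated.

## Activity scoring

The grid uses half-open bins `[t, t + res)` anchored at local midnight;
`res` must divide 1440 so bins tile the day. A bin is active when it
overlaps any bout; a bout ending exactly on a boundary does not activate
the next bin (no double counting), while an instantaneous bout activates
the bin containing its instant. The grid spans each animal's observed range
only — first bout start floored to the grid, last bout end ceiled — so
periods with no deployment are not scored as inactivity. Bins are naive
local wall-clock times: after conversion the timezone is dropped, which
keeps every bin an exact multiple of `res` after midnight even across
daylight-saving transitions (at the cost of one ambiguous/skipped hour per
year in zones that observe DST).

`daily_pattern` reports, per animal and time-of-day bin, the proportion of
observed days in which the bin was active, with `n_days` the denominator;
days never observed in a bin are excluded from the denominator rather than
counted inactive, and the full `1440/res` bin set is emitted with
`n_days = 0` for bins outside the observed range. Time-of-day vectors for
circular-statistics tooling map event times to
`2π · seconds-after-midnight / 86400`.

## Summaries and exports

`sum` totals presence minutes per logger and movement counts per undirected
path; `sum_indiv` divides by `animal_n`; `indiv` resolves per animal with
an optional id filter; `none` validates and passes through caller-computed
amounts — the route by which externally grouped summaries reach the
renderer unchanged. Two exact identities hold by construction and are
enforced in tests: `sum_indiv × animal_n = sum`, and per-logger `indiv`
rows partition the `sum` row.

Displacements export as a chronological winner/loser sequence plus a square
winner×loser count matrix (animals sorted lexicographically, zero
diagonal); detection tables export as a `(seconds-from-start, id, location)`
event stream. Both are defined structurally; downstream packages consume
them after trivial column renaming.

## Map rendering

Rendering is matplotlib-only and offline: straight edges in lon/lat space
under scatter nodes, equal-aspect axes, two legends, black station markers
always on top. Display sizes are a linear map of the value range onto a
configurable size range (constant layers map to the midpoint so they stay
visible), times the `p_scale`/`m_scale` tweaks; the exact scaling law of
interactive web maps is presentation, not computation, so a transparent
linear rule was preferred. Rendering is deterministic for fixed inputs.

## Simulator

`synth.simulate_detections` generates per-animal alternating bouts and
gaps: within a visit, reads at a fixed interval (default 2 s); within a
bout, 1 + Poisson(2) visits separated by uniform 6–300 s gaps; between
bouts, 1800 s + Exp(mean 2 h) gaps with optional station switching
(probability 0.5); default 3 animals over 36 h on a four-station grid.
All times are integer seconds so text round trips are exact. The draw
parameters are validated and clipped into guard bands around the target
cutoffs (read interval < visit cutoff; intra-bout gaps strictly between the
visit and presence cutoffs; inter-bout gaps above the presence cutoff),
which makes recovery exact by construction: the transformations must return
the emitted visits, bouts and movement counts identically, for any seed.
Infeasible guard bands raise immediately.

What the simulator does *not* emulate: diel rhythms, dominance-driven
interference, read dropouts, tag collisions at crowded perches, or clock
drift between loggers. Passing recovery tests therefore demonstrates the
correctness of the gap-rule algebra on well-separated data, not robustness
to noisy field data; the strict-error behaviour on impossible reads is the
main guard for the latter.

Test problem sizes were chosen to probe the combinatorics densely while
staying lightweight: 500 random streams of ≤ 200 reads for brute-force
oracle equivalence, 50 seeds × 2 animals × 6 h for exact recovery, and
3 animals × 12 h for dialect round trips.

## Timestamp handling

Timestamp dialects are described by field order (`"ymd HMS"`,
`"dmy HM p"`), not strftime patterns; separators are ignored. Two-digit
years pivot per POSIX convention (00–68 → 2000s, 69–99 → 1900s). Timezones
are IANA names; spring-forward nonexistent local times are an error, and
ambiguous fall-back times resolve deterministically to the earlier offset.
CSV output writes local wall-clock ISO 8601 to the second; the timezone
lives in the loading options, making round trips exact.

## Known limitations

- Station coordinates conflicting between a `details=2` file header and a
  logger index are never silently reconciled; overwriting requires an
  explicit flag.
- Activity bins ignore timezone offsets within a day (see above), so a DST
  transition shifts at most one hour of bins per year.
- The displacement rule cannot distinguish a supplant from a coincidental
  quick succession; the cutoff is the only filter.
- `summarize_movements` counts paths; it does not weight by strength
  (strength is per-event and available upstream for custom summaries).
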