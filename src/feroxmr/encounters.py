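"""Encounter records, cohort recapture tables and capture-history matrices.

The raw data of an angling mark-recapture study are *encounter records*:
one row per capture or recapture of an identified fish in a calendar year.
Publications usually summarise them as a *cohort recapture table* (an
m-array-like summary: first captures per year, plus recaptures
cross-classified by cohort year and recapture year), while the Jolly-Seber
model consumes an individuals x occasions binary *capture-history matrix*.
This module represents all three forms and converts between them, including
a canonical, deterministic reconstruction of capture histories from a
published cohort table when the per-individual histories themselves were
never published.

The packaged dataset is the 16-year (1994-2009) Loch Rannoch Ferox Trout
angling study: 69 individuals, 80 retained encounters, 11 inter-annual
recapture events, 7 individuals caught in more than one year.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "EncounterRecord",
    "CohortRecaptureTable",
    "CaptureHistoryMatrix",
    "MalformedDataError",
    "InfeasibleAssignmentError",
    "load_rannoch_table",
    "rannoch_encounter_records",
    "filter_encounters",
    "encounters_to_matrix",
    "reconstruct_histories",
    "enumerate_recapture_assignments",
    "summarize_to_table",
    "read_encounters",
    "write_encounters",
    "read_cohort_table",
    "write_cohort_table",
]

EVENT_TYPES = ("initial", "recapture")
EXCLUSION_REASONS = ("deformity", "intra_annual", "non_participant")

#: Occasions of the packaged Loch Rannoch study (annual, calendar years).
RANNOCH_YEARS: tuple[int, ...] = tuple(range(1994, 2010))

#: First captures per cohort year, 1994..2009 (sums to 69 individuals).
_RANNOCH_INITIAL = (7, 6, 5, 2, 5, 2, 12, 6, 3, 4, 2, 2, 1, 1, 2, 9)

#: The 11 inter-annual recapture events as (cohort year, recapture year).
_RANNOCH_RECAPTURES = (
    (1994, 1998),
    (1994, 2001),
    (1998, 2002),
    (1998, 2006),
    (2000, 2002),
    (2000, 2003),
    (2001, 2002),
    (2001, 2004),
    (2001, 2005),
    (2005, 2007),
    (2005, 2009),
)


class MalformedDataError(ValueError):
    """Raised for inconsistent or unparseable encounter/table data."""


class InfeasibleAssignmentError(ValueError):
    """Raised when a requested recaptured-individual count cannot be realised."""


@dataclass(frozen=True)
class EncounterRecord:
    """One capture or recapture of one fish in one calendar year."""

    fish_id: str
    year: int
    event: str
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event not in EVENT_TYPES:
            raise MalformedDataError(f"unknown event type {self.event!r}")
        if self.excluded_reason is not None and self.excluded_reason not in EXCLUSION_REASONS:
            raise MalformedDataError(f"unknown exclusion reason {self.excluded_reason!r}")


@dataclass(frozen=True)
class CohortRecaptureTable:
    """m-array-style summary: first captures per cohort year plus recaptures.

    ``recaptures`` maps ``(cohort_year, recapture_year)`` with
    ``recapture_year > cohort_year`` to a positive event count.
    """

    years: tuple[int, ...]
    initial_captures: tuple[int, ...]
    recaptures: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.years) != len(self.initial_captures):
            raise MalformedDataError("years and initial_captures length mismatch")
        if list(self.years) != sorted(set(self.years)):
            raise MalformedDataError("years must be strictly increasing")
        if any(c < 0 for c in self.initial_captures):
            raise MalformedDataError("negative initial capture count")
        yearset = set(self.years)
        for (c, r), n in self.recaptures.items():
            if c not in yearset or r not in yearset:
                raise MalformedDataError(f"recapture cell ({c}, {r}) outside study years")
            if r <= c:
                raise MalformedDataError(f"recapture year {r} not after cohort year {c}")
            if n < 0:
                raise MalformedDataError("negative recapture count")
            if n > 0 and self.initial_captures[self.years.index(c)] == 0:
                raise MalformedDataError(f"cohort {c} has recaptures but no initial captures")

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.initial_captures))

    @property
    def n_recapture_events(self) -> int:
        return int(sum(self.recaptures.values()))

    def cohort_events(self, cohort_year: int) -> list[int]:
        """Recapture years of one cohort, as a sorted multiset."""
        out: list[int] = []
        for (c, r), n in sorted(self.recaptures.items()):
            if c == cohort_year:
                out.extend([r] * n)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortRecaptureTable):
            return NotImplemented
        return (
            self.years == other.years
            and tuple(self.initial_captures) == tuple(other.initial_captures)
            and {k: v for k, v in self.recaptures.items() if v}
            == {k: v for k, v in other.recaptures.items() if v}
        )


@dataclass(frozen=True)
class CaptureHistoryMatrix:
    """Binary detections of observed individuals over annual occasions."""

    y: np.ndarray
    years: tuple[int, ...]
    fish_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int8)
        if y.ndim != 2 or y.shape[1] != len(self.years):
            raise MalformedDataError("matrix shape does not match occasion labels")
        if not np.isin(y, (0, 1)).all():
            raise MalformedDataError("detection matrix must be binary")
        if y.shape[0] and (y.sum(axis=1) < 1).any():
            raise MalformedDataError("every observed individual needs >=1 detection")
        object.__setattr__(self, "y", y)

    @property
    def n_individuals(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_occasions(self) -> int:
        return int(self.y.shape[1])

    @property
    def n_encounters(self) -> int:
        return int(self.y.sum())

    @property
    def annual_encounters(self) -> np.ndarray:
        """Total encounters (first captures plus recaptures) per occasion."""
        return self.y.sum(axis=0)

    def n_multiply_detected(self) -> int:
        return int((self.y.sum(axis=1) >= 2).sum())


def load_rannoch_table() -> CohortRecaptureTable:
    """The packaged Loch Rannoch Ferox Trout cohort recapture table.

    16 annual angling occasions 1994-2009; 69 first captures and 11
    inter-annual recapture events.
    """
    recaptures = {pair: 1 for pair in _RANNOCH_RECAPTURES}
    return CohortRecaptureTable(RANNOCH_YEARS, _RANNOCH_INITIAL, recaptures)


# ---------------------------------------------------------------------------
# Filtering raw encounter records
# ---------------------------------------------------------------------------

def filter_encounters(records: Sequence[EncounterRecord]) -> list[EncounterRecord]:
    """Apply the study's exclusion rules and return the retained records.

    Rules, in order:

    1. every encounter of a fish carrying a ``deformity`` flag is dropped
       (the fish leaves the study entirely);
    2. encounters flagged ``non_participant`` (recaptures by anglers outside
       the study crew) are dropped;
    3. within one (fish, year), only the first encounter is retained;
       second and later same-year encounters are intra-annual recaptures
       (occasions are annual and sampling is treated as instantaneous).

    Exact duplicate ``(fish_id, year, event)`` rows are rejected as
    malformed input. The operation is idempotent.
    """
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        key = (rec.fish_id, rec.year, rec.event)
        if key in seen:
            raise MalformedDataError(f"duplicate encounter row {key}")
        seen.add(key)

    deformed = {r.fish_id for r in records if r.excluded_reason == "deformity"}
    retained: list[EncounterRecord] = []
    taken_years: set[tuple[str, int]] = set()
    for rec in records:
        if rec.fish_id in deformed:
            continue
        if rec.excluded_reason == "non_participant":
            continue
        if (rec.fish_id, rec.year) in taken_years:
            continue
        if rec.excluded_reason == "intra_annual":
            # pre-flagged same-year duplicate; the first-of-year rule below
            # would also catch it when the first event is present
            continue
        taken_years.add((rec.fish_id, rec.year))
        retained.append(rec)
    return retained


def encounters_to_matrix(
    records: Sequence[EncounterRecord],
    years: Optional[Sequence[int]] = None,
) -> CaptureHistoryMatrix:
    """Build the binary capture-history matrix from retained encounters."""
    if years is None:
        if not records:
            raise MalformedDataError("cannot infer study years from no records")
        years = range(min(r.year for r in records), max(r.year for r in records) + 1)
    years = tuple(int(y) for y in years)
    index = {y: t for t, y in enumerate(years)}

    by_fish: dict[str, list[EncounterRecord]] = {}
    for rec in records:
        if rec.year not in index:
            raise MalformedDataError(f"encounter year {rec.year} outside study years")
        by_fish.setdefault(rec.fish_id, []).append(rec)

    ids = sorted(by_fish, key=lambda f: (min(r.year for r in by_fish[f]), f))
    y = np.zeros((len(ids), len(years)), dtype=np.int8)
    for i, fish in enumerate(ids):
        recs = sorted(by_fish[fish], key=lambda r: r.year)
        if recs[0].event != "initial":
            raise MalformedDataError(f"first retained encounter of {fish} is not 'initial'")
        for rec in recs:
            if y[i, index[rec.year]]:
                raise MalformedDataError(f"two retained encounters of {fish} in {rec.year}")
            y[i, index[rec.year]] = 1
    return CaptureHistoryMatrix(y, years, tuple(ids))


# ---------------------------------------------------------------------------
# Cohort table <-> capture histories
# ---------------------------------------------------------------------------

def _split_counts(table: CohortRecaptureTable, n_recaptured: int) -> dict[int, int]:
    """Number of recaptured individuals assigned to each cohort (canonical).

    Start with one recaptured individual per cohort that has any recapture
    events, then repeatedly add one more individual to the cohort with the
    most first captures that can still absorb one (ties broken by earlier
    cohort year) until the study-wide count is reached. Cohorts with many
    fish are the most plausible hosts of additional recaptured individuals.
    """
    cohorts = [c for c in table.years if table.cohort_events(c)]
    if not cohorts and n_recaptured == 0:
        return {}
    capacity = {
        c: min(len(table.cohort_events(c)), table.initial_captures[table.years.index(c)])
        for c in cohorts
    }
    n_min, n_max = len(cohorts), sum(capacity.values())
    if not n_min <= n_recaptured <= n_max:
        raise InfeasibleAssignmentError(
            f"n_recaptured_individuals={n_recaptured} infeasible; "
            f"attainable range is [{n_min}, {n_max}]"
        )
    counts = {c: 1 for c in cohorts}
    for _ in range(n_recaptured - n_min):
        open_cohorts = [c for c in cohorts if counts[c] < capacity[c]]
        pick = max(open_cohorts, key=lambda c: (table.initial_captures[table.years.index(c)], -c))
        counts[pick] += 1
    return counts


def _distribute_events(events: list[int], k: int) -> list[list[int]]:
    """Deterministically split a sorted recapture-year list among k individuals.

    The first individual takes the earliest ``len(events) - k + 1`` events;
    each remaining individual takes one of the later events in order.
    """
    head = len(events) - k + 1
    return [events[:head]] + [[e] for e in events[head:]]


def reconstruct_histories(
    table: CohortRecaptureTable,
    n_recaptured_individuals: int,
) -> CaptureHistoryMatrix:
    """Canonical capture-history matrix consistent with a cohort table.

    A cohort table fixes the annual first-capture and recapture totals but
    not which individual received which recapture event. This builds the one
    canonical matrix in which exactly ``n_recaptured_individuals`` rows have
    two or more detections: within each cohort the recapture events are
    concentrated on as few individuals as possible, and extra recaptured
    individuals are opened up cohort-by-cohort via :func:`_split_counts`.
    Row order is deterministic (cohort year, recaptured individuals first).

    Raises :class:`InfeasibleAssignmentError` when the requested count is
    outside the attainable range.
    """
    counts = _split_counts(table, n_recaptured_individuals)
    index = {y: t for t, y in enumerate(table.years)}
    rows: list[np.ndarray] = []
    for c in table.years:
        events = table.cohort_events(c)
        n_init = table.initial_captures[index[c]]
        groups = _distribute_events(events, counts[c]) if events else []
        for grp in groups:
            row = np.zeros(len(table.years), dtype=np.int8)
            row[index[c]] = 1
            for r in grp:
                row[index[r]] = 1
            rows.append(row)
        for _ in range(n_init - len(groups)):
            row = np.zeros(len(table.years), dtype=np.int8)
            row[index[c]] = 1
            rows.append(row)
    y = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(table.years)), np.int8)
    return CaptureHistoryMatrix(y, table.years)


def _set_partitions(items: Sequence[int], k: int) -> Iterator[list[list[int]]]:
    """All partitions of ``items`` into exactly k nonempty unlabeled blocks."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if k == len(items):
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    # first item joins an existing block of a (k)-partition of the rest,
    # or forms its own block alongside a (k-1)-partition of the rest
    for part in _set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
    for part in _set_partitions(rest, k - 1):
        yield [[first]] + part


def enumerate_recapture_assignments(
    table: CohortRecaptureTable,
    n_recaptured_individuals: int,
) -> Iterator[CaptureHistoryMatrix]:
    """All feasible assignments of recapture events to individuals.

    Yields every capture-history matrix whose summary equals ``table`` and
    in which exactly ``n_recaptured_individuals`` rows carry >=2 detections,
    enumerating set partitions of each cohort's recapture-event multiset.
    Used for sensitivity analyses over the assignment ambiguity.
    """
    cohorts = [c for c in table.years if table.cohort_events(c)]
    index = {y: t for t, y in enumerate(table.years)}
    capacity = [
        min(len(table.cohort_events(c)), table.initial_captures[index[c]]) for c in cohorts
    ]
    n_min, n_max = len(cohorts), sum(capacity)
    if cohorts and not n_min <= n_recaptured_individuals <= n_max:
        raise InfeasibleAssignmentError(
            f"n_recaptured_individuals={n_recaptured_individuals} infeasible; "
            f"attainable range is [{n_min}, {n_max}]"
        )

    ranges = [range(1, cap + 1) for cap in capacity]
    for ks in itertools.product(*ranges):
        if sum(ks) != n_recaptured_individuals:
            continue
        per_cohort_parts = [
            list(_set_partitions(table.cohort_events(c), k)) for c, k in zip(cohorts, ks)
        ]
        for combo in itertools.product(*per_cohort_parts):
            assignment = dict(zip(cohorts, combo))
            rows: list[np.ndarray] = []
            for c in table.years:
                groups = assignment.get(c, [])
                for grp in groups:
                    row = np.zeros(len(table.years), dtype=np.int8)
                    row[index[c]] = 1
                    for r in grp:
                        row[index[r]] = 1
                    rows.append(row)
                for _ in range(table.initial_captures[index[c]] - len(groups)):
                    row = np.zeros(len(table.years), dtype=np.int8)
                    row[index[c]] = 1
                    rows.append(row)
            yield CaptureHistoryMatrix(np.array(rows, dtype=np.int8), table.years)


def summarize_to_table(matrix: CaptureHistoryMatrix) -> CohortRecaptureTable:
    """Summarise a capture-history matrix back to a cohort recapture table."""
    if matrix.n_individuals and (matrix.y.sum(axis=1) == 0).any():
        raise MalformedDataError("row with no detections")
    initial = [0] * matrix.n_occasions
    recaptures: dict[tuple[int, int], int] = {}
    for row in matrix.y:
        det = np.flatnonzero(row)
        c = matrix.years[det[0]]
        initial[det[0]] += 1
        for t in det[1:]:
            key = (c, matrix.years[t])
            recaptures[key] = recaptures.get(key, 0) + 1
    return CohortRecaptureTable(matrix.years, tuple(initial), recaptures)


# ---------------------------------------------------------------------------
# Packaged encounter-record fixture
# ---------------------------------------------------------------------------

def rannoch_encounter_records(include_excluded: bool = True) -> list[EncounterRecord]:
    """The Loch Rannoch study as encounter records.

    The 80 retained encounters are derived from the canonical reconstruction
    of the published cohort table (individual identities beyond F21 are a
    synthetic but internally consistent numbering; F21 is the 1998-cohort
    fish recaught in 2002 and 2006). With ``include_excluded=True`` the rows
    removed by the study's filtering rules are appended, each flagged with
    its exclusion reason: the two deformed fish (each caught and recaught
    once), four intra-annual recaptures, and the two recaptures by
    non-participating anglers. The excluded rows' years are synthetic
    placeholders -- the publication does not report them -- chosen only to
    be valid study years; they never reach the model because
    :func:`filter_encounters` removes them.
    """
    matrix = reconstruct_histories(load_rannoch_table(), 7)
    # number fish in cohort order; recaptured fish come first within each
    # cohort, which places the 1998-cohort recaptured fish at F21; skip the
    # ids of the two excluded deformed fish so they can keep F53 and F58
    ids: list[str] = []
    n = 1
    for _ in range(matrix.n_individuals):
        while n in (53, 58):
            n += 1
        ids.append(f"F{n:02d}")
        n += 1
    records: list[EncounterRecord] = []
    for fish, row in zip(ids, matrix.y):
        det = np.flatnonzero(row)
        records.append(EncounterRecord(fish, matrix.years[det[0]], "initial"))
        for t in det[1:]:
            records.append(EncounterRecord(fish, matrix.years[t], "recapture"))
    if include_excluded:
        records += [
            # deformed spine / deformed jaw: the whole fish is excluded
            EncounterRecord("F53", 1999, "initial", "deformity"),
            EncounterRecord("F53", 2001, "recapture", "deformity"),
            EncounterRecord("F58", 2000, "initial", "deformity"),
            EncounterRecord("F58", 2003, "recapture", "deformity"),
            # four intra-annual recaptures (same-year second captures)
            EncounterRecord("F03", 1994, "recapture", "intra_annual"),
            EncounterRecord("F24", 1998, "recapture", "intra_annual"),
            EncounterRecord("F31", 2000, "recapture", "intra_annual"),
            EncounterRecord("F66", 2009, "recapture", "intra_annual"),
            # recaptures by non-participating anglers
            EncounterRecord("F13", 1998, "recapture", "non_participant"),
            EncounterRecord("F45", 2006, "recapture", "non_participant"),
        ]
    return records


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

_ENCOUNTER_COLUMNS = ("fish_id", "year", "event", "excluded_reason")


def write_encounters(records: Iterable[EncounterRecord], path) -> None:
    """Write encounter records as UTF-8 CSV with a fixed header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ENCOUNTER_COLUMNS)
        for rec in records:
            writer.writerow([rec.fish_id, rec.year, rec.event, rec.excluded_reason or ""])


def read_encounters(path) -> list[EncounterRecord]:
    """Read encounter records from CSV; parse errors name the line."""
    records: list[EncounterRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedDataError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != list(_ENCOUNTER_COLUMNS):
            raise MalformedDataError(f"{path}: line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise MalformedDataError(f"{path}: line {lineno}: expected 4 columns")
            fish_id, year_s, event, reason = (cell.strip() for cell in row)
            try:
                year = int(year_s)
            except ValueError:
                raise MalformedDataError(
                    f"{path}: line {lineno}: non-integer year {year_s!r}"
                ) from None
            try:
                records.append(
                    EncounterRecord(fish_id, year, event, reason or None)
                )
            except MalformedDataError as exc:
                raise MalformedDataError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_cohort_table(table: CohortRecaptureTable, path) -> None:
    """Write a cohort recapture table as wide CSV (one row per cohort year)."""
    recap_years = list(table.years[1:])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cohort_year", "initial_captures"] + [str(y) for y in recap_years])
        for i, c in enumerate(table.years):
            row = [c, table.initial_captures[i]]
            for r in recap_years:
                row.append(table.recaptures.get((c, r), 0) if r > c else "")
            writer.writerow(row)


def read_cohort_table(path) -> CohortRecaptureTable:
    """Read a wide-CSV cohort recapture table written by :func:`write_cohort_table`."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedDataError(f"{path}: empty file, expected header") from None
        if len(header) < 2 or header[0] != "cohort_year" or header[1] != "initial_captures":
            raise MalformedDataError(f"{path}: line 1: bad header")
        try:
            recap_years = [int(h) for h in header[2:]]
        except ValueError:
            raise MalformedDataError(f"{path}: line 1: non-integer recapture-year column") from None
        years: list[int] = []
        initial: list[int] = []
        recaptures: dict[tuple[int, int], int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                c = int(row[0])
                initial.append(int(row[1]))
            except (ValueError, IndexError):
                raise MalformedDataError(f"{path}: line {lineno}: bad cohort row") from None
            years.append(c)
            for r, cell in zip(recap_years, row[2:]):
                cell = cell.strip()
                if not cell or r <= c:
                    continue
                try:
                    n = int(cell)
                except ValueError:
                    raise MalformedDataError(
                        f"{path}: line {lineno}: non-integer count {cell!r}"
                    ) from None
                if n:
                    recaptures[(c, r)] = n
    return CohortRecaptureTable(tuple(years), tuple(initial), recaptures)
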