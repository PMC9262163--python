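"""Annual dyadic count/opportunity tables from raw behavioral event streams.

Three behaviors are scored, each with its own opportunity denominator:

* **grooming** (directed) — scored per 10-min focal follow; the opportunity
  for the ordered dyad (i, j) is the number of follows of *i* plus follows of
  *j* while the two were co-resident, and the count is the number of those
  follows in which *i* groomed *j* at least once.
* **support** (directed) — the aggression stream is segmented into 5-min
  conflict intervals; *i* joins *j* when *i* aggresses *j*'s opponent or
  victim within the interval (at most once per interval); every co-resident
  had the opportunity to join either participant of a conflict.
* **foraging** (undirected) — group scans in a foraging context; a dyad is in
  close proximity when scanned within 5 body lengths; opportunities are the
  dyad's qualifying scans thinned to be at least 10 min apart.

All builders are deterministic and emit tidy tables with columns
``year, behavior, actor, partner, count, opportunities``; rows with zero
opportunities are omitted. For the undirected foraging table ``actor`` and
``partner`` hold the unordered pair in sorted order.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADULT_AGE_YEARS = 5.0
DYAD_COLUMNS = ["year", "behavior", "actor", "partner", "count", "opportunities"]

#: optional predicate deciding whether a directed (actor, partner) pair at a
#: given time belongs to the dataset under construction
PairFilter = Callable[[str, str, pd.Timestamp], bool]


class MembershipIndex:
    """Fast lookups of group residence from the membership interval table.

    Interval bounds are held as int64 nanoseconds so residence queries are a
    vectorized mask rather than per-interval Timestamp comparisons.
    """

    def __init__(self, membership: pd.DataFrame):
        self._by_id: dict[str, list[tuple[int, int, str]]] = {}
        by_group: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for row in membership.itertuples(index=False):
            iv = (row.entry.value, row.exit.value, row.group)
            self._by_id.setdefault(row.id, []).append(iv)
            by_group[row.group].append((row.entry.value, row.exit.value, row.id))
        for intervals in self._by_id.values():
            intervals.sort()
        self._by_group = {
            g: (
                np.array([e for e, _, _ in rows], dtype=np.int64),
                np.array([x for _, x, _ in rows], dtype=np.int64),
                np.array([i for _, _, i in rows], dtype=object),
            )
            for g, rows in by_group.items()
        }

    def group_at(self, individual: str, t: pd.Timestamp) -> str | None:
        tv = t.value
        for entry, exit_, group in self._by_id.get(individual, ()):
            if entry <= tv <= exit_:
                return group
        return None

    def coresident(self, i: str, j: str, t: pd.Timestamp) -> bool:
        """True iff i and j belong to the same group at time t."""
        if i not in self._by_id or j not in self._by_id:
            raise KeyError(f"unknown individual id: {i if i not in self._by_id else j}")
        gi = self.group_at(i, t)
        return gi is not None and gi == self.group_at(j, t)

    def members_at(self, group: str, t: pd.Timestamp) -> set[str]:
        if group not in self._by_group:
            return set()
        entry, exit_, ids = self._by_group[group]
        tv = t.value
        return set(ids[(entry <= tv) & (tv <= exit_)])


def age_years(birth_date: pd.Timestamp, t: pd.Timestamp) -> float:
    """Age in years at time t (365.25-day years)."""
    return (t - birth_date) / pd.Timedelta(days=365.25)


def make_partner_filter(
    individuals: pd.DataFrame, partner_type: str, directed: bool
) -> PairFilter:
    """Build the dataset predicate for one of the three partner datasets.

    The subject side is always an adult female (age >= 5 at the event date);
    the partner side is restricted per ``partner_type``: ``all`` keeps every
    group member including immatures, ``adult_females`` / ``adult_males`` keep
    only adults of that sex. A directed row is kept when either direction has
    an adult-female subject paired with an in-class partner.
    """
    if partner_type not in ("all", "adult_females", "adult_males"):
        raise ValueError(f"unknown partner_type: {partner_type}")
    birth = dict(zip(individuals["id"], individuals["birth_date"]))
    sex = dict(zip(individuals["id"], individuals["sex"]))

    def is_adult_female(x: str, t: pd.Timestamp) -> bool:
        return sex[x] == "F" and age_years(birth[x], t) >= ADULT_AGE_YEARS

    def in_class(x: str, t: pd.Timestamp) -> bool:
        if partner_type == "all":
            return True
        want = "F" if partner_type == "adult_females" else "M"
        return sex[x] == want and age_years(birth[x], t) >= ADULT_AGE_YEARS

    def keep(a: str, b: str, t: pd.Timestamp) -> bool:
        return (is_adult_female(a, t) and in_class(b, t)) or (
            is_adult_female(b, t) and in_class(a, t)
        )

    return keep


def _finish(rows: dict, behavior: str, directed: bool) -> pd.DataFrame:
    out = [
        {
            "year": year,
            "behavior": behavior,
            "actor": a,
            "partner": b,
            "count": c,
            "opportunities": n,
        }
        for (year, a, b), (c, n) in rows.items()
        if n > 0
    ]
    df = pd.DataFrame(out, columns=DYAD_COLUMNS)
    df = df.sort_values(["year", "actor", "partner"], kind="mergesort").reset_index(drop=True)
    if (df["count"] > df["opportunities"]).any():
        raise AssertionError(f"count > opportunities in {behavior} table")
    return df


def build_grooming_dyads(
    follows: pd.DataFrame,
    grooming: pd.DataFrame,
    index: MembershipIndex,
    years: list[int] | None = None,
    pair_filter: PairFilter | None = None,
) -> pd.DataFrame:
    """Directed grooming dyad-year table from focal follows.

    The opportunity for (i, j) is the number of follows of i plus follows of
    j, restricted to times when i and j were co-resident; the count is the
    number of those follows in which i groomed j at least once. Grooming
    events that do not reference a known follow are skipped with a warning.
    """
    keep = pair_filter or (lambda a, b, t: True)
    follow_info: dict[str, tuple[str, pd.Timestamp]] = {}
    rows: dict[tuple, list] = defaultdict(lambda: [0, 0])

    for f in follows.itertuples(index=False):
        if years is not None and f.start.year not in years:
            continue
        follow_info[f.follow_id] = (f.focal, f.start)
        partners = index.members_at(f.group, f.start) - {f.focal}
        for p in partners:
            # one follow of the focal is one opportunity in both directions
            for a, b in ((f.focal, p), (p, f.focal)):
                if keep(a, b, f.start):
                    rows[(f.start.year, a, b)][1] += 1

    # at most one count per (groomer, groomee, follow)
    seen: set[tuple] = set()
    n_skipped = 0
    for ev in grooming.itertuples(index=False):
        info = follow_info.get(ev.follow_id)
        if info is None:
            if years is None or ev.time.year in years:
                n_skipped += 1
            continue
        focal, start = info
        if focal not in (ev.groomer, ev.groomee) or not index.coresident(
            ev.groomer, ev.groomee, start
        ):
            # an event its own follow could not have observed
            n_skipped += 1
            continue
        key = (ev.follow_id, ev.groomer, ev.groomee)
        if key in seen:
            continue
        seen.add(key)
        if keep(ev.groomer, ev.groomee, start):
            rows[(start.year, ev.groomer, ev.groomee)][0] += 1
    if n_skipped:
        logger.warning("skipped %d grooming events outside any valid follow", n_skipped)

    return _finish(rows, "grooming", directed=True)


def segment_aggression_intervals(
    aggression: pd.DataFrame, interval_minutes: float = 5.0
) -> list[dict]:
    """Partition each group's aggression stream into 5-min conflict intervals.

    Windows are anchored at the first event of each burst: a new interval
    starts at the first event at least ``interval_minutes`` after the current
    interval's anchor, so the segmentation is invariant to clock offset.
    Each interval carries its events and participant set.
    """
    width = pd.Timedelta(minutes=interval_minutes)
    intervals: list[dict] = []
    for group, g in aggression.groupby("group", sort=True):
        g = g.sort_values("time", kind="mergesort")
        anchor = None
        current: list = []
        for ev in g.itertuples(index=False):
            if anchor is None or ev.time - anchor >= width:
                if current:
                    intervals.append(_make_interval(group, anchor, current))
                anchor = ev.time
                current = []
            current.append((ev.aggressor, ev.target))
        if current:
            intervals.append(_make_interval(group, anchor, current))
    intervals.sort(key=lambda iv: (iv["start"], iv["group"]))
    return intervals


def _make_interval(group: str, start: pd.Timestamp, events: list) -> dict:
    participants = set()
    for a, t in events:
        participants.add(a)
        participants.add(t)
    return {"group": group, "start": start, "events": list(events), "participants": participants}


def score_joining(events: list[tuple[str, str]]) -> set[tuple[str, str]]:
    """Directed (joiner, joinee) pairs within one conflict interval.

    i joins j when i aggresses some third party X that j also aggressed
    (j's opponent or victim) or that aggressed j; dichotomous per interval.
    Temporal order within the interval is not required.
    """
    pairs: set[tuple[str, str]] = set()
    eset = set(events)
    participants = {x for ab in eset for x in ab}
    for i, x in eset:
        for j in participants:
            if j == i or j == x:
                continue
            if (j, x) in eset or (x, j) in eset:
                pairs.add((i, j))
    return pairs


def build_support_dyads(
    intervals: list[dict],
    index: MembershipIndex,
    years: list[int] | None = None,
    pair_filter: PairFilter | None = None,
) -> pd.DataFrame:
    """Directed coalitionary-support dyad-year table from conflict intervals.

    count(i -> j) is the number of intervals in which i joined j;
    opportunities(i -> j) is the number of intervals in which j was a conflict
    participant and i was co-resident in that group at the interval start.
    """
    keep = pair_filter or (lambda a, b, t: True)
    rows: dict[tuple, list] = defaultdict(lambda: [0, 0])
    for iv in intervals:
        t = iv["start"]
        if years is not None and t.year not in years:
            continue
        residents = index.members_at(iv["group"], t)
        joins = score_joining(iv["events"])
        for j in iv["participants"]:
            for i in residents - {j}:
                if keep(i, j, t):
                    rows[(t.year, i, j)][1] += 1
                    if (i, j) in joins:
                        rows[(t.year, i, j)][0] += 1
    return _finish(rows, "support", directed=True)


def build_foraging_dyads(
    scans: pd.DataFrame,
    scan_neighbors: pd.DataFrame,
    index: MembershipIndex,
    years: list[int] | None = None,
    proximity_threshold: float = 5.0,
    window_minutes: float = 10.0,
    pair_filter: PairFilter | None = None,
) -> pd.DataFrame:
    """Undirected foraging-proximity dyad-year table from group scans.

    Only scans in a foraging context qualify. For each unordered dyad the
    qualifying scans (those whose subject is one of the pair, with the other
    co-resident) are thinned greedily from the earliest so retained scans are
    at least ``window_minutes`` apart; opportunities is the retained count and
    the count is the number of retained 10-min windows in which the dyad was
    scanned within ``proximity_threshold`` body lengths. A neighbor with a
    missing distance is treated as beyond the threshold.
    """
    keep = pair_filter or (lambda a, b, t: True)
    width = pd.Timedelta(minutes=window_minutes)

    n_missing = int(scan_neighbors["distance_bl"].isna().sum())
    if n_missing:
        logger.warning("%d scan neighbors with missing distance treated as far", n_missing)
    close_by_scan: dict[str, set[str]] = defaultdict(set)
    for nb in scan_neighbors.dropna(subset=["distance_bl"]).itertuples(index=False):
        if nb.distance_bl <= proximity_threshold:
            close_by_scan[nb.scan_id].add(nb.neighbor)

    # per-dyad chronological list of (time, in_proximity) qualifying scans
    dyad_scans: dict[tuple, list[tuple[pd.Timestamp, bool]]] = defaultdict(list)
    foraging = scans[scans["activity"] == "foraging"]
    foraging = foraging.sort_values("time", kind="mergesort")
    for sc in foraging.itertuples(index=False):
        if years is not None and sc.time.year not in years:
            continue
        others = index.members_at(sc.group, sc.time) - {sc.subject}
        close = close_by_scan.get(sc.scan_id, set())
        for j in others:
            a, b = sorted((sc.subject, j))
            if keep(a, b, sc.time):
                dyad_scans[(sc.time.year, a, b)].append((sc.time, j in close))

    rows: dict[tuple, list] = {}
    for key, entries in dyad_scans.items():
        retained: list[pd.Timestamp] = []
        for t, _ in entries:
            if not retained or t - retained[-1] >= width:
                retained.append(t)
        count = 0
        for t0 in retained:
            hit = any(close for t, close in entries if t0 <= t < t0 + width)
            count += hit
        rows[key] = [count, len(retained)]
    return _finish(rows, "foraging", directed=False)


def build_partner_dataset(
    bundle,
    behavior: str,
    partner_type: str = "all",
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Build one behavior x partner-type dyad-year table from raw events.

    The partner restriction is applied at the event/opportunity level (the
    table is rebuilt from the filtered event base, not by subsetting rows of
    a previously aggregated table). Subjects are always adult females.
    """
    index = MembershipIndex(bundle.membership)
    directed = behavior != "foraging"
    pf = make_partner_filter(bundle.individuals, partner_type, directed)
    if behavior == "grooming":
        df = build_grooming_dyads(bundle.follows, bundle.grooming, index, years, pf)
    elif behavior == "support":
        intervals = segment_aggression_intervals(bundle.aggression)
        df = build_support_dyads(intervals, index, years, pf)
    elif behavior == "foraging":
        df = build_foraging_dyads(bundle.scans, bundle.scan_neighbors, index, years, pair_filter=pf)
    else:
        raise ValueError(f"unknown behavior: {behavior}")
    if df.empty:
        logger.warning("empty dyad table for %s/%s", behavior, partner_type)
    return df
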