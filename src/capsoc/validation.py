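"""Brute-force reference implementations of the dyad-scoring rules.

These functions restate each aggregation rule in the most literal way
possible — scanning the membership table per query, enumerating every ordered
pair, and re-deriving every denominator from scratch — with no code shared
with :mod:`capsoc.interactions`. They are quadratic and meant only for
validating the production builders on small event streams; equality of the
two routes on random toy data is part of the test suite.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .interactions import DYAD_COLUMNS


def _same_group(membership: pd.DataFrame, i: str, j: str, t: pd.Timestamp) -> bool:
    gi = [
        r.group
        for r in membership.itertuples(index=False)
        if r.id == i and r.entry <= t <= r.exit
    ]
    gj = [
        r.group
        for r in membership.itertuples(index=False)
        if r.id == j and r.entry <= t <= r.exit
    ]
    return bool(gi) and bool(gj) and gi[0] == gj[0]


def _to_frame(rows: dict, behavior: str) -> pd.DataFrame:
    recs = [
        dict(year=y, behavior=behavior, actor=a, partner=b, count=c, opportunities=n)
        for (y, a, b), (c, n) in rows.items()
        if n > 0
    ]
    df = pd.DataFrame(recs, columns=DYAD_COLUMNS)
    return df.sort_values(["year", "actor", "partner"], kind="mergesort").reset_index(drop=True)


def naive_grooming(
    follows: pd.DataFrame,
    grooming: pd.DataFrame,
    membership: pd.DataFrame,
    individuals: pd.DataFrame,
    pair_keep=None,
) -> pd.DataFrame:
    keep = pair_keep or (lambda a, b, t: True)
    ids = list(individuals["id"])
    rows = defaultdict(lambda: [0, 0])
    for i in ids:
        for j in ids:
            if i == j:
                continue
            for f in follows.itertuples(index=False):
                if f.focal not in (i, j):
                    continue
                if not _same_group(membership, i, j, f.start):
                    continue
                if not keep(i, j, f.start):
                    continue
                rows[(f.start.year, i, j)][1] += 1
                groomed = any(
                    ev.follow_id == f.follow_id
                    and ev.groomer == i
                    and ev.groomee == j
                    for ev in grooming.itertuples(index=False)
                )
                rows[(f.start.year, i, j)][0] += int(groomed)
    return _to_frame(rows, "grooming")


def naive_intervals(aggression: pd.DataFrame, minutes: float = 5.0) -> list[dict]:
    out = []
    for group in sorted(set(aggression["group"])):
        evs = sorted(
            [
                (r.time, r.aggressor, r.target)
                for r in aggression.itertuples(index=False)
                if r.group == group
            ]
        )
        while evs:
            anchor = evs[0][0]
            inside = [e for e in evs if (e[0] - anchor) < pd.Timedelta(minutes=minutes)]
            evs = evs[len(inside):]
            out.append(
                dict(
                    group=group,
                    start=anchor,
                    events=[(a, t) for _, a, t in inside],
                    participants={x for _, a, t in inside for x in (a, t)},
                )
            )
    out.sort(key=lambda iv: (iv["start"], iv["group"]))
    return out


def naive_joining(events: list[tuple[str, str]]) -> set[tuple[str, str]]:
    pairs = set()
    participants = {x for ab in events for x in ab}
    for i in participants:
        for j in participants:
            if i == j:
                continue
            for a1, x in events:
                if a1 != i or x == j:
                    continue
                if (j, x) in set(events) or (x, j) in set(events):
                    pairs.add((i, j))
    return pairs


def naive_support(
    aggression: pd.DataFrame,
    membership: pd.DataFrame,
    individuals: pd.DataFrame,
    pair_keep=None,
) -> pd.DataFrame:
    keep = pair_keep or (lambda a, b, t: True)
    ids = list(individuals["id"])
    rows = defaultdict(lambda: [0, 0])
    for iv in naive_intervals(aggression):
        joins = naive_joining(iv["events"])
        for j in sorted(iv["participants"]):
            for i in ids:
                if i == j:
                    continue
                # the opportunity to join requires residence in the group
                # where the conflict took place
                resident = [
                    r.group
                    for r in membership.itertuples(index=False)
                    if r.id == i and r.entry <= iv["start"] <= r.exit
                ]
                if not resident or resident[0] != iv["group"]:
                    continue
                if not keep(i, j, iv["start"]):
                    continue
                rows[(iv["start"].year, i, j)][1] += 1
                rows[(iv["start"].year, i, j)][0] += int((i, j) in joins)
    return _to_frame(rows, "support")


def naive_foraging(
    scans: pd.DataFrame,
    scan_neighbors: pd.DataFrame,
    membership: pd.DataFrame,
    individuals: pd.DataFrame,
    threshold: float = 5.0,
    window_min: float = 10.0,
    pair_keep=None,
) -> pd.DataFrame:
    keep = pair_keep or (lambda a, b, t: True)
    ids = sorted(individuals["id"])
    width = pd.Timedelta(minutes=window_min)
    rows = defaultdict(lambda: [0, 0])
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            i, j = ids[ai], ids[bi]
            qual = []
            for sc in scans.sort_values("time").itertuples(index=False):
                if sc.activity != "foraging" or sc.subject not in (i, j):
                    continue
                if not _same_group(membership, i, j, sc.time):
                    continue
                if not keep(i, j, sc.time):
                    continue
                other = j if sc.subject == i else i
                close = any(
                    nb.scan_id == sc.scan_id
                    and nb.neighbor == other
                    and pd.notna(nb.distance_bl)
                    and nb.distance_bl <= threshold
                    for nb in scan_neighbors.itertuples(index=False)
                )
                qual.append((sc.time, close))
            # annual aggregation: thinning restarts at each calendar year
            for year in sorted({t.year for t, _ in qual}):
                year_qual = [(t, c) for t, c in qual if t.year == year]
                retained = []
                for t, _ in year_qual:
                    if not retained or t - retained[-1] >= width:
                        retained.append(t)
                cnt = sum(
                    any(c for t, c in year_qual if t0 <= t < t0 + width)
                    for t0 in retained
                )
                rows[(year, i, j)] = [cnt, len(retained)]
    return _to_frame(rows, "foraging")


def random_toy_stream(rng: np.random.Generator, n_individuals: int = 8):
    """A small random event stream for oracle-equivalence checks.

    Up to ``n_individuals`` individuals in two groups, with one mid-year
    group transfer and a mix of adults and immatures; returns the dict of
    input DataFrames the builders consume. Timestamps span two calendar
    years so annual aggregation is exercised.
    """
    n = int(rng.integers(4, n_individuals + 1))
    ids = [f"X{i}" for i in range(n)]
    sexes = rng.choice(["F", "M"], size=n)
    sexes[0] = "F"  # at least one female subject
    year0 = 2010
    births = [
        pd.Timestamp(year0 - int(a), 1, 1) + pd.Timedelta(days=int(rng.integers(0, 364)))
        for a in rng.integers(1, 20, size=n)
    ]
    start = pd.Timestamp(year0, 1, 1)
    end = pd.Timestamp(year0 + 1, 12, 31)
    individuals = pd.DataFrame({"id": ids, "sex": sexes, "birth_date": births})

    mem_rows = []
    for i, iid in enumerate(ids):
        group = "A" if i < n // 2 + 1 else "B"
        if i == 1 and n > 4:  # one transfer mid-study
            mid = start + pd.Timedelta(days=int(rng.integers(100, 500)))
            mem_rows.append(dict(id=iid, group=group, entry=start, exit=mid))
            mem_rows.append(dict(id=iid, group="B" if group == "A" else "A",
                                 entry=mid + pd.Timedelta(days=1), exit=end))
        else:
            mem_rows.append(dict(id=iid, group=group, entry=start, exit=end))
    membership = pd.DataFrame(mem_rows)

    def t_rand():
        return start + pd.Timedelta(minutes=int(rng.integers(0, 2 * 364 * 24 * 60)))

    n_follows = int(rng.integers(8, 25))
    follows = pd.DataFrame(
        [
            dict(follow_id=f"f{k}", focal=str(rng.choice(ids)), group="",
                 start=t_rand(), duration_min=10)
            for k in range(n_follows)
        ]
    )
    # attach the focal's group at follow time (builders trust this column)
    groups = []
    for f in follows.itertuples(index=False):
        g = [
            r.group for r in membership.itertuples(index=False)
            if r.id == f.focal and r.entry <= f.start <= r.exit
        ]
        groups.append(g[0] if g else "A")
    follows["group"] = groups

    groom_rows = []
    for _ in range(int(rng.integers(5, 20))):
        f = follows.iloc[int(rng.integers(0, len(follows)))]
        a, b = rng.choice(ids, size=2, replace=False)
        groom_rows.append(
            dict(follow_id=f.follow_id, groomer=a, groomee=b,
                 time=f.start + pd.Timedelta(minutes=int(rng.integers(0, 10))))
        )
    # a couple of events with unknown follow ids must be skipped by builders
    for _ in range(2):
        a, b = rng.choice(ids, size=2, replace=False)
        groom_rows.append(dict(follow_id="orphan", groomer=a, groomee=b, time=t_rand()))
    grooming = pd.DataFrame(groom_rows)

    agg_rows = []
    t = start
    for _ in range(int(rng.integers(5, 18))):
        t = t + pd.Timedelta(minutes=int(rng.integers(1, 3000)))
        a, b = rng.choice(ids, size=2, replace=False)
        g = [
            r.group for r in membership.itertuples(index=False)
            if r.id == a and r.entry <= t <= r.exit
        ]
        agg_rows.append(dict(time=t, group=g[0] if g else "A", aggressor=a, target=b))
    aggression = pd.DataFrame(agg_rows)

    scan_rows, nb_rows = [], []
    t = start
    for k in range(int(rng.integers(8, 25))):
        t = t + pd.Timedelta(minutes=int(rng.integers(2, 2000)))
        subj = str(rng.choice(ids))
        g = [
            r.group for r in membership.itertuples(index=False)
            if r.id == subj and r.entry <= t <= r.exit
        ]
        activity = "foraging" if rng.random() < 0.7 else "other"
        scan_rows.append(dict(scan_id=f"s{k}", time=t, group=g[0] if g else "A",
                              subject=subj, activity=activity))
        for other in ids:
            if other != subj and rng.random() < 0.4:
                dist = float(rng.uniform(0.5, 10.0))
                if rng.random() < 0.1:
                    dist = np.nan  # missing distance -> treated as far
                nb_rows.append(dict(scan_id=f"s{k}", neighbor=other, distance_bl=dist))
    scans = pd.DataFrame(scan_rows)
    scan_neighbors = pd.DataFrame(nb_rows, columns=["scan_id", "neighbor", "distance_bl"])

    return dict(
        individuals=individuals, membership=membership, follows=follows,
        grooming=grooming, aggression=aggression, scans=scans,
        scan_neighbors=scan_neighbors,
    )


def builders_match_oracles(stream: dict, check_filtered: bool = True) -> bool:
    """Run every production builder and its naive oracle on one stream and
    compare the tables exactly. Raises AssertionError on mismatch."""
    from .interactions import (
        MembershipIndex,
        build_foraging_dyads,
        build_grooming_dyads,
        build_support_dyads,
        make_partner_filter,
        segment_aggression_intervals,
    )

    index = MembershipIndex(stream["membership"])
    filters = [None]
    if check_filtered:
        filters.append(make_partner_filter(stream["individuals"], "adult_females", True))
    for pf in filters:
        got = build_grooming_dyads(stream["follows"], stream["grooming"], index, pair_filter=pf)
        want = naive_grooming(
            stream["follows"], stream["grooming"], stream["membership"],
            stream["individuals"], pair_keep=pf,
        )
        if not got.equals(want):
            raise AssertionError("grooming builder disagrees with oracle")
        intervals = segment_aggression_intervals(stream["aggression"])
        got = build_support_dyads(intervals, index, pair_filter=pf)
        want = naive_support(
            stream["aggression"], stream["membership"], stream["individuals"], pair_keep=pf
        )
        if not got.equals(want):
            raise AssertionError("support builder disagrees with oracle")
        got = build_foraging_dyads(
            stream["scans"], stream["scan_neighbors"], index, pair_filter=pf
        )
        want = naive_foraging(
            stream["scans"], stream["scan_neighbors"], stream["membership"],
            stream["individuals"], pair_keep=pf,
        )
        if not got.equals(want):
            raise AssertionError("foraging builder disagrees with oracle")
    return True
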