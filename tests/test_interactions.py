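"""Dyad builders: spec'd toy examples, invariants, and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from capsoc.interactions import (
    MembershipIndex,
    build_foraging_dyads,
    build_grooming_dyads,
    build_partner_dataset,
    build_support_dyads,
    make_partner_filter,
    score_joining,
    segment_aggression_intervals,
)
from capsoc.io import EventBundle
from capsoc.validation import builders_match_oracles, random_toy_stream

from conftest import ts


def follows_df(rows):
    return pd.DataFrame(rows, columns=["follow_id", "focal", "group", "start", "duration_min"])


def grooming_df(rows):
    return pd.DataFrame(rows, columns=["follow_id", "groomer", "groomee", "time"])


class TestCoresidence:
    def test_before_partner_entry(self, toy_population):
        _, _, index = toy_population
        assert not index.coresident("F1", "M1", ts("2010-06-01"))

    def test_after_partner_entry(self, toy_population):
        _, _, index = toy_population
        assert index.coresident("F1", "M1", ts("2010-08-01"))

    def test_disjoint_groups(self):
        mem = pd.DataFrame(
            {"id": ["a", "b"], "group": ["A", "B"],
             "entry": [ts("2010-01-01")] * 2, "exit": [ts("2010-12-31")] * 2}
        )
        index = MembershipIndex(mem)
        assert not index.coresident("a", "b", ts("2010-06-01"))

    def test_unknown_id_raises(self, toy_population):
        _, _, index = toy_population
        with pytest.raises(KeyError):
            index.coresident("F1", "nobody", ts("2010-08-01"))


class TestGroomingBuilder:
    def _follows(self):
        rows = [(f"fi{k}", "F1", "A", ts("2010-03-01 10:00") + pd.Timedelta(days=k), 10)
                for k in range(3)]
        rows += [(f"fj{k}", "F2", "A", ts("2010-04-01 10:00") + pd.Timedelta(days=k), 10)
                 for k in range(2)]
        return follows_df(rows)

    def test_opportunities_sum_both_members_follows(self, toy_population):
        _, _, index = toy_population
        out = build_grooming_dyads(self._follows(), grooming_df([]), index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert (row["count"], row.opportunities) == (0, 5)

    def test_at_least_once_per_follow_collapses_repeats(self, toy_population):
        _, _, index = toy_population
        groom = grooming_df([
            ("fi0", "F1", "F2", ts("2010-03-01 10:02")),
            ("fi0", "F1", "F2", ts("2010-03-01 10:07")),  # same follow, collapses
            ("fj0", "F1", "F2", ts("2010-04-01 10:05")),
        ])
        out = build_grooming_dyads(self._follows(), groom, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert (row["count"], row.opportunities) == (2, 5)

    def test_never_coresident_dyad_absent(self, toy_population):
        _, _, index = toy_population
        fl = follows_df([("f0", "F1", "A", ts("2010-03-01 10:00"), 10)])
        out = build_grooming_dyads(fl, grooming_df([]), index)
        # M1 enters A only on 2010-07-01: no shared residence at follow time
        assert out[(out.actor == "F1") & (out.partner == "M1")].empty

    def test_orphan_event_skipped_with_warning(self, toy_population, caplog):
        _, _, index = toy_population
        groom = grooming_df([("missing", "F1", "F2", ts("2010-03-01 10:02"))])
        with caplog.at_level("WARNING", logger="capsoc.interactions"):
            out = build_grooming_dyads(self._follows(), groom, index)
        assert out["count"].sum() == 0
        assert any("skipped" in r.message for r in caplog.records)


class TestAggressionIntervals:
    def _agg(self, times):
        return pd.DataFrame(
            [dict(time=t, group="A", aggressor="F1", target="F2") for t in times]
        )

    def test_events_within_window_share_interval(self):
        iv = segment_aggression_intervals(self._agg([ts("2010-05-01 12:00"), ts("2010-05-01 12:03")]))
        assert len(iv) == 1

    def test_event_beyond_window_opens_new_interval(self):
        iv = segment_aggression_intervals(self._agg([ts("2010-05-01 12:00"), ts("2010-05-01 12:06")]))
        assert len(iv) == 2

    def test_burst_anchored_segmentation(self):
        times = [ts("2010-05-01 12:00"), ts("2010-05-01 12:04"), ts("2010-05-01 12:08")]
        iv = segment_aggression_intervals(self._agg(times))
        assert [len(x["events"]) for x in iv] == [2, 1]
        assert iv[1]["start"] == times[2]


class TestJoining:
    def test_attacking_same_target_joins(self):
        assert score_joining([("j", "x"), ("i", "x")]) == {("i", "j"), ("j", "i")}

    def test_dichotomous_per_interval(self):
        events = [("j", "x"), ("i", "x"), ("i", "x"), ("i", "x")]
        pairs = score_joining(events)
        assert ("i", "j") in pairs and len([p for p in pairs if p[0] == "i"]) == 1

    def test_two_party_conflict_has_no_joining(self):
        assert score_joining([("i", "j")]) == set()

    def test_attacking_j_opponent_joins_j(self):
        # x attacked j; i attacks x -> i joins j
        assert ("i", "j") in score_joining([("x", "j"), ("i", "x")])


class TestSupportBuilder:
    def test_counts_and_opportunities(self, toy_population):
        _, _, index = toy_population
        rows = []
        for k in range(10):
            t = ts("2011-02-01 08:00") + pd.Timedelta(hours=k)
            rows.append(dict(time=t, group="A", aggressor="F2", target="M1"))
            if k < 2:  # F1 joins F2 by attacking F2's victim
                rows.append(dict(time=t + pd.Timedelta(minutes=1), group="A",
                                 aggressor="F1", target="M1"))
        iv = segment_aggression_intervals(pd.DataFrame(rows))
        out = build_support_dyads(iv, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert (row["count"], row.opportunities) == (2, 10)

    def test_joining_both_roles_counts_once(self, toy_population):
        _, _, index = toy_population
        t = ts("2011-02-01 08:00")
        rows = [
            dict(time=t, group="A", aggressor="F2", target="M1"),
            dict(time=t + pd.Timedelta(minutes=1), group="A", aggressor="M1", target="F2"),
            dict(time=t + pd.Timedelta(minutes=2), group="A", aggressor="F1", target="M1"),
        ]
        iv = segment_aggression_intervals(pd.DataFrame(rows))
        out = build_support_dyads(iv, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert row["count"] == 1


class TestForagingBuilder:
    def _scan(self, k, t, subject="F1"):
        return dict(scan_id=f"s{k}", time=t, group="A", subject=subject, activity="foraging")

    def test_beyond_threshold_scores_zero(self, toy_population):
        _, _, index = toy_population
        scans = pd.DataFrame([self._scan(0, ts("2010-05-01 09:00"))])
        nb = pd.DataFrame([dict(scan_id="s0", neighbor="F2", distance_bl=6.0)])
        out = build_foraging_dyads(scans, nb, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert (row["count"], row.opportunities) == (0, 1)

    def test_within_threshold_scores_one(self, toy_population):
        _, _, index = toy_population
        scans = pd.DataFrame([self._scan(0, ts("2010-05-01 09:00"))])
        nb = pd.DataFrame([dict(scan_id="s0", neighbor="F2", distance_bl=4.0)])
        out = build_foraging_dyads(scans, nb, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert (row["count"], row.opportunities) == (1, 1)

    @pytest.mark.parametrize(
        "gap_minutes,expected_opp", [(4, 1), (11, 2)],
        ids=["within-window-thinned", "beyond-window-kept"],
    )
    def test_ten_minute_thinning(self, toy_population, gap_minutes, expected_opp):
        _, _, index = toy_population
        t0 = ts("2010-05-01 12:00")
        scans = pd.DataFrame([
            self._scan(0, t0),
            self._scan(1, t0 + pd.Timedelta(minutes=gap_minutes)),
        ])
        nb = pd.DataFrame(columns=["scan_id", "neighbor", "distance_bl"])
        out = build_foraging_dyads(scans, nb, index)
        row = out[(out.actor == "F1") & (out.partner == "F2")].iloc[0]
        assert row.opportunities == expected_opp

    def test_missing_distance_treated_as_far(self, toy_population):
        _, _, index = toy_population
        scans = pd.DataFrame([self._scan(0, ts("2010-05-01 09:00"))])
        nb = pd.DataFrame([dict(scan_id="s0", neighbor="F2", distance_bl=np.nan)])
        out = build_foraging_dyads(scans, nb, index)
        assert out.iloc[0]["count"] == 0


class TestPartnerDatasets:
    def test_adult_female_dataset_drops_immature_partners(self, toy_population):
        individuals, _, _ = toy_population
        keep = make_partner_filter(individuals, "adult_females", directed=True)
        t = ts("2010-06-01")
        assert keep("F1", "F2", t)
        assert not keep("F1", "Y1", t)  # Y1 is 2.9 years old
        assert not keep("F1", "M1", t)

    def test_all_dataset_keeps_immature_partners(self, toy_population):
        individuals, _, _ = toy_population
        keep = make_partner_filter(individuals, "all", directed=True)
        assert keep("F1", "Y1", ts("2010-06-01"))
        # but a pair with no adult female subject is excluded
        assert not keep("M1", "Y1", ts("2010-06-01"))

    def test_female_becomes_subject_at_adulthood(self, toy_population):
        individuals, _, _ = toy_population
        keep = make_partner_filter(individuals, "adult_males", directed=True)
        # Y1 born 2007-07-01: not yet a subject in 2011, a subject in 2013
        assert not keep("Y1", "M1", ts("2011-06-01"))
        assert keep("Y1", "M1", ts("2013-06-01"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_builders_match_naive_reimplementation(self, seed):
        stream = random_toy_stream(np.random.default_rng(seed))
        assert builders_match_oracles(stream)

    def test_builders_deterministic(self):
        stream = random_toy_stream(np.random.default_rng(99))
        index = MembershipIndex(stream["membership"])
        a = build_grooming_dyads(stream["follows"], stream["grooming"], index)
        b = build_grooming_dyads(stream["follows"], stream["grooming"], index)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_invariants_on_random_streams(self):
        stream = random_toy_stream(np.random.default_rng(7))
        bundle = EventBundle(covariates=pd.DataFrame(), demography=pd.DataFrame(), **stream)
        for behavior in ["grooming", "support", "foraging"]:
            df = build_partner_dataset(bundle, behavior, "all")
            assert (df["count"] <= df["opportunities"]).all()
            assert (df["opportunities"] > 0).all()
            if behavior == "foraging":
                pairs = df.apply(lambda r: (r.year, r.actor, r.partner), axis=1)
                rev = df.apply(lambda r: (r.year, r.partner, r.actor), axis=1)
                assert not set(pairs) & set(rev)
                assert (df["actor"] < df["partner"]).all()
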