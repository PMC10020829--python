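"""Devoted days, participant categories, paired-week differencing."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bioblitz import engagement
from conftest import project_row


ANCHOR = pd.Timestamp("2019-02-23")  # a Saturday


def days_after(anchor, offsets):
    return [pd.Timestamp(anchor) + pd.Timedelta(days=int(d)) for d in offsets]


class TestWeeklyDevotedDays:
    def test_three_distinct_days_in_week_one(self):
        dd = engagement.weekly_devoted_days(days_after(ANCHOR, [1, 3, 5]), ANCHOR)
        table = dd.set_index("week_index")["devoted_days"]
        assert table[1] == 3
        assert table.drop(1).eq(0).all()

    def test_same_day_counted_once(self):
        dd = engagement.weekly_devoted_days(days_after(ANCHOR, [2, 2, 2]), ANCHOR)
        assert dd.set_index("week_index")["devoted_days"][1] == 1

    def test_no_events_all_zero(self):
        dd = engagement.weekly_devoted_days([], ANCHOR, horizon_weeks=10)
        assert len(dd) == 20
        assert dd["devoted_days"].eq(0).all()

    def test_matches_brute_force_calendar_count(self):
        """Counts equal an explicit per-block scan over random date sets."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            offsets = rng.integers(-500, 500, size=rng.integers(1, 60))
            dates = {ANCHOR + pd.Timedelta(days=int(d)) for d in offsets}
            dd = engagement.weekly_devoted_days(sorted(dates), ANCHOR, horizon_weeks=52)
            got = dd.set_index("week_index")["devoted_days"]
            for w in range(1, 53):
                lo = ANCHOR + pd.Timedelta(days=1 + 7 * (w - 1))
                hi = ANCHOR + pd.Timedelta(days=7 * w)
                expect = sum(lo <= d <= hi for d in dates)
                assert got[w] == expect
                lo_p, hi_p = lo - pd.Timedelta(days=364), hi - pd.Timedelta(days=364)
                expect_pre = sum(lo_p <= d <= hi_p for d in dates)
                assert got[-w] == expect_pre

    @given(st.lists(st.integers(min_value=-400, max_value=400), min_size=1, max_size=80))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_devoted_days_bounded(self, offsets):
        dd = engagement.weekly_devoted_days(days_after(ANCHOR, offsets), ANCHOR)
        assert dd["devoted_days"].between(0, 7).all()


class TestCategorize:
    PROJECT = project_row()  # 2019-02-22 .. 2019-02-23

    def test_only_during(self):
        cat = engagement.categorize([pd.Timestamp("2019-02-22")], self.PROJECT)
        assert cat == "only_during"

    def test_continuing_veteran(self):
        dates = [pd.Timestamp("2019-02-12"), pd.Timestamp("2019-02-22"),
                 pd.Timestamp("2019-03-05")]
        assert engagement.categorize(dates, self.PROJECT) == "continuing_veteran"

    def test_lapsed(self):
        dates = [pd.Timestamp("2018-11-01"), pd.Timestamp("2019-02-22")]
        assert engagement.categorize(dates, self.PROJECT) == "lapsed"

    def test_continuing_new(self):
        dates = [pd.Timestamp("2019-02-23"), pd.Timestamp("2019-08-01")]
        assert engagement.categorize(dates, self.PROJECT) == "continuing_new"

    def test_activity_outside_year_window_ignored(self):
        dates = [pd.Timestamp("2016-01-01"), pd.Timestamp("2019-02-22")]
        assert engagement.categorize(dates, self.PROJECT) == "only_during"

    def test_non_participant_raises(self):
        with pytest.raises(engagement.ParticipationError):
            engagement.categorize([pd.Timestamp("2019-06-01")], self.PROJECT)


class TestPairedDifferences:
    PROJECT = project_row()

    def test_identical_years_give_zero(self):
        base = pd.Timestamp("2019-02-24")
        post = [base + pd.Timedelta(days=7 * w) for w in range(0, 50)]
        pre = [d - pd.Timedelta(days=364) for d in post]
        out = engagement.paired_differences(post + pre, self.PROJECT)
        assert out["diff"].eq(0).all()

    def test_maximum_difference_attained(self):
        post_week1 = days_after(pd.Timestamp("2019-02-23"), [1, 2, 3, 4, 5, 6, 7])
        out = engagement.paired_differences(
            post_week1 + [pd.Timestamp("2019-02-22")], self.PROJECT)
        got = out.set_index("week_after")["diff"]
        assert got[1] == 7
        assert got.drop(1).eq(0).all()

    def test_event_days_excluded(self):
        """Records during the event do not leak into either block."""
        out = engagement.paired_differences(
            [pd.Timestamp("2019-02-22"), pd.Timestamp("2019-02-23")], self.PROJECT)
        assert out["diff"].eq(0).all()

    def test_known_boost_schedule(self):
        """Hand-constructed activity: k distinct post days in week k for
        k=1..4, empty paired weeks, gives diffs (1,2,3,4,0,...)."""
        end = pd.Timestamp("2019-02-23")
        dates = []
        for week, k in [(1, 1), (2, 2), (3, 3), (4, 4)]:
            start = end + pd.Timedelta(days=1 + 7 * (week - 1))
            dates += [start + pd.Timedelta(days=i) for i in range(k)]
        got = engagement.paired_differences(dates, self.PROJECT).set_index("week_after")["diff"]
        assert [got[w] for w in (1, 2, 3, 4, 5)] == [1, 2, 3, 4, 0]

    def test_insufficient_span_reported_missing_not_zero(self):
        out = engagement.paired_differences(
            [pd.Timestamp("2019-03-01")], self.PROJECT,
            log_end=pd.Timestamp("2019-06-01"))
        assert out["week_after"].max() < 50
        full = engagement.paired_differences([pd.Timestamp("2019-03-01")], self.PROJECT)
        assert list(full["week_after"]) == list(range(1, 51))

    def test_weekday_alignment(self):
        """Week t and its paired week start on the same weekday."""
        end = pd.Timestamp(self.PROJECT["end"]).normalize()
        for t in (1, 17, 50):
            post_start = end + pd.Timedelta(days=1 + 7 * (t - 1))
            pre_start = post_start - pd.Timedelta(days=364)
            assert post_start.dayofweek == pre_start.dayofweek

    @given(st.lists(st.integers(min_value=-400, max_value=400), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_diff_bounded(self, offsets):
        dates = days_after(pd.Timestamp("2019-02-22"), offsets)
        out = engagement.paired_differences(dates, self.PROJECT)
        assert out["diff"].between(-7, 7).all()

    def test_shift_by_364_days_preserves_diffs(self):
        """Shifting the log and the event by exactly 364 days reproduces the
        same difference values."""
        rng = np.random.default_rng(11)
        offsets = rng.integers(-350, 350, size=40)
        dates = days_after(pd.Timestamp("2019-02-22"), offsets)
        base = engagement.paired_differences(dates, self.PROJECT)
        shifted_project = project_row(start="2020-02-21T09:00:00",
                                      end="2020-02-22T09:00:00")
        shifted = engagement.paired_differences(
            [d + pd.Timedelta(days=364) for d in dates], shifted_project)
        assert list(base["diff"]) == list(shifted["diff"])


class TestDifferencePanel:
    def test_agrees_with_per_user_differences(self, small_corpus):
        t = small_corpus
        panel, cats = engagement.difference_panel(t.observations, t.projects)
        assert panel["diff"].between(-7, 7).all()
        # spot-check three users against the single-user entry point
        by_user = t.observations.groupby("observer_id")["observed_date"]
        for user in panel["user_id"].drop_duplicates().head(3):
            row = cats[cats["user_id"] == user].iloc[0]
            proj = t.projects[t.projects["project_id"] == row["project_id"]].iloc[0]
            dates = by_user.get_group(user)
            expected = engagement.paired_differences(dates, proj)
            got = panel[panel["user_id"] == user].set_index("week_after")["diff"]
            assert list(got) == list(expected["diff"])

    def test_categories_match_single_user_categorize(self, small_corpus):
        t = small_corpus
        _, cats = engagement.difference_panel(t.observations, t.projects)
        by_user = t.observations.groupby("observer_id")["observed_date"]
        for _, row in cats.head(20).iterrows():
            proj = t.projects[t.projects["project_id"] == row["project_id"]].iloc[0]
            assert engagement.categorize(by_user.get_group(row["user_id"]), proj) \
                == row["category"]

    def test_panel_contains_only_continuing_users(self, small_corpus):
        t = small_corpus
        panel, cats = engagement.difference_panel(t.observations, t.projects)
        continuing = set(cats.loc[cats["category"].str.startswith("continuing"),
                                  "user_id"])
        assert set(panel["user_id"]) <= continuing
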