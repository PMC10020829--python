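"""Qualification, summaries, timing and word-frequency statistics."""

import numpy as np
import pandas as pd
import pytest

from bioblitz import projects
from conftest import project_row


def _obs(rows):
    return pd.DataFrame(rows, columns=["observation_id", "observer_id",
                                       "observed_date", "project_id", "taxon"])


def _ids(rows):
    return pd.DataFrame(rows, columns=["identification_id", "observation_id",
                                       "identifier_id"])


class TestQualify:
    def test_thresholds_met_exactly(self):
        obs = _obs([("O1", "U1", pd.Timestamp("2019-02-22"), "P1", "a"),
                    ("O2", "U2", pd.Timestamp("2019-02-22"), "P1", "b")])
        ids = _ids([("I1", "O1", "U9")])
        res = projects.qualify(project_row(), obs, ids)
        assert res.qualifies
        assert (res.n_observers, res.n_identifiers) == (2, 1)
        assert res.failed_criteria == []

    def test_single_observer_fails(self):
        obs = _obs([("O1", "U1", pd.Timestamp("2019-02-22"), "P1", "a")])
        ids = _ids([("I1", "O1", "U9")])
        res = projects.qualify(project_row(), obs, ids)
        assert not res.qualifies
        assert res.failed_criteria == ["min_observers"]

    def test_no_observations_fails_min_observers(self):
        res = projects.qualify(project_row(), _obs([]), _ids([]))
        assert not res.qualifies
        assert "min_observers" in res.failed_criteria

    def test_out_of_window_records_not_counted(self):
        obs = _obs([("O1", "U1", pd.Timestamp("2019-02-22"), "P1", "a"),
                    ("O2", "U2", pd.Timestamp("2019-06-01"), "P1", "b")])
        res = projects.qualify(project_row(), obs, _ids([]))
        assert res.n_observers == 1

    def test_matches_brute_force_on_random_corpus(self, small_corpus):
        """Qualified set equals an independent per-project recount."""
        t = small_corpus
        crit = projects.QualificationCriteria(min_observers=5, min_identifiers=2,
                                              max_duration_hours=72)
        got = projects.qualify_all(t.projects, t.observations, t.identifications, crit)
        for _, proj in t.projects.iterrows():
            mine = t.observations[
                (t.observations["project_id"] == proj["project_id"])
                & (t.observations["observed_date"] >= proj["start"].normalize())
                & (t.observations["observed_date"] <= proj["end"].normalize())]
            n_obsr = mine["observer_id"].nunique()
            n_idr = t.identifications[
                t.identifications["observation_id"].isin(mine["observation_id"])
            ]["identifier_id"].nunique()
            dur = (proj["end"] - proj["start"]).total_seconds() / 3600
            expect = n_obsr >= 5 and n_idr >= 2 and dur <= 72
            row = got[got["project_id"] == proj["project_id"]].iloc[0]
            assert bool(row["qualifies"]) == expect

    @pytest.mark.parametrize("tight,loose", [
        (dict(min_observers=5), dict(min_observers=2)),
        (dict(min_identifiers=3), dict(min_identifiers=0)),
        (dict(max_duration_hours=24), dict(max_duration_hours=336)),
    ])
    def test_relaxing_criteria_never_shrinks_qualified_set(self, small_corpus, tight, loose):
        t = small_corpus
        q_tight = projects.qualify_all(t.projects, t.observations, t.identifications,
                                       projects.QualificationCriteria(**tight))
        q_loose = projects.qualify_all(t.projects, t.observations, t.identifications,
                                       projects.QualificationCriteria(**loose))
        tight_set = set(q_tight.loc[q_tight["qualifies"], "project_id"])
        loose_set = set(q_loose.loc[q_loose["qualifies"], "project_id"])
        assert tight_set <= loose_set

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            projects.QualificationCriteria(min_observers=0)
        with pytest.raises(ValueError):
            projects.QualificationCriteria(max_duration_hours=0)


class TestSummarize:
    def test_counts(self):
        obs = _obs([("O1", "U1", pd.Timestamp("2019-02-22"), "P1", "a"),
                    ("O2", "U1", pd.Timestamp("2019-02-22"), "P1", "b"),
                    ("O3", "U1", pd.Timestamp("2019-02-22"), "P1", "b"),
                    ("O4", "U2", pd.Timestamp("2019-02-22"), "P1", "c"),
                    ("O5", "U2", pd.Timestamp("2019-02-22"), "P1", None)])
        s = projects.summarize_project(project_row(), obs, _ids([]))
        assert (s.n_observations, s.n_taxa, s.n_observers) == (5, 3, 2)
        assert s.start_weekday == "Friday"
        assert s.start_month == 2

    def test_all_taxa_missing(self):
        obs = _obs([("O1", "U1", pd.Timestamp("2019-02-22"), "P1", None)])
        assert projects.summarize_project(project_row(), obs, _ids([])).n_taxa == 0

    def test_matches_brute_force_recount(self, small_corpus):
        t = small_corpus
        got = projects.summarize_all(t.projects, t.observations, t.identifications)
        for _, row in got.iterrows():
            proj = t.projects[t.projects["project_id"] == row["project_id"]].iloc[0]
            mine = t.observations[
                (t.observations["project_id"] == proj["project_id"])
                & (t.observations["observed_date"] >= proj["start"].normalize())
                & (t.observations["observed_date"] <= proj["end"].normalize())]
            assert row["n_observations"] == len(mine)
            assert row["n_taxa"] == mine["taxon"].dropna().nunique()
            assert row["n_observers"] == mine["observer_id"].nunique()
            assert row["n_taxa"] <= row["n_observations"]

    def test_row_order_invariance(self, small_corpus):
        t = small_corpus
        shuffled = t.observations.sample(frac=1, random_state=0).reset_index(drop=True)
        a = projects.summarize_all(t.projects, t.observations, t.identifications)
        b = projects.summarize_all(t.projects, shuffled, t.identifications)
        pd.testing.assert_frame_equal(a, b)


class TestTimingHistograms:
    def test_all_saturday(self):
        projs = pd.DataFrame({
            "project_id": ["P1", "P2", "P3"],
            "start": pd.to_datetime(["2019-02-23", "2019-03-02", "2019-03-09"]),
        })
        weekday, month = projects.timing_histograms(projs)
        assert weekday["Saturday"] == 3
        assert weekday.sum() == 3 and month.sum() == 3

    def test_uniform_starts_binomially_balanced(self):
        """7000 uniform random start dates: each weekday within 5 SD of 1000."""
        rng = np.random.default_rng(0)
        starts = pd.Timestamp("2015-01-01") + pd.to_timedelta(
            rng.integers(0, 7 * 520, size=7000), unit="D")
        projs = pd.DataFrame({"project_id": range(7000), "start": starts})
        weekday, _ = projects.timing_histograms(projs)
        sd = np.sqrt(7000 * (1 / 7) * (6 / 7))
        assert (np.abs(weekday.to_numpy() - 1000) < 5 * sd).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            projects.timing_histograms(pd.DataFrame(columns=["start"]))


class TestWordFrequencies:
    def test_example(self):
        out = projects.word_frequencies(["BioBlitz fun", "fun for all"],
                                        stopwords={"for", "all"}, min_length=3)
        assert out.to_dict() == {"fun": 2, "bioblitz": 1}

    def test_empty(self):
        assert projects.word_frequencies([]).empty

    def test_known_token_multiset(self):
        """Counts equal the multiset used to build the corpus."""
        rng = np.random.default_rng(3)
        vocab = [f"word{i:02d}" for i in range(20)]
        multiset = {w: int(rng.integers(1, 9)) for w in vocab}
        tokens = [w for w, k in multiset.items() for _ in range(k)]
        rng.shuffle(tokens)
        docs = [" ".join(tokens[i::5]) for i in range(5)]
        out = projects.word_frequencies(docs, stopwords=frozenset(), min_length=1)
        assert out.to_dict() == multiset
        assert out.sum() == sum(multiset.values())
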