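"""Multi-rater scoring of bioblitz aims and inter-rater agreement.

Published bioblitz accounts are scored by raters on the importance (1 =
lowest, 5 = highest) of five common aims: creating a biodiversity inventory,
participant learning, discovering species new to an area, promoting an
organization, and public engagement.  This module tallies the score
distribution per aim and measures agreement between two raters with the
Jaccard similarity coefficient over (item, aim, score) triples — directly
interpretable as the fraction of scoring decisions the raters share.

Input is a long-format table: ``item_id, rater_id, aim, score``.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["AIMS", "validate_ratings", "rank_tally", "jaccard_agreement"]

AIMS = ("inventory", "learning", "new_species", "promotion", "public_engagement")
SCORES = (1, 2, 3, 4, 5)


def validate_ratings(ratings: pd.DataFrame, strict_permutation: bool = False) -> pd.DataFrame:
    """Check a long-format rating table.

    Every (item, rater) pair must score all five aims with integers in
    [1, 5].  With ``strict_permutation`` the five scores must additionally be
    a permutation of 1..5 (forced ranking).  Returns the table unchanged.
    """
    required = {"item_id", "rater_id", "aim", "score"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table missing columns: {sorted(missing)}")
    bad_aims = set(ratings["aim"]) - set(AIMS)
    if bad_aims:
        raise ValueError(f"unknown aims: {sorted(bad_aims)}")
    scores = ratings["score"]
    if not scores.isin(SCORES).all():
        raise ValueError("scores must be integers in [1, 5]")
    for (item, rater), grp in ratings.groupby(["item_id", "rater_id"]):
        aims = sorted(grp["aim"])
        if aims != sorted(AIMS):
            raise ValueError(f"({item}, {rater}) does not score all five aims exactly once")
        if strict_permutation and sorted(grp["score"]) != list(SCORES):
            raise ValueError(f"({item}, {rater}) scores are not a permutation of 1..5")
    return ratings


def rank_tally(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-aim counts of each score 1..5 over items.

    For items scored by several raters, the first-listed rater's scores are
    tallied (double scoring exists to measure agreement, not to average).
    Rows are aims, columns scores; each row sums to the number of items.
    """
    validate_ratings(ratings)
    first_rater = ratings.drop_duplicates("item_id")[["item_id", "rater_id"]]
    primary = ratings.merge(first_rater, on=["item_id", "rater_id"])
    tally = (primary.groupby(["aim", "score"]).size().unstack(fill_value=0)
             .reindex(index=list(AIMS), columns=list(SCORES), fill_value=0))
    tally.index.name = "aim"
    tally.columns.name = "score"
    return tally


def _triples(ratings: pd.DataFrame, rater: str, items: set) -> set[tuple]:
    sub = ratings[(ratings["rater_id"] == rater) & (ratings["item_id"].isin(items))]
    return set(zip(sub["item_id"], sub["aim"], sub["score"]))


def jaccard_agreement(ratings: pd.DataFrame, rater_a: str, rater_b: str,
                      mode: str = "exact_pairs") -> float:
    """Jaccard similarity J = |A∩B| / |A∪B| between two raters.

    In ``exact_pairs`` mode the compared elements are (item, aim, score)
    triples over the items both raters scored; J is the fraction of scoring
    decisions on which they agree exactly.  Raises if the raters share no
    items.
    """
    if mode != "exact_pairs":
        raise ValueError(f"unknown mode {mode!r}")
    items_a = set(ratings.loc[ratings["rater_id"] == rater_a, "item_id"])
    items_b = set(ratings.loc[ratings["rater_id"] == rater_b, "item_id"])
    common = items_a & items_b
    if not common:
        raise ValueError(f"raters {rater_a!r} and {rater_b!r} share no items")
    a = _triples(ratings, rater_a, common)
    b = _triples(ratings, rater_b, common)
    return len(a & b) / len(a | b)
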