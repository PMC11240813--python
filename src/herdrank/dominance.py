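"""Pairwise dominance tournaments: scheduling, scoring, classification.

Scoring rules for a bout between two pen-mates:

* decisive bout: winner +1, loser -0.5 on the Dominant tally; the
  Confirmed tally receives the same +1/-0.5 only when the win was
  confirmed in the second stage (otherwise 0 for both animals),
* draw: 0 for both animals on both tallies,
* inconclusive bout: no contribution and not counted in the means.

Per-animal means over counted bouts give ``dominant_mean`` and
``confirmed_mean``; the ranking score is ``dominant_mean / 2 +
confirmed_mean``.  Per pen of 8, the two highest-ranked animals are
dominant, the two lowest submissive, the middle four intermediate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_ORDER = {"submissive": 0, "intermediate": 1, "dominant": 2}

Schedule = list[tuple[int, list[tuple[str, str]]]]


def round_robin_schedule(animal_ids, pairs_per_day: int | None = None) -> Schedule:
    """Deterministic 1-factorization of the complete graph on the animals.

    Circle method: with ``n`` animals the schedule spans ``n - 1`` days of
    ``n / 2`` disjoint pairs, covering every unordered pair exactly once.

    Returns a list of ``(day_index, pairs)`` with 0-based day indices and
    pairs as sorted id tuples.
    """
    ids = list(animal_ids)
    n = len(ids)
    if n < 2 or n % 2 != 0:
        raise ValueError(f"need an even number (>= 2) of animals, got {n}")
    if pairs_per_day is not None and pairs_per_day != n // 2:
        raise ValueError(f"pairs_per_day must be n/2 = {n // 2}, got {pairs_per_day}")
    fixed, rest = ids[0], ids[1:]
    schedule: Schedule = []
    for day in range(n - 1):
        ring = rest[day:] + rest[:day]
        pairs = [tuple(sorted((fixed, ring[0])))]
        for k in range(1, n // 2):
            pairs.append(tuple(sorted((ring[k], ring[-k]))))
        schedule.append((day, pairs))
    return schedule


def score_bout(bout) -> dict[str, tuple[float, float]] | None:
    """Per-animal (dominant, confirmed) contributions of one bout.

    ``bout`` is a mapping with keys ``animal_a, animal_b, outcome,
    winner, confirmed``.  Returns ``None`` for inconclusive bouts (they
    are not counted); otherwise a dict animal_id -> (dom, conf).
    """
    a, b = bout["animal_a"], bout["animal_b"]
    if a == b:
        raise ValueError(f"bout pits animal {a!r} against itself")
    outcome = bout["outcome"]
    if outcome == "inconclusive":
        return None
    if outcome == "draw":
        return {a: (0.0, 0.0), b: (0.0, 0.0)}
    if outcome != "decisive":
        raise ValueError(f"unknown outcome {outcome!r}")
    winner = bout["winner"]
    if winner not in (a, b):
        raise ValueError(f"winner {winner!r} is not a participant of ({a}, {b})")
    loser = b if winner == a else a
    if bout.get("confirmed", False):
        return {winner: (1.0, 1.0), loser: (-0.5, -0.5)}
    return {winner: (1.0, 0.0), loser: (-0.5, 0.0)}


def ranking_scores(bouts: pd.DataFrame, phase: int | None = None) -> pd.DataFrame:
    """Per-animal Dominant/Confirmed means and ranking score.

    Animals that appear only in inconclusive bouts get NaN scores and
    ``n_bouts = 0`` (an explicit missing marker, never a silent zero).
    """
    df = bouts if phase is None else bouts[bouts["phase"] == phase]
    if df.empty:
        raise ValueError("no bouts to score")
    dom_sum: dict[str, float] = {}
    conf_sum: dict[str, float] = {}
    n_counted: dict[str, int] = {}
    for animal in pd.unique(df[["animal_a", "animal_b"]].values.ravel()):
        dom_sum[animal] = conf_sum[animal] = 0.0
        n_counted[animal] = 0
    for bout in df.to_dict("records"):
        contrib = score_bout(bout)
        if contrib is None:
            continue
        for animal, (d, c) in contrib.items():
            dom_sum[animal] += d
            conf_sum[animal] += c
            n_counted[animal] += 1
    rows = []
    for animal in sorted(dom_sum):
        n = n_counted[animal]
        if n == 0:
            dom_mean = conf_mean = score = np.nan
        else:
            dom_mean = dom_sum[animal] / n
            conf_mean = conf_sum[animal] / n
            score = dom_mean / 2.0 + conf_mean
        rows.append(
            {
                "animal_id": animal,
                "dominant_mean": dom_mean,
                "confirmed_mean": conf_mean,
                "ranking_score": score,
                "n_bouts": n,
            }
        )
    return pd.DataFrame(rows)


def classify_hierarchy(table: pd.DataFrame, pens: pd.Series) -> pd.DataFrame:
    """Assign dominant / intermediate / submissive classes per pen.

    ``pens`` maps animal_id -> pen_id.  Animals are ranked by
    ``ranking_score`` descending; ties break by higher ``confirmed_mean``,
    then higher ``dominant_mean``, then lexicographic animal_id, so the
    assignment is a pure function of the table contents.
    """
    missing = table.loc[table["ranking_score"].isna(), "animal_id"].tolist()
    if missing:
        raise ValueError(f"animals without a ranking score: {missing}")
    df = table.copy()
    df["pen_id"] = df["animal_id"].map(pens)
    if df["pen_id"].isna().any():
        lost = df.loc[df["pen_id"].isna(), "animal_id"].tolist()
        raise ValueError(f"animals without a pen assignment: {lost}")
    out = []
    for pen, grp in df.groupby("pen_id"):
        grp = grp.sort_values(
            by=["ranking_score", "confirmed_mean", "dominant_mean", "animal_id"],
            ascending=[False, False, False, True],
            kind="mergesort",
        )
        n = len(grp)
        if n < 5:
            raise ValueError(f"pen {pen!r} has {n} scored animals; need >= 5 for 2/4/2")
        classes = ["dominant"] * 2 + ["intermediate"] * (n - 4) + ["submissive"] * 2
        for (_, row), cls in zip(grp.iterrows(), classes):
            out.append(
                {
                    "animal_id": row["animal_id"],
                    "pen_id": pen,
                    "class": cls,
                    "ranking_score": row["ranking_score"],
                }
            )
    return pd.DataFrame(out).sort_values("animal_id", ignore_index=True)


def classify_change(before: str, after: str) -> str:
    """Better / Worse / Same for a class transition between phases."""
    for cls in (before, after):
        if cls not in CLASS_ORDER:
            raise ValueError(f"unknown hierarchy class {cls!r}")
    if CLASS_ORDER[after] > CLASS_ORDER[before]:
        return "Better"
    if CLASS_ORDER[after] < CLASS_ORDER[before]:
        return "Worse"
    return "Same"


def transition_table(
    assignments_from: pd.DataFrame, assignments_to: pd.DataFrame
) -> pd.DataFrame:
    """3x3 count matrix of class transitions between two phases.

    Rows are from-classes, columns to-classes (submissive, intermediate,
    dominant order).  Animals present in only one phase are excluded with
    a logged warning; disjoint animal sets raise.
    """
    a = assignments_from.set_index("animal_id")["class"]
    b = assignments_to.set_index("animal_id")["class"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two assignments share no animals")
    dropped = a.index.symmetric_difference(b.index)
    if len(dropped):
        logger.warning("excluding %d animals missing in one phase: %s",
                       len(dropped), sorted(dropped))
    order = ["submissive", "intermediate", "dominant"]
    mat = pd.DataFrame(0, index=pd.Index(order, name="from"), columns=pd.Index(order, name="to"))
    for animal in common:
        mat.loc[a.loc[animal], b.loc[animal]] += 1
    return mat


def change_labels(
    assignments_from: pd.DataFrame, assignments_to: pd.DataFrame
) -> pd.DataFrame:
    """Per-animal Better/Worse/Same labels for a phase pair."""
    a = assignments_from.set_index("animal_id")["class"]
    b = assignments_to.set_index("animal_id")["class"]
    common = a.index.intersection(b.index)
    rows = [
        {
            "animal_id": animal,
            "from_class": a.loc[animal],
            "to_class": b.loc[animal],
            "change": classify_change(a.loc[animal], b.loc[animal]),
        }
        for animal in sorted(common)
    ]
    return pd.DataFrame(rows)
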