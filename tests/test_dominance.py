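import itertools

import numpy as np
import pandas as pd
import pytest

from herdrank.config import CohortConfig
from herdrank.dominance import (
    change_labels,
    classify_change,
    classify_hierarchy,
    ranking_scores,
    round_robin_schedule,
    score_bout,
    transition_table,
)
from herdrank.simulate import generate_bouts, generate_cohort, true_hierarchy


class TestRoundRobinSchedule:
    def test_pen_of_eight(self):
        sched = round_robin_schedule([f"A{i}" for i in range(8)])
        assert len(sched) == 7
        all_pairs = set()
        for _, pairs in sched:
            assert len(pairs) == 4
            all_pairs.update(pairs)
        assert len(all_pairs) == 28

    def test_two_animals(self):
        sched = round_robin_schedule(["x", "y"])
        assert sched == [(0, [("x", "y")])]

    def test_four_animals_covers_all_pairs(self):
        ids = ["a", "b", "c", "d"]
        sched = round_robin_schedule(ids)
        assert len(sched) == 3
        seen = set(itertools.chain.from_iterable(p for _, p in sched))
        expected = {tuple(sorted(p)) for p in itertools.combinations(ids, 2)}
        assert seen == expected

    def test_odd_count_raises(self):
        with pytest.raises(ValueError):
            round_robin_schedule(["a", "b", "c"])

    def test_wrong_pairs_per_day_raises(self):
        with pytest.raises(ValueError):
            round_robin_schedule(list("abcd"), pairs_per_day=3)

    @pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
    def test_one_factorization_property(self, n):
        ids = [f"A{i}" for i in range(n)]
        sched = round_robin_schedule(ids)
        assert len(sched) == n - 1
        all_pairs = []
        for _, pairs in sched:
            day_animals = list(itertools.chain.from_iterable(pairs))
            assert len(day_animals) == len(set(day_animals)) == n
            all_pairs.extend(pairs)
        assert len(all_pairs) == len(set(all_pairs)) == n * (n - 1) // 2


class TestScoreBout:
    def test_confirmed_win(self, bout_factory):
        out = score_bout(bout_factory("A", "B", winner="A", confirmed=True))
        assert out == {"A": (1.0, 1.0), "B": (-0.5, -0.5)}

    def test_draw(self, bout_factory):
        out = score_bout(bout_factory("A", "B", outcome="draw"))
        assert out == {"A": (0.0, 0.0), "B": (0.0, 0.0)}

    def test_unconfirmed_win(self, bout_factory):
        out = score_bout(bout_factory("A", "B", winner="A", confirmed=False))
        assert out == {"A": (1.0, 0.0), "B": (-0.5, 0.0)}

    def test_inconclusive_not_counted(self, bout_factory):
        assert score_bout(bout_factory("A", "B", outcome="inconclusive")) is None

    def test_invalid_winner(self, bout_factory):
        with pytest.raises(ValueError):
            score_bout(bout_factory("A", "B", winner="C"))

    def test_self_bout_raises(self, bout_factory):
        with pytest.raises(ValueError):
            score_bout(bout_factory("A", "A", winner="A"))

    def test_decisive_net_contribution(self, bout_factory):
        # every decisive bout moves the pen's Dominant tally by +0.5 net
        out = score_bout(bout_factory("A", "B", winner="B", confirmed=True))
        assert sum(v[0] for v in out.values()) == pytest.approx(0.5)


class TestRankingScores:
    def test_all_confirmed_wins_is_maximum(self, bout_factory):
        bouts = pd.DataFrame(
            [bout_factory("A", f"B{i}", winner="A", confirmed=True) for i in range(7)]
        )
        table = ranking_scores(bouts).set_index("animal_id")
        assert table.loc["A", "dominant_mean"] == pytest.approx(1.0)
        assert table.loc["A", "confirmed_mean"] == pytest.approx(1.0)
        assert table.loc["A", "ranking_score"] == pytest.approx(1.5)

    def test_all_losses_is_minimum(self, bout_factory):
        bouts = pd.DataFrame(
            [bout_factory("A", f"B{i}", winner=f"B{i}", confirmed=True) for i in range(7)]
        )
        table = ranking_scores(bouts).set_index("animal_id")
        assert table.loc["A", "ranking_score"] == pytest.approx(-0.75)

    def test_hand_worked_mixed_week(self, bout_factory):
        # 3 confirmed wins, 2 unconfirmed wins, 1 loss of a confirmed bout,
        # 1 draw -> dominant mean 0.642857..., confirmed mean 0.357142...
        rows = [bout_factory("A", f"O{i}", winner="A", confirmed=True) for i in range(3)]
        rows += [bout_factory("A", f"O{i + 3}", winner="A", confirmed=False) for i in range(2)]
        rows += [bout_factory("A", "O5", winner="O5", confirmed=True)]
        rows += [bout_factory("A", "O6", outcome="draw")]
        table = ranking_scores(pd.DataFrame(rows)).set_index("animal_id")
        assert table.loc["A", "dominant_mean"] == pytest.approx(4.5 / 7, abs=1e-12)
        assert table.loc["A", "confirmed_mean"] == pytest.approx(2.5 / 7, abs=1e-12)
        assert table.loc["A", "ranking_score"] == pytest.approx(
            4.5 / 14 + 2.5 / 7, abs=1e-12
        )

    def test_inconclusive_excluded_from_denominator(self, bout_factory):
        rows = [
            bout_factory("A", "B", winner="A", confirmed=True),
            bout_factory("A", "C", outcome="inconclusive"),
        ]
        table = ranking_scores(pd.DataFrame(rows)).set_index("animal_id")
        assert table.loc["A", "dominant_mean"] == pytest.approx(1.0)
        assert table.loc["A", "n_bouts"] == 1
        # C only appeared in the inconclusive bout: explicit missing marker
        assert np.isnan(table.loc["C", "ranking_score"])
        assert table.loc["C", "n_bouts"] == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ranking_scores(pd.DataFrame(columns=["animal_a", "animal_b", "outcome"]))


class TestClassifyHierarchy:
    @staticmethod
    def _table(scores):
        return pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(len(scores))],
                "dominant_mean": scores,
                "confirmed_mean": scores,
                "ranking_score": scores,
            }
        )

    @staticmethod
    def _pens(n, pen="P1"):
        return pd.Series(pen, index=[f"A{i}" for i in range(n)])

    def test_distinct_scores_give_2_4_2(self):
        table = self._table([0.9, 0.7, 0.5, 0.3, 0.1, -0.1, -0.3, -0.5])
        out = classify_hierarchy(table, self._pens(8)).set_index("animal_id")["class"]
        assert list(out.loc[["A0", "A1"]]) == ["dominant"] * 2
        assert list(out.loc[["A6", "A7"]]) == ["submissive"] * 2
        assert (out.loc[["A2", "A3", "A4", "A5"]] == "intermediate").all()

    def test_full_tie_deterministic(self):
        table = self._table([0.5] * 8)
        out1 = classify_hierarchy(table, self._pens(8))
        out2 = classify_hierarchy(table.sample(frac=1, random_state=3), self._pens(8))
        pd.testing.assert_frame_equal(out1, out2)
        assert out1["class"].value_counts().to_dict() == {
            "intermediate": 4, "dominant": 2, "submissive": 2,
        }

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = self._table(list(rng.normal(size=8)))
        base = classify_hierarchy(table, self._pens(8))
        shuffled = classify_hierarchy(
            table.sample(frac=1, random_state=11), self._pens(8)
        )
        pd.testing.assert_frame_equal(base, shuffled)

    def test_eight_pens_totals(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        bouts = generate_bouts(cohort, 1, seed=3)
        table = ranking_scores(bouts, 1)
        out = classify_hierarchy(table, cohort.pens_in_phase(1))
        assert out["class"].value_counts().to_dict() == {
            "intermediate": 32, "dominant": 16, "submissive": 16,
        }

    def test_missing_scores_error_names_animals(self):
        table = self._table([0.5] * 8)
        table.loc[3, ["dominant_mean", "confirmed_mean", "ranking_score"]] = np.nan
        with pytest.raises(ValueError, match="A3"):
            classify_hierarchy(table, self._pens(8))

    def test_unknown_pen_raises(self):
        table = self._table([0.1] * 8)
        with pytest.raises(ValueError):
            classify_hierarchy(table, pd.Series({"A0": "P1"}))


class TestClassifyChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [
            ("submissive", "dominant", "Better"),
            ("submissive", "intermediate", "Better"),
            ("intermediate", "dominant", "Better"),
            ("dominant", "dominant", "Same"),
            ("intermediate", "submissive", "Worse"),
            ("dominant", "intermediate", "Worse"),
        ],
    )
    def test_ordering(self, before, after, expected):
        assert classify_change(before, after) == expected

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            classify_change("alpha", "dominant")


class TestTransitionTable:
    @staticmethod
    def _assign(classes):
        return pd.DataFrame(
            {"animal_id": [f"A{i}" for i in range(len(classes))], "class": classes}
        )

    def test_identical_assignments_diagonal(self):
        a = self._assign(["dominant"] * 2 + ["intermediate"] * 4 + ["submissive"] * 2)
        mat = transition_table(a, a)
        assert np.trace(mat.to_numpy()) == 8
        assert mat.to_numpy().sum() == 8

    def test_row_sums_match_source_sizes(self):
        cohort = generate_cohort(CohortConfig(seed=3))
        assigns = {}
        for phase in (1, 2):
            bouts = generate_bouts(cohort, phase, seed=3)
            assigns[phase] = classify_hierarchy(
                ranking_scores(bouts, phase), cohort.pens_in_phase(phase)
            )
        mat = transition_table(assigns[1], assigns[2])
        assert mat.sum(axis=1).to_dict() == {
            "submissive": 16, "intermediate": 32, "dominant": 16,
        }

    def test_random_permutation_matches_brute_force(self, rng):
        classes = ["dominant", "intermediate", "submissive"]
        before = self._assign(list(rng.choice(classes, size=30)))
        after = self._assign(list(rng.choice(classes, size=30)))
        mat = transition_table(before, after)
        for frm in classes:
            for to in classes:
                expected = sum(
                    1
                    for b, a in zip(before["class"], after["class"])
                    if b == frm and a == to
                )
                assert mat.loc[frm, to] == expected

    def test_disjoint_sets_raise(self):
        a = self._assign(["dominant"] * 3)
        b = self._assign(["dominant"] * 3)
        b["animal_id"] = ["Z1", "Z2", "Z3"]
        with pytest.raises(ValueError):
            transition_table(a, b)

    def test_partial_overlap_warns_and_excludes(self, caplog):
        a = self._assign(["dominant", "submissive", "intermediate"])
        b = self._assign(["dominant", "submissive", "intermediate"])
        b.loc[2, "animal_id"] = "Zx"
        with caplog.at_level("WARNING"):
            mat = transition_table(a, b)
        assert mat.to_numpy().sum() == 2

    def test_change_labels(self):
        a = self._assign(["dominant", "submissive"])
        b = self._assign(["submissive", "dominant"])
        out = change_labels(a, b).set_index("animal_id")["change"]
        assert out.loc["A0"] == "Worse" and out.loc["A1"] == "Better"


class TestSimulationRecovery:
    def test_monotone_in_latent_ability(self):
        """Raising one animal's ability never lowers its expected score."""
        cfg = CohortConfig(seed=11)
        means = []
        for bump in (0.0, 2.0):
            cohort = generate_cohort(cfg)
            cohort.animals.loc[0, "latent_ability"] = (
                cohort.animals["latent_ability"].median() + bump
            )
            target = cohort.animals.loc[0, "animal_id"]
            scores = []
            for rep in range(40):
                bouts = generate_bouts(cohort, 1, seed=100 + rep)
                table = ranking_scores(bouts, 1).set_index("animal_id")
                scores.append(table.loc[target, "ranking_score"])
            means.append(np.mean(scores))
        assert means[1] > means[0]

    def test_extreme_gaps_recover_true_order(self):
        """With no draws and huge ability gaps, classification recovers the
        latent top-2/bottom-2 in >= 95% of pens."""
        hits = total = 0
        for seed in range(3):
            cohort = generate_cohort(CohortConfig(seed=seed))
            spread = {
                pen: dict(zip(grp.sort_values("latent_ability")["animal_id"],
                              np.arange(len(grp)) * 10.0))
                for pen, grp in cohort.animals.groupby("pen_id")
            }
            cohort.animals["latent_ability"] = [
                spread[p][a] for p, a in zip(cohort.animals["pen_id"], cohort.animals["animal_id"])
            ]
            bouts = generate_bouts(
                cohort, 1, p_draw=0, p_inconclusive=0, p_confirm=1.0, seed=seed
            )
            assign = classify_hierarchy(
                ranking_scores(bouts, 1), cohort.pens_in_phase(1)
            )
            truth = true_hierarchy(cohort, 1)
            merged = assign.merge(truth, on="animal_id", suffixes=("", "_true"))
            for _, grp in merged.groupby("pen_id"):
                total += 1
                if (grp["class"] == grp["class_true"]).all():
                    hits += 1
        assert hits / total >= 0.95
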