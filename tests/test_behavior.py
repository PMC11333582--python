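"""Behavioral scoring: tube ranks, stability, inflection, proportions,
competitive order, latency criterion, warm spot, rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comprank import behavior as bh
from comprank.series import LongSeries
from conftest import make_bouts

MICE = ["A", "B", "C", "D"]
PAIRS = list(itertools.combinations(MICE, 2))


def tournament(bits):
    """Outcome table from 6 bits: bit=0 -> first of pair wins."""
    return {p: (p[0] if b == 0 else p[1]) for p, b in zip(PAIRS, bits)}


def oracle_ranks(outcomes):
    """Independent re-statement of the declared ranking rule."""
    wins = {m: 0 for m in MICE}
    for (a, b), w in outcomes.items():
        wins[w] += 1
    order = []
    for _, grp in itertools.groupby(
        sorted(MICE, key=lambda m: (-wins[m], m)), key=lambda m: wins[m]
    ):
        grp = list(grp)
        if len(grp) == 2:
            a, b = grp
            head_to_head = outcomes.get((a, b), outcomes.get((b, a)))
            if head_to_head == b:
                grp = [b, a]
        order.extend(grp)
    return {m: i + 1 for i, m in enumerate(order)}


class TestTubeRanks:
    def test_transitive_tournament(self):
        out = {
            ("A", "B"): "A", ("A", "C"): "A", ("A", "D"): "A",
            ("B", "C"): "B", ("B", "D"): "B", ("C", "D"): "C",
        }
        [r] = bh.tube_daily_ranks(make_bouts(out))
        assert r.ranks == {"A": 1, "B": 2, "C": 3, "D": 4}
        assert r.linear

    def test_cycle_is_not_linear(self):
        out = {
            ("A", "B"): "A", ("B", "C"): "B", ("A", "C"): "C",
            ("A", "D"): "A", ("B", "D"): "B", ("C", "D"): "C",
        }
        [r] = bh.tube_daily_ranks(make_bouts(out))
        assert not r.linear
        assert r.ranks == oracle_ranks(out)

    def test_all_64_tournaments_match_oracle(self):
        """Exhaustive enumeration of 4-mouse round-robin outcomes."""
        for code in range(64):
            bits = [(code >> k) & 1 for k in range(6)]
            out = tournament(bits)
            [r] = bh.tube_daily_ranks(make_bouts(out))
            assert r.ranks == oracle_ranks(out), f"code={code}"
            wins = sorted(
                (sum(w == m for w in out.values()) for m in MICE), reverse=True
            )
            assert r.linear == (wins == [3, 2, 1, 0])

    def test_incomplete_round_robin_names_missing_pair(self):
        out = {
            ("A", "B"): "A", ("A", "C"): "A", ("A", "D"): "A",
            ("B", "C"): "B", ("B", "D"): "B",
        }
        with pytest.raises(ValueError, match=r"\('C', 'D'\)"):
            bh.tube_daily_ranks(make_bouts(out))


class TestStableHierarchy:
    @staticmethod
    def days(rank_seq):
        return [
            bh.RankDay("g0", d, ranks, len(set(ranks.values())) == len(ranks))
            for d, ranks in enumerate(rank_seq, start=1)
        ]

    def test_constant_linear_from_day_one(self):
        ranks = {"A": 1, "B": 2, "C": 3, "D": 4}
        assert bh.detect_stable_hierarchy(self.days([ranks] * 5)) == 1

    def test_never_stable_returns_none(self):
        seqs = [
            {"A": 1 + (d % 2), "B": 2 - (d % 2), "C": 3, "D": 4} for d in range(6)
        ]
        assert bh.detect_stable_hierarchy(self.days(seqs)) is None

    def test_fluctuation_then_stable_from_day_five(self):
        r1 = {"A": 2, "B": 1, "C": 3, "D": 4}
        r2 = {"A": 1, "B": 2, "C": 3, "D": 4}
        seq = [r1, r2, r2, r1] + [r2] * 6  # days 1-4 fluctuate, 5-10 constant
        assert bh.detect_stable_hierarchy(self.days(seq)) == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bh.detect_stable_hierarchy([])


class TestTubeTimeInflection:
    def test_exact_two_level_series(self):
        s = LongSeries("t", np.arange(6), [30, 30, 30, 10, 10, 10])
        assert bh.tube_time_inflection(s) == 3

    def test_constant_series_has_no_drop(self):
        s = LongSeries("t", np.arange(6), [20.0] * 6)
        assert bh.tube_time_inflection(s) is None

    def test_increasing_step_has_no_drop(self):
        s = LongSeries("t", np.arange(6), [10, 10, 10, 30, 30, 30])
        assert bh.tube_time_inflection(s) is None

    def test_noisy_recovery_within_one_day(self, rng):
        hits = 0
        for _ in range(200):
            y = np.concatenate([rng.normal(25, 2, 8), rng.normal(8, 2, 12)])
            got = bh.tube_time_inflection(LongSeries("t", np.arange(20), y))
            hits += got is not None and abs(got - 8) <= 1
        assert hits >= 180  # >= 90% of replicates

    def test_missing_days_rejected(self):
        s = LongSeries("t", [0, 1, 3, 4], [30, 30, 10, 10])
        with pytest.raises(ValueError, match="missing"):
            bh.tube_time_inflection(s)


class TestWinningProportions:
    def test_hand_counted_pellets(self, pair_trials):
        props = bh.winning_proportions(pair_trials, "pellet")
        by_mouse = props.set_index("mouse_id")["proportion"]
        assert by_mouse["A"] == pytest.approx(0.8)
        assert by_mouse["B"] == pytest.approx(0.2)

    def test_stage_winner_from_timestamps(self, pair_trials):
        for stage in ("exit_sa", "reach_rz"):
            props = bh.winning_proportions(pair_trials, stage)
            by_mouse = props.set_index("mouse_id")["proportion"]
            # fixture makes the pellet winner first at every stage
            assert by_mouse["A"] == pytest.approx(0.8)

    def test_tied_timestamps_split_credit(self, pair_trials):
        tied = pair_trials.copy()
        tied["t_exit_sa_s"] = tied["t_gate_open_s"] + 1.0
        props = bh.winning_proportions(tied, "exit_sa")
        assert (props["proportion"] == 0.5).all()

    @given(st.lists(st.sampled_from(["A", "B"]), min_size=2, max_size=12))
    def test_per_pair_proportions_sum_to_one(self, winners):
        rows = []
        for i, w in enumerate(winners):
            for m, opp in (("A", "B"), ("B", "A")):
                rows.append(
                    {
                        "group_id": "g0", "day": 0, "pair_id": "A-B",
                        "trial_idx": i, "subject_id": m, "opponent_id": opp,
                        "t_gate_open_s": 30.0 * i,
                        "t_exit_sa_s": 30.0 * i + (1 if m == w else 2),
                        "t_reach_rz_s": 30.0 * i + (3 if m == w else 5),
                        "pellet_winner_id": w,
                        "opponent_relative_rank": "dominant",
                    }
                )
        df = pd.DataFrame(rows)
        for stage in bh.STAGES:
            props = bh.winning_proportions(df, stage)
            assert props["proportion"].sum() == pytest.approx(1.0)


def _group_trials(props_by_mouse, latencies):
    """Trial table realizing given per-mouse win proportions/latencies."""
    mice = sorted(props_by_mouse)
    rows = []
    t = 0.0
    for a, b in itertools.combinations(mice, 2):
        # a wins round(10 * p_a/(p_a+p_b)) of 10 trials against b
        pa = props_by_mouse[a] / (props_by_mouse[a] + props_by_mouse[b] + 1e-12)
        wins_a = int(round(10 * pa))
        for i in range(10):
            w = a if i < wins_a else b
            for m, opp in ((a, b), (b, a)):
                rows.append(
                    {
                        "group_id": "g0", "day": 0, "pair_id": f"{a}-{b}",
                        "trial_idx": i, "subject_id": m, "opponent_id": opp,
                        "t_gate_open_s": t,
                        "t_exit_sa_s": t + 0.5,
                        "t_reach_rz_s": t + latencies[m],
                        "pellet_winner_id": w,
                        "opponent_relative_rank": "dominant",
                    }
                )
            t += 30.0
    return pd.DataFrame(rows)


class TestCompetitiveOrder:
    def test_strict_proportion_order(self):
        trials = _group_trials(
            {"A": 0.8, "B": 0.6, "C": 0.4, "D": 0.2},
            {"A": 3.0, "B": 3.0, "C": 3.0, "D": 3.0},
        )
        [res] = bh.assign_competitive_order(trials)
        assert res.order == {"A": "C1", "B": "C2", "C": "C3", "D": "C4"}

    def test_latency_breaks_proportion_tie(self):
        rows = []
        for i in range(10):
            w = "A" if i % 2 == 0 else "B"  # 5/5 split
            for m, opp in (("A", "B"), ("B", "A")):
                rows.append(
                    {
                        "group_id": "g0", "day": 0, "pair_id": "A-B",
                        "trial_idx": i, "subject_id": m, "opponent_id": opp,
                        "t_gate_open_s": 30.0 * i,
                        "t_exit_sa_s": 30.0 * i + 0.5,
                        "t_reach_rz_s": 30.0 * i + (3.0 if m == "A" else 5.0),
                        "pellet_winner_id": w,
                        "opponent_relative_rank": "dominant",
                    }
                )
        [res] = bh.assign_competitive_order(pd.DataFrame(rows))
        assert res.order["A"] == "C1"
        assert res.order["B"] == "C2"
        assert res.tie_broken["A"] and res.tie_broken["B"]

    def test_matches_oracle_sort_on_random_fixtures(self, rng):
        for _ in range(20):
            props = {m: rng.uniform(0.1, 0.9) for m in "ABCD"}
            lats = {m: rng.uniform(2, 8) for m in "ABCD"}
            trials = _group_trials(props, lats)
            [res] = bh.assign_competitive_order(trials)
            # oracle: sort on (-observed proportion, latency, id)
            observed = res.pellet_proportion
            expected = sorted("ABCD", key=lambda m: (-observed[m], lats[m], m))
            got = sorted("ABCD", key=lambda m: res.order[m])
            assert got == expected

    def test_relabeling_equivariance(self):
        trials = _group_trials(
            {"A": 0.9, "B": 0.5, "C": 0.3, "D": 0.1},
            {"A": 3.0, "B": 4.0, "C": 5.0, "D": 6.0},
        )
        relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        renamed = trials.copy()
        for col in ("subject_id", "opponent_id", "pellet_winner_id"):
            renamed[col] = renamed[col].map(relabel)
        renamed["pair_id"] = renamed["pair_id"].map(
            lambda p: "-".join(relabel[x] for x in p.split("-"))
        )
        [r1] = bh.assign_competitive_order(trials)
        [r2] = bh.assign_competitive_order(renamed)
        assert {relabel[m]: c for m, c in r1.order.items()} == r2.order


class TestLatencySummary:
    @staticmethod
    def trials_for(latency_by_day, mouse="A"):
        rows = []
        for day, lats in latency_by_day.items():
            for i, lat in enumerate(lats):
                rows.append(
                    {
                        "group_id": "g0", "day": day, "pair_id": "solo",
                        "trial_idx": i, "subject_id": mouse, "opponent_id": "",
                        "t_gate_open_s": 100.0 * i,
                        "t_exit_sa_s": 100.0 * i + 0.5,
                        "t_reach_rz_s": 100.0 * i + lat,
                        "pellet_winner_id": mouse,
                        "opponent_relative_rank": "",
                    }
                )
        return pd.DataFrame(rows)

    def test_criterion_met_on_two_fast_days(self):
        df = self.trials_for({1: [4.0, 4.0], 2: [4.0, 4.0]})
        out = bh.latency_summary(df, mode="alone")
        assert bool(out.loc[0, "criterion_met"])
        assert out.loc[0, "criterion_day"] == 2

    def test_criterion_met_after_slow_start(self):
        df = self.trials_for({1: [6.0], 2: [4.0], 3: [4.0]})
        out = bh.latency_summary(df, mode="alone")
        assert bool(out.loc[0, "criterion_met"])
        assert out.loc[0, "criterion_day"] == 3

    def test_boundary_five_seconds_not_met(self):
        df = self.trials_for({1: [5.0], 2: [5.0]})
        out = bh.latency_summary(df, mode="alone")
        assert not bool(out.loc[0, "criterion_met"])

    def test_empty_mode_selection_rejected(self):
        df = self.trials_for({1: [4.0]})
        with pytest.raises(ValueError, match="competing"):
            bh.latency_summary(df, mode="competing")


class TestWarmspot:
    @staticmethod
    def records(occ):
        return pd.DataFrame(
            [
                {"group_id": "g0", "day": 1, "mouse_id": m, "occupancy_s": o}
                for m, o in occ.items()
            ]
        )

    def test_descending_order(self):
        out = bh.warmspot_occupancy(
            self.records({"A": 600.0, "B": 300.0, "C": 200.0, "D": 100.0})
        )
        assert list(out.sort_values("ws_order")["mouse_id"]) == ["A", "B", "C", "D"]

    def test_all_zero_occupancy_ties_by_id(self):
        out = bh.warmspot_occupancy(self.records({m: 0.0 for m in "DCBA"}))
        assert list(out.sort_values("ws_order")["mouse_id"]) == ["A", "B", "C", "D"]

    def test_totals_bounded_by_session_length(self):
        with pytest.raises(ValueError, match="session length"):
            bh.warmspot_occupancy(
                self.records({"A": 900.0, "B": 400.0, "C": 0.0, "D": 0.0})
            )

    def test_negative_durations_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bh.warmspot_occupancy(self.records({"A": -1.0, "B": 1.0}))


class TestOrderRankCorrelation:
    @staticmethod
    def make_order(seq):
        return bh.CompetitiveOrderResult(
            "g0",
            {m: f"C{i + 1}" for i, m in enumerate(seq)},
            {m: 0.0 for m in seq},
            {m: 0.0 for m in seq},
            {m: False for m in seq},
        )

    @staticmethod
    def make_ranks(seq):
        return bh.RankDay("g0", 1, {m: i + 1 for i, m in enumerate(seq)}, True)

    def test_identical_orders_give_rho_one(self):
        assert bh.order_rank_correlation(
            self.make_order("ABCD"), self.make_ranks("ABCD")
        ) == pytest.approx(1.0)

    def test_reversed_orders_give_rho_minus_one(self):
        assert bh.order_rank_correlation(
            self.make_order("ABCD"), self.make_ranks("DCBA")
        ) == pytest.approx(-1.0)

    def test_matches_closed_form_on_permutations(self):
        import itertools as it

        for perm in it.permutations("ABCD"):
            rho = bh.order_rank_correlation(
                self.make_order("ABCD"), self.make_ranks(perm)
            )
            order_idx = {m: i + 1 for i, m in enumerate("ABCD")}
            rank_idx = {m: i + 1 for i, m in enumerate(perm)}
            d2 = sum((order_idx[m] - rank_idx[m]) ** 2 for m in "ABCD")
            expected = 1 - 6 * d2 / (4 * (16 - 1))
            assert rho == pytest.approx(expected)

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError):
            bh.order_rank_correlation(self.make_order("AB"), self.make_ranks("AB"))
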