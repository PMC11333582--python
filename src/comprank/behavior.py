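"""Dominance-hierarchy and competitive-behavior scoring.

Implements the behavioral readouts of the round-robin assays: daily tube
ranks with a linearity flag, detection of the stable linear hierarchy,
the tube-time inflection point, stage-wise winning proportions in the
food-competition test, the C1..CN competitive order with the
latency tie-break, training-criterion latency summaries, warm-spot
occupancy order, and the rank correlation between competitive order and
tube rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import LongSeries

__all__ = [
    "RankDay",
    "CompetitiveOrderResult",
    "tube_daily_ranks",
    "detect_stable_hierarchy",
    "tube_time_inflection",
    "winning_proportions",
    "assign_competitive_order",
    "latency_summary",
    "warmspot_occupancy",
    "order_rank_correlation",
]

STAGES = ("exit_sa", "reach_rz", "pellet")
_STAGE_COLUMN = {"exit_sa": "t_exit_sa_s", "reach_rz": "t_reach_rz_s"}


@dataclass
class RankDay:
    """Ranks of one group on one day; rank 1 is most dominant."""

    group_id: str
    day: int
    ranks: dict[str, int]
    linear: bool


@dataclass
class CompetitiveOrderResult:
    """C1..CN competitive order from overall pellet proportions."""

    group_id: str
    order: dict[str, str]  # mouse -> "C1".."CN"
    pellet_proportion: dict[str, float]
    mean_latency_s: dict[str, float]
    tie_broken: dict[str, bool]


# ---------------------------------------------------------------------------
# tube test


def _validate_round_robin(day_bouts: pd.DataFrame, group_id: str, day: int) -> list[str]:
    mice = sorted(set(day_bouts["mouse_a"]) | set(day_bouts["mouse_b"]))
    seen = {
        frozenset((a, b))
        for a, b in zip(day_bouts["mouse_a"], day_bouts["mouse_b"])
    }
    missing = [
        tuple(sorted(p))
        for p in (frozenset(c) for c in itertools.combinations(mice, 2))
        if p not in seen
    ]
    if missing:
        raise ValueError(
            f"incomplete round robin for group {group_id} day {day}: "
            f"missing pairs {missing}"
        )
    return mice


def tube_daily_ranks(bouts: pd.DataFrame) -> list[RankDay]:
    """Per-day tube ranks from round-robin win counts.

    Mice are ranked by descending bout wins. A day is *linear* iff the
    win counts are exactly N-1, N-2, ..., 0 (a transitive tournament).
    Tied win counts (non-linear days) are broken by the head-to-head
    result, then by lexicographically smaller mouse id, so ranks are
    always deterministic.
    """
    if bouts.empty:
        raise ValueError("empty bout table")
    bad = bouts[(bouts["winner"] != bouts["mouse_a"]) & (bouts["winner"] != bouts["mouse_b"])]
    if not bad.empty:
        raise ValueError("bout winner must be one of the two contestants")
    results = []
    for (group_id, day), day_bouts in bouts.groupby(["group_id", "day"], sort=True):
        mice = _validate_round_robin(day_bouts, group_id, int(day))
        wins = {m: 0 for m in mice}
        beat: dict[tuple[str, str], bool] = {}
        for row in day_bouts.itertuples(index=False):
            wins[row.winner] += 1
            loser = row.mouse_b if row.winner == row.mouse_a else row.mouse_a
            beat[(row.winner, loser)] = True

        # sort by descending wins; two-way ties by head-to-head result,
        # larger tie groups (cycles) by lexicographic mouse id
        ordered: list[str] = []
        for _, tied in itertools.groupby(
            sorted(mice, key=lambda m: (-wins[m], m)), key=lambda m: wins[m]
        ):
            tied = list(tied)
            if len(tied) == 2 and beat.get((tied[1], tied[0])):
                tied.reverse()
            ordered.extend(tied)
        ranks = {m: r + 1 for r, m in enumerate(ordered)}
        linear = sorted(wins.values(), reverse=True) == list(range(len(mice) - 1, -1, -1))
        results.append(RankDay(group_id, int(day), ranks, linear))
    return results


def detect_stable_hierarchy(
    rank_days: list[RankDay], window: int = 3
) -> int | None:
    """Earliest day d with identical linear ranks on days d..d+window-1.

    Days must be consecutive calendar days within the window. Returns
    None if the hierarchy never stabilizes.
    """
    if not rank_days:
        raise ValueError("empty rank-day list")
    days = sorted(rank_days, key=lambda r: r.day)
    for i in range(len(days) - window + 1):
        block = days[i : i + window]
        if not all(r.linear for r in block):
            continue
        if any(block[k + 1].day != block[k].day + 1 for k in range(window - 1)):
            continue
        if all(r.ranks == block[0].ranks for r in block[1:]):
            return block[0].day
    return None


def tube_time_inflection(mean_duration_by_day: LongSeries) -> int | None:
    """Change-point day where the mean tube-bout duration settles.

    Fits a two-segment piecewise-constant model by exhaustive scan of
    the split point, minimizing total squared error. Returns the day
    label of the first day of the after segment, or None when the best
    split does not decrease the mean (no drop to detect).
    """
    days = mean_duration_by_day.days
    y = mean_duration_by_day.values
    if days.size < 4:
        raise ValueError("need at least 4 days")
    if np.any(np.diff(days) != 1):
        raise ValueError("series has missing days")
    best = None
    for k in range(1, days.size):  # after segment starts at index k
        left, right = y[:k], y[k:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, left.mean(), right.mean())
    _, k, m_before, m_after = best
    if m_after >= m_before:
        return None
    return int(days[k])


# ---------------------------------------------------------------------------
# food competition


def winning_proportions(trials: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Per-pair, per-mouse winning proportion at one race stage.

    For ``exit_sa`` and ``reach_rz`` the winner of a trial is the mouse
    with the earlier timestamp (ties award 0.5 to each, keeping per-pair
    sums at 1); for ``pellet`` it is the recorded pellet consumer.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    if trials.empty:
        raise ValueError("empty trial table")
    rows = []
    for (group_id, pair_id), block in trials.groupby(["group_id", "pair_id"], sort=True):
        mice = sorted(block["subject_id"].unique())
        if len(mice) != 2:
            raise ValueError(f"pair {pair_id} does not have exactly two mice")
        credit = {m: 0.0 for m in mice}
        n_trials = 0
        for _, trial in block.groupby(["day", "trial_idx"], sort=True):
            n_trials += 1
            if stage == "pellet":
                credit[trial["pellet_winner_id"].iloc[0]] += 1.0
            else:
                col = _STAGE_COLUMN[stage]
                if trial[col].isna().any():
                    raise ValueError(f"missing {col} timestamps for stage {stage}")
                t = dict(zip(trial["subject_id"], trial[col]))
                if len(t) != 2:
                    raise ValueError(
                        f"trial needs both perspectives of pair {pair_id}"
                    )
                (m1, t1), (m2, t2) = t.items()
                if t1 == t2:
                    credit[m1] += 0.5
                    credit[m2] += 0.5
                else:
                    credit[m1 if t1 < t2 else m2] += 1.0
        for m in mice:
            rows.append(
                {
                    "group_id": group_id,
                    "pair_id": pair_id,
                    "mouse_id": m,
                    "stage": stage,
                    "proportion": credit[m] / n_trials,
                    "n_trials": n_trials,
                }
            )
    return pd.DataFrame(rows)


def _mean_rz_latency(trials: pd.DataFrame) -> dict[str, float]:
    lat = trials["t_reach_rz_s"] - trials["t_gate_open_s"]
    return lat.groupby(trials["subject_id"]).mean().to_dict()


def assign_competitive_order(trials: pd.DataFrame) -> list[CompetitiveOrderResult]:
    """C1..CN order by overall pellet proportion, latency tie-break.

    Mice are sorted by descending fraction of their trials won (pellet
    consumed); mice sharing the same winning proportion are ordered by
    ascending mean latency to reach the reward zone.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    out = []
    for group_id, block in trials.groupby("group_id", sort=True):
        mice = sorted(block["subject_id"].unique())
        expected_pairs = {frozenset(p) for p in itertools.combinations(mice, 2)}
        seen_pairs = {
            frozenset((s, o))
            for s, o in zip(block["subject_id"], block["opponent_id"])
        }
        missing = expected_pairs - seen_pairs
        if missing:
            raise ValueError(
                f"group {group_id}: missing round-robin pairs "
                f"{sorted(tuple(sorted(p)) for p in missing)}"
            )
        props = {}
        for m in mice:
            mine = block[block["subject_id"] == m]
            if mine.empty:
                raise ValueError(f"mouse {m} has no trials")
            props[m] = float((mine["pellet_winner_id"] == m).mean())
        latency = _mean_rz_latency(block)
        ordered = sorted(mice, key=lambda m: (-props[m], latency[m], m))
        tie = {
            m: any(props[m] == props[o] for o in mice if o != m) for m in mice
        }
        out.append(
            CompetitiveOrderResult(
                group_id=group_id,
                order={m: f"C{i + 1}" for i, m in enumerate(ordered)},
                pellet_proportion=props,
                mean_latency_s={m: float(latency[m]) for m in mice},
                tie_broken=tie,
            )
        )
    return out


def latency_summary(trials: pd.DataFrame, mode: str = "competing") -> pd.DataFrame:
    """Per-mouse mean gate-open -> RZ latency and the training criterion.

    ``mode='alone'`` selects training trials (no opponent recorded),
    ``mode='competing'`` selects paired trials. The training criterion is
    met when a mouse's daily mean latency is below 5 s on two consecutive
    days.
    """
    if mode not in ("alone", "competing"):
        raise ValueError("mode must be 'alone' or 'competing'")
    alone = trials["opponent_id"].isna() | (trials["opponent_id"] == "")
    sel = trials[alone] if mode == "alone" else trials[~alone]
    if sel.empty:
        raise ValueError(f"no trials in mode {mode!r}")
    if sel["t_reach_rz_s"].isna().any():
        raise ValueError("RZ timestamps required for latency summary")
    lat = sel["t_reach_rz_s"] - sel["t_gate_open_s"]
    rows = []
    for mouse, idx in sel.groupby("subject_id").groups.items():
        sub = sel.loc[idx]
        daily = (sub["t_reach_rz_s"] - sub["t_gate_open_s"]).groupby(sub["day"]).mean()
        daily = daily.sort_index()
        met = False
        met_day = None
        days = daily.index.to_numpy()
        for i in range(len(days) - 1):
            if days[i + 1] == days[i] + 1 and daily.iloc[i] < 5.0 and daily.iloc[i + 1] < 5.0:
                met, met_day = True, int(days[i + 1])
                break
        rows.append(
            {
                "mouse_id": mouse,
                "mode": mode,
                "mean_latency_s": float(lat.loc[idx].mean()),
                "criterion_met": met,
                "criterion_day": met_day,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# warm spot


def warmspot_occupancy(
    records: pd.DataFrame, session_length_s: float = 1200.0
) -> pd.DataFrame:
    """Total warm-spot occupancy per mouse and the within-group order.

    Occupancy totals are validated against the 20-min session length.
    Ties in total occupancy are broken by mouse id (deterministic).
    """
    if records.empty:
        raise ValueError("empty warm-spot table")
    if (records["occupancy_s"] < 0).any():
        raise ValueError("negative occupancy duration")
    rows = []
    for (group_id, day), block in records.groupby(["group_id", "day"], sort=True):
        totals = block.groupby("mouse_id")["occupancy_s"].sum()
        if totals.sum() > session_length_s + 1e-9:
            raise ValueError(
                f"group {group_id} day {day}: occupancy exceeds session length"
            )
        ordered = sorted(totals.index, key=lambda m: (-totals[m], m))
        for i, m in enumerate(ordered):
            rows.append(
                {
                    "group_id": group_id,
                    "day": int(day),
                    "mouse_id": m,
                    "occupancy_s": float(totals[m]),
                    "ws_order": i + 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# order vs rank


def order_rank_correlation(
    order: CompetitiveOrderResult, ranks: RankDay
) -> float:
    """Spearman correlation between competitive order and tube rank."""
    mice = sorted(order.order)
    if set(mice) != set(ranks.ranks):
        raise ValueError("competitive order and ranks cover different mice")
    if len(mice) < 3:
        raise ValueError("need at least 3 mice for a rank correlation")
    x = [int(order.order[m][1:]) for m in mice]
    y = [ranks.ranks[m] for m in mice]
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
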